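"""Read-depth dosage diagnostics: compensation, sex ratio, copy number."""

import numpy as np
import pandas as pd
import pytest

import sexlink as sl
from sexlink.dosage import (
    analyze_marker,
    compensation_test,
    depth_summary,
    depth_histogram,
    estimate_extra_copies,
    flag_paralog_suspects,
    sex_depth_ratio,
    textbook_depth_stats,
)
from sexlink.gbsio import AlleleDepthMatrix, GenotypeMatrix, PhenotypeTable
from sexlink.simulate import SimConfig, simulate_population


def build_marker(ref_depths, alt_depths, codes, sexes):
    n = len(ref_depths)
    markers = pd.DataFrame(
        {"chrom": ["c1"], "pos": [1], "ref": ["A"], "alt": ["C"]},
        index=pd.Index(["m1"], name="marker_id"),
    )
    adm = AlleleDepthMatrix(
        [f"a{i}" for i in range(n)], markers,
        np.stack([np.asarray(ref_depths), np.asarray(alt_depths)], axis=1
                 ).reshape(n, 1, 2),
    )
    g = GenotypeMatrix(adm.accessions, markers.copy(),
                       np.asarray(codes, dtype=np.int8).reshape(n, 1))
    ph = PhenotypeTable(pd.DataFrame({"accession": adm.accessions, "sex": sexes}))
    return adm, g, ph


def test_uniform_depth_summary():
    n = 40
    adm, g, ph = build_marker([30] * n, [30] * n, [1] * n, ["F"] * 20 + ["M"] * 20)
    rep = depth_summary(adm, g, ph, "m1")
    assert rep.total_f.mean == 60.0 and rep.total_f.sd == 0.0
    assert rep.total_m.mean == 60.0
    assert rep.allele_by_class[("het", "ref")].mean == 30.0


def test_compensation_exact_halving():
    # homozygote allele depth 60, heterozygote allele depth 30 -> ratio 0.5
    ref = [60] * 10 + [30] * 10 + [0] * 10
    alt = [0] * 10 + [30] * 10 + [60] * 10
    codes = [0] * 10 + [1] * 10 + [2] * 10
    adm, g, ph = build_marker(ref, alt, codes, ["F", "M"] * 15)
    rep = compensation_test(depth_summary(adm, g, ph, "m1"))
    assert rep.compensation_ratios["ref"] == pytest.approx(0.5)
    assert rep.compensation_ratios["alt"] == pytest.approx(0.5)
    assert rep.dose_compensated is True
    assert rep.compensation_violated is False


def test_compensation_violation_common_allele_not_halved():
    # collapsed-paralog signature: common-allele depth the same in
    # heterozygous females and homozygous males (~9 reads), rare-allele
    # depth in hets about twice that
    rng = np.random.default_rng(0)
    n_f, n_m = 60, 60
    ref = np.r_[rng.poisson(9.6, n_f), rng.poisson(8.8, n_m)]
    alt = np.r_[rng.poisson(22.3, n_f), np.zeros(n_m, dtype=int)]
    codes = [1] * n_f + [0] * n_m
    adm, g, ph = build_marker(ref, alt, codes, ["F"] * n_f + ["M"] * n_m)
    rep = compensation_test(depth_summary(adm, g, ph, "m1"))
    assert rep.compensation_ratios["ref"] > 0.8
    assert rep.dose_compensated is False
    assert rep.compensation_violated is True


def test_sex_depth_ratio_elevated_and_flat():
    rng = np.random.default_rng(1)
    # printed-scale contrast: female mean ~31.9, male mean ~9.0
    f = rng.normal(31.9, 14.1, 160).clip(0).round()
    m = rng.normal(9.0, 5.3, 100).clip(0).round()
    adm, g, ph = build_marker(
        np.r_[f, m].astype(int), np.zeros(260, dtype=int),
        [0] * 260, ["F"] * 160 + ["M"] * 100)
    rep = sex_depth_ratio(depth_summary(adm, g, ph, "m1"))
    assert rep.sex_depth_ratio > 3
    assert rep.ratio_elevated is True
    est = estimate_extra_copies(rep, seed=0)
    assert est.extra_copy_estimate == pytest.approx(31.9 / 9.0 - 1.0, abs=0.4)
    lo, hi = est.extra_copy_ci
    assert lo < est.extra_copy_estimate < hi

    # textbook-like marker: ~60.5 vs ~61.3 -> ratio ~ated 1, not elevated
    f2 = rng.normal(60.5, 19.0, 160).round()
    m2 = rng.normal(61.3, 19.0, 100).round()
    adm, g, ph = build_marker(np.r_[f2, m2].astype(int), np.zeros(260, dtype=int),
                              [0] * 260, ["F"] * 160 + ["M"] * 100)
    rep2 = sex_depth_ratio(depth_summary(adm, g, ph, "m1"))
    assert rep2.sex_depth_ratio == pytest.approx(1.0, abs=0.1)
    assert rep2.ratio_elevated is False
    est2 = estimate_extra_copies(rep2, seed=0)
    assert est2.extra_copy_estimate <= 0.05


def test_equal_means_ratio_one_estimate_zero():
    adm, g, ph = build_marker([10] * 20, [0] * 20, [0] * 20, ["F", "M"] * 10)
    rep = estimate_extra_copies(sex_depth_ratio(depth_summary(adm, g, ph, "m1")),
                                seed=0)
    assert rep.sex_depth_ratio == 1.0
    assert rep.extra_copy_estimate == 0.0


def test_male_null_depth_flagged_separately():
    ref = [12] * 10 + [0] * 10
    adm, g, ph = build_marker(ref, [0] * 20, [0] * 10 + [-1] * 10,
                              ["F"] * 10 + ["M"] * 10)
    rep = sex_depth_ratio(depth_summary(adm, g, ph, "m1"))
    assert rep.male_null is True
    assert not np.isfinite(rep.sex_depth_ratio)


def test_flag_reasons_compose():
    # equal copy number but a null allele in one sex: compensation broken
    # while total depth stays flat -> flagged for compensation only
    rng = np.random.default_rng(2)
    n = 120
    half = n // 2
    ref = np.r_[rng.poisson(20, half), rng.poisson(20, half)]
    alt = np.r_[np.zeros(half, dtype=int), rng.poisson(20, half)]
    total_ref = ref.copy()
    codes = [0] * half + [1] * half
    adm, g, ph = build_marker(total_ref, alt, codes, ["F", "M"] * (n // 2))
    rep = analyze_marker(adm, g, ph, "m1", seed=0)
    flagged = flag_paralog_suspects([rep], None)
    assert flagged == ["m1"]
    assert rep.flag_reasons == ["compensation_violated"]


def test_extra_copy_recovery_and_scale_invariance():
    ests = {}
    for depth in (10.0, 20.0):
        cfg = SimConfig(n_accessions=265, n_autosomal=30, n_w_strict=0,
                        n_w_partial=0, n_z_poly=0, n_paralog_tags=10,
                        extra_w_copies=2, mean_depth=depth, missing_rate=0.0,
                        seed=23)
        adm, ph, truth = simulate_population(cfg)
        g = sl.call_genotypes(adm)
        par = truth.table.index[truth.table["class_label"] == "paralog_collapsed"]
        vals = [analyze_marker(adm, g, ph, m, seed=0).extra_copy_estimate
                for m in par]
        ests[depth] = np.mean(vals)
        assert all(1.5 <= v <= 2.5 for v in vals)
    # doubling sequencing depth leaves the copy-number estimate unchanged
    assert ests[10.0] == pytest.approx(ests[20.0], abs=0.2)


def test_paralog_flagging_against_truth(zw_genotypes):
    _, adm_f, g, ph, truth = zw_genotypes
    classes = truth.table.loc[g.markers.index, "class_label"]
    textbook = sl.identify_textbook_markers(g, min_call_rate=0.95)
    tb_reports = [analyze_marker(adm_f, g, ph, m, seed=0) for m in textbook[:60]]
    reference = textbook_depth_stats(tb_reports)
    reports = [analyze_marker(adm_f, g, ph, m, seed=0) for m in g.markers.index]
    flagged = set(flag_paralog_suspects(reports, reference))
    paralogs = set(g.markers.index[classes == "paralog_collapsed"])
    autosomal = set(g.markers.index[classes == "autosomal"])
    assert paralogs <= flagged
    assert len(flagged & autosomal) / len(autosomal) <= 0.01


def test_bootstrap_is_seed_reproducible():
    rng = np.random.default_rng(3)
    ref = rng.poisson(12, 60)
    adm, g, ph = build_marker(ref, np.zeros(60, dtype=int), [0] * 60,
                              ["F", "M"] * 30)
    r1 = analyze_marker(adm, g, ph, "m1", seed=11)
    r2 = analyze_marker(adm, g, ph, "m1", seed=11)
    assert r1.extra_copy_ci == r2.extra_copy_ci


def test_depth_histogram_binning():
    adm, g, ph = build_marker([5, 15, 25, 104], [0, 0, 0, 0], [0, 0, 0, 0],
                              ["F", "F", "M", "M"])
    hist = depth_histogram(adm, g, ph, "m1", bin_width=10)
    f_ref = hist[(hist.group == "F") & (hist.allele == "ref")]
    assert sorted(f_ref.bin_low) == [0, 10]
    assert int(hist[(hist.group == "M") & (hist.allele == "ref")].bin_low.max()) == 100
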