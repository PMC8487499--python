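"""Exact-test correctness against enumeration oracles, kinship/structure
contracts, and the mixed-model scan's limiting cases."""

from fractions import Fraction
from itertools import product
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sexlink as sl
from sexlink.assoc import (
    KinshipMatrix,
    bonferroni_threshold,
    compute_kinship,
    fisher_exact_rc,
    fisher_scan,
    gwas_sex,
    mlm_scan,
    sex_genotype_table,
    structure_components,
    _reml_neg_ll,
)
from sexlink.gbsio import GenotypeMatrix, PhenotypeTable
from sexlink.simulate import SimConfig, simulate_population


# ---------------------------------------------------------------------------
# independent exact-test oracle: enumerate margin-fixed tables with exact
# rational point probabilities; qualification decided by exact integer
# comparison of factorial products (within a margin class the point
# probability is inversely proportional to the product of cell factorials)
# ---------------------------------------------------------------------------

def brute_force_exact_p(table) -> float:
    t = np.asarray(table, dtype=np.int64)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = int(t.sum())
    const = Fraction(
        np.prod([factorial(int(x)) for x in r], dtype=object)
        * np.prod([factorial(int(x)) for x in c], dtype=object),
        factorial(n),
    )

    def cellfact(tab):
        out = 1
        for v in tab.flat:
            out *= factorial(int(v))
        return out

    obs_fact = cellfact(t)
    total = Fraction(0)
    ranges = [range(int(min(r[0], c[j])) + 1) for j in range(len(c) - 1)]
    for top in product(*ranges):
        last = int(r[0]) - sum(top)
        if last < 0 or last > c[-1]:
            continue
        row0 = np.array([*top, last])
        tab = np.vstack([row0, c - row0])
        if (tab < 0).any():
            continue
        f = cellfact(tab)
        if f >= obs_fact:  # point prob <= observed's, exactly
            total += Fraction(const, f)
    return float(total)


def test_balanced_table_is_null():
    assert fisher_exact_rc([[10, 10], [10, 10]]) == 1.0
    assert fisher_exact_rc([[7, 7, 7], [3, 3, 3]]) == 1.0


@pytest.mark.parametrize("shape", [(2, 2), (2, 3)])
def test_exact_test_matches_enumeration_on_random_tables(shape):
    rng = np.random.default_rng(0)
    checked = 0
    while checked < 120:
        t = rng.integers(0, 11, shape)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            continue
        p = fisher_exact_rc(t)
        assert p == pytest.approx(brute_force_exact_p(t), rel=1e-10)
        checked += 1


@given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
@settings(max_examples=250, deadline=None, derandomize=True)
def test_2x2_matches_scipy(cells):
    t = np.array(cells).reshape(2, 2)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return
    assert fisher_exact_rc(t) == pytest.approx(
        stats.fisher_exact(t).pvalue, rel=1e-9
    )


def test_extreme_association_scale():
    # a near-perfect genotype-sex association at n ~ 265 reaches the
    # p ~ 1e-60 scale and still matches the exact enumeration oracle
    t = [[3, 159], [101, 2]]
    p = fisher_exact_rc(t)
    assert p < 1e-50
    assert p == pytest.approx(brute_force_exact_p(t), rel=1e-9)


def test_degenerate_tables_return_one():
    assert fisher_exact_rc([[0, 0], [5, 3]]) == 1.0  # zero row margin
    assert fisher_exact_rc([[4, 0], [2, 0]]) == 1.0  # single surviving column


def test_bonferroni_threshold():
    assert bonferroni_threshold(1) == 0.05
    assert bonferroni_threshold(19_592) == pytest.approx(0.05 / 19_592)
    with pytest.raises(ValueError):
        bonferroni_threshold(0)
    # monotone: lowering alpha never adds significant markers
    p = np.array([1e-8, 1e-4, 0.2])
    m = len(p)
    sig_at = lambda a: set(np.flatnonzero(p < bonferroni_threshold(m, a)))
    assert sig_at(0.01) <= sig_at(0.05)


def test_sex_genotype_table_toy():
    g = GenotypeMatrix(
        ["a1", "a2", "a3", "a4", "a5"],
        pd.DataFrame({"chrom": ["c1"], "pos": [1], "ref": ["A"], "alt": ["C"]},
                     index=pd.Index(["m1"], name="marker_id")),
        np.array([[1], [1], [0], [0], [-1]], dtype=np.int8),
    )
    ph = PhenotypeTable(pd.DataFrame({
        "accession": ["a1", "a2", "a3", "a4", "a5"],
        "sex": ["F", "F", "M", "M", "unknown"],
    }))
    tab = sex_genotype_table(g, ph, "m1")
    assert tab.columns == ("hom_a", "het")
    np.testing.assert_array_equal(tab.counts, [[0, 2], [2, 0]])
    # all unknown -> skipped
    ph_unk = PhenotypeTable(pd.DataFrame({
        "accession": ["a1", "a2", "a3", "a4", "a5"], "sex": ["unknown"] * 5}))
    assert sex_genotype_table(g, ph_unk, "m1") is None


def test_sex_genotype_table_matches_direct_tally(zw_genotypes):
    _, _, g, ph, _ = zw_genotypes
    sex = ph.sex_vector(g.accessions)
    rng = np.random.default_rng(2)
    for j in rng.choice(g.n_markers, 10, replace=False):
        mid = g.markers.index[j]
        tab = sex_genotype_table(g, ph, mid)
        codes = g.codes[:, j]
        expected = np.array([
            [int(((sex == s) & (codes == k)).sum()) for k in (0, 1, 2)]
            for s in ("F", "M")
        ])
        expected = expected[:, expected.sum(axis=0) > 0]
        np.testing.assert_array_equal(tab.counts, expected)


# ---------------------------------------------------------------------------
# kinship and structure
# ---------------------------------------------------------------------------

def test_kinship_contracts(zw_genotypes):
    _, _, g, _, truth = zw_genotypes
    auto = (truth.table.loc[g.markers.index, "class_label"] == "autosomal").to_numpy()
    gk = sl.filter_kinship_markers(g.subset_markers(auto)).genotypes
    k = compute_kinship(gk)
    v = k.values
    assert np.allclose(v, v.T)
    assert np.trace(v) / len(v) == pytest.approx(1.0)
    assert np.linalg.eigvalsh(v).min() > -1e-8
    # unrelated accessions in a panmictic population: off-diagonal ~ 0
    off = v[~np.eye(len(v), dtype=bool)]
    assert abs(off.mean()) < 0.05


def test_duplicate_accessions_have_selflike_kinship():
    rng = np.random.default_rng(3)
    codes = rng.integers(0, 3, (20, 200)).astype(np.int8)
    codes[1] = codes[0]  # two identical accessions
    g = GenotypeMatrix(
        [f"a{i}" for i in range(20)],
        pd.DataFrame({"chrom": "c1", "pos": np.arange(200) + 1,
                      "ref": "A", "alt": "C"},
                     index=pd.Index([f"m{j}" for j in range(200)], name="marker_id")),
        codes,
    )
    k = compute_kinship(g).values
    assert k[0, 1] == pytest.approx(k[0, 0])


def test_structure_components_contracts(zw_genotypes):
    _, _, g, _, _ = zw_genotypes
    q0 = structure_components(g, 0)
    assert q0.shape == (g.n_accessions, 1)
    assert np.allclose(q0, 1.0)
    q2 = structure_components(g, 2)
    gram = q2[:, 1:].T @ q2[:, 1:]
    assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)
    with pytest.raises(ValueError):
        structure_components(g, g.n_accessions)


def test_pc1_separates_divergent_subpopulations():
    cfg = SimConfig(n_accessions=120, n_autosomal=800, n_w_strict=0, n_w_partial=0,
                    n_z_poly=0, n_paralog_tags=0, n_subpops=2,
                    fst_like_divergence=0.3, mean_depth=30.0, missing_rate=0.0,
                    seed=13)
    adm, ph, _ = simulate_population(cfg)
    g = sl.filter_assoc_markers(sl.call_genotypes(adm)).genotypes
    pcs = structure_components(g, 1)
    grp = (ph.data["subpop"].to_numpy() == "1").astype(float)
    r = np.corrcoef(pcs[:, 1], grp)[0, 1]
    assert abs(r) > 0.9


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def test_mlm_identity_kinship_equals_ols(zw_genotypes):
    import statsmodels.api as sm

    _, _, g, ph, _ = zw_genotypes
    sub = g.subset_markers(list(g.markers.index[:25]))
    k = KinshipMatrix(list(sub.accessions), np.eye(sub.n_accessions))
    res = mlm_scan(sub, ph, kinship=k)
    y = (ph.sex_vector(sub.accessions) == "F").astype(float)
    dos = sub.dosage()
    for j, mid in enumerate(sub.markers.index):
        x = dos[:, j]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        if np.ptp(x) == 0:
            continue
        p_ols = sm.OLS(y, sm.add_constant(x)).fit().pvalues[1]
        assert res.loc[mid, "p_mlm"] == pytest.approx(p_ols, abs=1e-6)


def test_reml_optimum_matches_dense_grid():
    # tiny dataset: the 1-D REML profile optimised by the scan must agree
    # with a dense grid search over the variance ratio
    rng = np.random.default_rng(8)
    n = 8
    k = rng.normal(size=(n, 12))
    k = k @ k.T
    k /= np.trace(k) / n
    s, u = np.linalg.eigh(k)
    s = np.clip(s, 0, None)
    y = rng.normal(size=n)
    x = np.column_stack([np.ones(n), rng.integers(0, 3, n).astype(float)])
    ys, xs = u.T @ y, u.T @ x
    from sexlink.assoc import _optimize_delta

    opt = _optimize_delta(s, ys, xs)
    grid = np.logspace(-6, 6, 20_000)
    vals = [_reml_neg_ll(d, s, ys, xs)[0] for d in grid]
    best = grid[int(np.argmin(vals))]
    nll_opt = _reml_neg_ll(opt, s, ys, xs)[0]
    nll_best = _reml_neg_ll(best, s, ys, xs)[0]
    assert nll_opt <= nll_best + abs(nll_best) * 1e-3


def test_permuting_sex_destroys_association(zw_genotypes):
    _, _, g, ph, _ = zw_genotypes
    res = fisher_scan(g, ph).sort_values("p_fisher")
    top = list(res.index[:5])
    sub = g.subset_markers(top)
    rng = np.random.default_rng(4)
    perm_ps = []
    sexes = ph.data["sex"].to_numpy().copy()
    for _ in range(20):
        ph_perm = PhenotypeTable(
            ph.data.assign(sex=rng.permutation(sexes)))
        perm_ps.extend(fisher_scan(sub, ph_perm)["p_fisher"].tolist())
    assert np.median(perm_ps) > 0.01


def test_gwas_sex_recovers_sd_markers(zw_genotypes):
    _, _, g, ph, truth = zw_genotypes
    res, summary = gwas_sex(g, ph, run_mlm=True, n_pcs=0)
    classes = truth.table.loc[res.index, "class_label"]
    w_strict = res.index[classes == "w_strict"]
    assert res.loc[w_strict, "significant_fisher"].all()
    # fully W-linked markers outrank every autosomal marker
    worst_w = res.loc[w_strict, "rank_fisher"].max()
    best_auto = res.loc[res.index[classes == "autosomal"], "rank_fisher"].min()
    assert worst_w < best_auto
    assert summary["n_significant_both"] <= min(
        summary["n_significant_fisher"], summary["n_significant_mlm"])
    # Fisher and MLM rank the sex-linked markers concordantly
    sd = res.index[classes.isin(["w_strict", "w_partial", "paralog_collapsed"])]
    rho = stats.spearmanr(res.loc[sd, "p_fisher"], res.loc[sd, "p_mlm"]).statistic
    assert rho > 0.8
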