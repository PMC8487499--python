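"""Copy-number and collapsed-paralog diagnostics from allele-specific depth.

A well-behaved single-locus SNP ("textbook marker") shows dose-dependent
read depth: a heterozygote's allele-specific depth is about half of the
homozygote depth for the same allele, and total depth does not differ
between the sexes. Superimposed paralogous loci break both rules — the
common allele's depth stops halving in heterozygotes (the reads come
from a second, monomorphic locus), and if the extra copies are
hemizygous and sex-limited, total depth is systematically higher in the
carrier sex. Under the model "female locus count = male locus count x
depth ratio" with one shared locus, the female-to-male mean total depth
ratio minus one estimates the number of extra hemizygous copies.

Sex-level depth summaries deliberately include accessions *without* a
genotype call (a collapsed paralog can push an accession's depths out of
the callable range); genotype-conditional summaries can only use called
accessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sexlink.gbsio import (
    GENO_HET,
    GENO_HOM_ALT,
    GENO_HOM_REF,
    AlleleDepthMatrix,
    GenotypeMatrix,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)


@dataclass
class DosageParams:
    """Thresholds for the dosage diagnostics (all configurable; the
    defaults encode "about halved" as 0.5 +/- 0.15 and "clearly more
    sequence in one sex" as a >= 2-fold, Welch-significant ratio)."""

    compensation_delta: float = 0.15
    ratio_threshold: float = 2.0
    welch_alpha: float = 0.01
    depth_zscore: float = 3.0
    n_min: int = 5
    n_bootstrap: int = 200
    # Genotype-conditional summaries only use cells with at least this
    # total depth (2x the default calling threshold). Near the calling
    # threshold, heterozygotes whose binomial read split came out all one
    # allele are miscalled homozygous; these leaked cells concentrate at
    # low depth and bias the homozygote class mean downward, which would
    # fake compensation violations at GBS-typical depths. Conditioning
    # both classes on the same floor cancels out of the het/hom ratio.
    depth_floor: float = 10.0


@dataclass
class ClassStat:
    n: int
    mean: float
    sd: float


def _class_stat(values: np.ndarray) -> ClassStat:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return ClassStat(0, np.nan, np.nan)
    return ClassStat(int(v.size), float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0)


@dataclass
class DosageReport:
    """Per-marker depth summaries and copy-number diagnostics."""

    marker_id: str
    total_f: ClassStat
    total_m: ClassStat
    overall: ClassStat
    # allele-specific depth by genotype class (called accessions, sexes pooled)
    allele_by_class: dict  # {(class, allele): ClassStat}
    # per-accession total depths kept for ratio tests / bootstrap
    totals_f: np.ndarray = field(repr=False, default=None)
    totals_m: np.ndarray = field(repr=False, default=None)
    # filled by the diagnostic operations
    sex_depth_ratio: float = np.nan
    male_null: bool = False
    ratio_elevated: bool | None = None
    ratio_p: float = np.nan
    compensation_ratios: dict = field(default_factory=dict)
    compensation_p: dict = field(default_factory=dict)
    dose_compensated: bool | None = None
    compensation_violated: bool | None = None
    extra_copy_estimate: float = np.nan
    extra_copy_ci: tuple = (np.nan, np.nan)
    paralog_suspect: bool = False
    flag_reasons: list = field(default_factory=list)


def depth_summary(
    adm: AlleleDepthMatrix,
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    marker_id: str,
    params: DosageParams | None = None,
) -> DosageReport:
    """Depth summaries for one marker.

    Sex-level total-depth statistics include every accession of that sex
    (called or not); genotype-conditional allele-specific statistics use
    called accessions only, and only cells with total depth at least
    ``params.depth_floor`` (see :class:`DosageParams` for why).
    """
    p = params or DosageParams()
    j = adm.markers.index.get_loc(marker_id)
    ref_d = adm.depths[:, j, 0].astype(float)
    alt_d = adm.depths[:, j, 1].astype(float)
    total = ref_d + alt_d
    sex = ph.sex_vector(adm.accessions)
    totals_f = total[sex == "F"]
    totals_m = total[sex == "M"]
    if totals_f.size == 0 or totals_m.size == 0:
        logger.warning("marker %s: a sex has zero accessions; its summary omitted",
                       marker_id)
    codes = g.codes[:, j]
    deep = total >= p.depth_floor
    by_class = {}
    for cls_label, code in (("hom_ref", GENO_HOM_REF), ("het", GENO_HET),
                            ("hom_alt", GENO_HOM_ALT)):
        in_cls = (codes == code) & deep
        by_class[(cls_label, "ref")] = _class_stat(ref_d[in_cls])
        by_class[(cls_label, "alt")] = _class_stat(alt_d[in_cls])
    return DosageReport(
        marker_id=marker_id,
        total_f=_class_stat(totals_f),
        total_m=_class_stat(totals_m),
        overall=_class_stat(total),
        allele_by_class=by_class,
        totals_f=totals_f,
        totals_m=totals_m,
    )


def compensation_test(
    report: DosageReport, params: DosageParams | None = None
) -> DosageReport:
    """Heterozygote/homozygote allele-depth compensation ratios.

    For each allele with at least ``n_min`` heterozygotes and ``n_min``
    same-allele homozygotes, ratio = mean het allele depth / mean hom
    allele depth. ``dose_compensated`` is True when every testable ratio
    lies in [0.5 - delta, 0.5 + delta]; ``compensation_violated`` is the
    statistically guarded opposite — some testable ratio falls outside
    the band *and* a one-sided Welch test places the het mean beyond the
    nearest band edge (edge x hom mean) at ``welch_alpha``. Testing
    against the edge rather than against 0.5 means sampling noise around
    a true ratio of one half cannot produce a violation, however many
    markers are screened.
    """
    from scipy import stats as sps

    p = params or DosageParams()
    ratios: dict[str, float] = {}
    pvals: dict[str, float] = {}
    lo, hi = 0.5 - p.compensation_delta, 0.5 + p.compensation_delta
    for allele, hom_cls in (("ref", "hom_ref"), ("alt", "hom_alt")):
        het = report.allele_by_class[("het", allele)]
        hom = report.allele_by_class[(hom_cls, allele)]
        if het.n < p.n_min or hom.n < p.n_min or hom.mean == 0:
            continue
        r = het.mean / hom.mean
        ratios[allele] = r
        edge = hi if r > 0.5 else lo
        v1 = het.sd**2 / het.n
        v2 = (edge * hom.sd) ** 2 / hom.n
        if v1 + v2 == 0:
            pvals[allele] = 0.0 if (r < lo or r > hi) else 1.0
            continue
        t = (het.mean - edge * hom.mean) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (het.n - 1) + v2**2 / (hom.n - 1))
        pvals[allele] = float(sps.t.sf(abs(t), df))  # one-sided, toward exceedance
    report.compensation_ratios = ratios
    report.compensation_p = pvals
    if not ratios:
        report.dose_compensated = None
        report.compensation_violated = None
        return report
    in_band = {a: lo <= r <= hi for a, r in ratios.items()}
    report.dose_compensated = all(in_band.values())
    report.compensation_violated = any(
        (not in_band[a]) and (pvals[a] < p.welch_alpha) for a in ratios
    )
    return report


def sex_depth_ratio(
    report: DosageReport, params: DosageParams | None = None
) -> DosageReport:
    """Female/male mean total depth ratio with a Welch guard.

    ``ratio_elevated`` requires the ratio to reach ``ratio_threshold``
    *and* the Welch two-sample test on per-accession totals to reject
    equal means at ``welch_alpha``. A zero male mean leaves the ratio
    undefined and sets ``male_null`` instead.
    """
    from scipy import stats as sps

    p = params or DosageParams()
    if report.total_m.n == 0 or report.total_f.n == 0:
        report.ratio_elevated = None
        return report
    if report.total_m.mean == 0:
        report.male_null = True
        report.ratio_elevated = None
        return report
    report.sex_depth_ratio = report.total_f.mean / report.total_m.mean
    if report.totals_f is not None and min(report.total_f.n, report.total_m.n) > 1:
        w = sps.ttest_ind(report.totals_f, report.totals_m, equal_var=False)
        report.ratio_p = float(w.pvalue)
    report.ratio_elevated = bool(
        report.sex_depth_ratio >= p.ratio_threshold
        and np.isfinite(report.ratio_p)
        and report.ratio_p < p.welch_alpha
    )
    return report


def estimate_extra_copies(
    report: DosageReport,
    params: DosageParams | None = None,
    seed: int | None = 0,
) -> DosageReport:
    """Extra hemizygous copy number from the sex depth ratio.

    Model: males carry one locus, females carry ``ratio`` loci, so the
    estimate is ratio - 1 (floored at 0 with a note when the ratio dips
    below 1). A seeded bootstrap over accessions within each sex gives a
    percentile interval.
    """
    p = params or DosageParams()
    if not np.isfinite(report.sex_depth_ratio):
        return report
    est = report.sex_depth_ratio - 1.0
    if est < 0:
        logger.info("marker %s: depth ratio < 1; extra-copy estimate floored at 0",
                    report.marker_id)
        est = 0.0
    report.extra_copy_estimate = float(est)
    if report.totals_f is not None and report.totals_m is not None and p.n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        nf, nm = len(report.totals_f), len(report.totals_m)
        if nf and nm:
            bf = report.totals_f[rng.integers(0, nf, (p.n_bootstrap, nf))].mean(axis=1)
            bm = report.totals_m[rng.integers(0, nm, (p.n_bootstrap, nm))].mean(axis=1)
            ok = bm > 0
            if ok.any():
                boots = np.clip(bf[ok] / bm[ok] - 1.0, 0.0, None)
                report.extra_copy_ci = (
                    float(np.percentile(boots, 2.5)),
                    float(np.percentile(boots, 97.5)),
                )
    return report


def analyze_marker(
    adm: AlleleDepthMatrix,
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    marker_id: str,
    params: DosageParams | None = None,
    seed: int | None = 0,
) -> DosageReport:
    """Full dosage diagnostic chain for one marker."""
    report = depth_summary(adm, g, ph, marker_id, params)
    compensation_test(report, params)
    sex_depth_ratio(report, params)
    estimate_extra_copies(report, params, seed=seed)
    return report


def textbook_depth_stats(reports: list[DosageReport]) -> ClassStat:
    """Distribution of per-marker mean total depth over a textbook set."""
    means = np.array([r.overall.mean for r in reports if r.overall.n > 0])
    return _class_stat(means)


def flag_paralog_suspects(
    reports: list[DosageReport],
    textbook_reference: ClassStat | None,
    params: DosageParams | None = None,
) -> list[str]:
    """Flag markers whose depths look like superimposed paralogous loci.

    A marker is suspect if its compensation pattern is violated, its
    female/male depth ratio is elevated, or its mean total depth is an
    outlier (z > ``depth_zscore``) against the textbook-marker depth
    distribution. Reasons are recorded on each report. Without a
    textbook reference the depth-outlier rule is skipped.
    """
    p = params or DosageParams()
    flagged = []
    for rep in reports:
        reasons = []
        if rep.compensation_violated:
            reasons.append("compensation_violated")
        if rep.ratio_elevated:
            reasons.append("ratio_elevated")
        if rep.male_null:
            reasons.append("male_null_depth")
        if (
            textbook_reference is not None
            and textbook_reference.n > 1
            and textbook_reference.sd > 0
            and rep.overall.n > 0
        ):
            z = (rep.overall.mean - textbook_reference.mean) / textbook_reference.sd
            if z > p.depth_zscore:
                reasons.append("depth_outlier")
        rep.flag_reasons = reasons
        rep.paralog_suspect = bool(reasons)
        if reasons:
            flagged.append(rep.marker_id)
    return flagged


def depth_histogram(
    adm: AlleleDepthMatrix,
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    marker_id: str,
    bin_width: int = 10,
):
    """Accession counts per allele-specific read-depth class (bins
    ``bin_width`` reads wide), split by called genotype and by sex —
    the tabular form of the usual depth-distribution figure.

    Returns a DataFrame with columns group, allele, bin_low, count.
    """
    import pandas as pd

    j = adm.markers.index.get_loc(marker_id)
    sex = ph.sex_vector(adm.accessions)
    codes = g.codes[:, j]
    groups = {
        "F": sex == "F",
        "M": sex == "M",
        "hom_ref": codes == GENO_HOM_REF,
        "het": codes == GENO_HET,
        "hom_alt": codes == GENO_HOM_ALT,
    }
    rows = []
    for gname, mask in groups.items():
        for ai, allele in enumerate(("ref", "alt")):
            depths = adm.depths[mask, j, ai]
            if depths.size == 0:
                continue
            bins = (depths // bin_width) * bin_width
            for b in np.unique(bins):
                rows.append((gname, allele, int(b), int((bins == b).sum())))
    return pd.DataFrame(rows, columns=["group", "allele", "bin_low", "count"])
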