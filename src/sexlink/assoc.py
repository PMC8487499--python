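"""Genome-wide association of sex: exact contingency tests and mixed model.

Two complementary scans are provided. The primary scan tests, per
marker, independence of genotype class and sex with the Freeman-Halton
exact test (the r x c generalisation of Fisher's exact test), computed
in log space so that p-values far below float underflow of the naive
product form (e.g. 1e-70) remain representable. The second scan fits a
single-marker Gaussian mixed linear model with sex coded 0/1 as the
response, fixed structure covariates, and a random polygenic term with
covariance proportional to a kinship matrix; the variance ratio is
re-estimated by REML for every marker using one spectral decomposition
of the kinship matrix (EMMA-style exact scan, no P3D approximation).
Both scans are controlled for multiple testing with the Bonferroni
bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from sexlink.gbsio import (
    GENO_HET,
    GENO_HOM_ALT,
    GENO_HOM_REF,
    GenotypeMatrix,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

GENOTYPE_CLASS_LABELS = ("hom_a", "het", "hom_b")

# log-factorial lookup, grown on demand
_LOGFACT = gammaln(np.arange(1024) + 1.0)


def _logfact(n: int) -> np.ndarray:
    global _LOGFACT
    if n >= len(_LOGFACT):
        _LOGFACT = gammaln(np.arange(2 * n + 1) + 1.0)
    return _LOGFACT


@dataclass
class ContingencyTable:
    """Sex (rows F, M) by genotype-class counts for one marker."""

    marker_id: str
    counts: np.ndarray  # shape (2, k)
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("contingency table must have two rows (F, M)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def sex_genotype_table(
    g: GenotypeMatrix, ph: PhenotypeTable, marker_id: str
) -> ContingencyTable | None:
    """Tally genotype classes by sex for one marker.

    Unknown-sex and missing-genotype accessions are excluded and empty
    genotype columns dropped. Returns None (with a log entry) if no
    sexed accession has a call.
    """
    j = g.markers.index.get_loc(marker_id)
    sex = ph.sex_vector(g.accessions)
    codes = g.codes[:, j]
    counts = np.zeros((2, 3), dtype=np.int64)
    for row, s in enumerate(("F", "M")):
        in_sex = sex == s
        for col, geno in enumerate((GENO_HOM_REF, GENO_HET, GENO_HOM_ALT)):
            counts[row, col] = int(np.sum(in_sex & (codes == geno)))
    keep = counts.sum(axis=0) > 0
    if counts.sum() == 0:
        logger.info("marker %s skipped: no sexed, genotyped accessions", marker_id)
        return None
    labels = tuple(np.array(GENOTYPE_CLASS_LABELS)[keep])
    return ContingencyTable(marker_id, counts[:, keep], labels)


def fisher_exact_rc(table) -> float:
    """Freeman-Halton exact p-value for a 2 x c table (c = 2 or 3).

    Sums, over all tables with the observed margins, the hypergeometric
    point probabilities no greater than that of the observed table. The
    comparison uses a relative tolerance of 1e-12 in log space so that
    exactly tied tables are never excluded by floating-point error.
    Degenerate tables (a zero row or column margin after dropping empty
    columns) return p = 1 by convention.
    """
    t = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x c table")
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return 1.0
    if t.shape[1] > 3:
        raise ValueError("only 2 or 3 genotype-class columns are supported")
    r = t.sum(axis=1)
    c = np.sort(t.sum(axis=0))[::-1]  # largest column last in the free grid
    order = np.argsort(t.sum(axis=0))[::-1]
    t = t[:, order]
    n = int(r.sum())
    lf = _logfact(n)
    const = lf[r].sum() + lf[c].sum() - lf[n]
    logp_obs = const - lf[t].sum()

    r0 = int(r[0])
    if t.shape[1] == 2:
        c0, c1 = int(c[0]), int(c[1])
        a = np.arange(max(0, r0 - c1), min(r0, c0) + 1)
        logps = const - (lf[a] + lf[r0 - a] + lf[c0 - a] + lf[c1 - r0 + a])
    else:
        c0, c1, c2 = int(c[0]), int(c[1]), int(c[2])
        # free cells: top row of the two smaller columns
        a = np.arange(min(r0, c1) + 1)[:, None]
        b = np.arange(min(r0, c2) + 1)[None, :]
        d = r0 - a - b  # top cell of the largest column
        valid = (d >= 0) & (d <= c0)
        with np.errstate(invalid="ignore"):
            dd = np.where(valid, d, 0)
            logps = const - (
                lf[dd] + lf[a] + lf[b] + lf[c0 - dd] + lf[c1 - a] + lf[c2 - b]
            )
        logps = logps[valid]
    # 2 x 3 free grid above indexes columns (c1, c2) with c0 absorbed; for
    # the 2 x 2 branch columns are (c0, c1). Point-probability comparison:
    qualifying = logps <= logp_obs + 1e-12 * (1.0 + np.abs(logp_obs))
    return float(min(1.0, np.exp(logsumexp(logps[qualifying]))))


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Kinship and structure
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    accessions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.accessions),) * 2:
            raise ValueError("kinship matrix must be square over the accessions")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = v


def _imputed_centered_dosage(g: GenotypeMatrix) -> np.ndarray:
    """Dosage matrix with per-marker mean imputation of missing cells,
    then column centering. Used for kinship and structure only."""
    d = g.dosage()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    return d - d.mean(axis=0)


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Realised-relationship (VanRaden-style) kinship from centered dosages.

    K = Z Z' / s, rescaled so the mean diagonal equals 1. Missing
    dosages are mean-imputed for this computation only. The cross
    product is positive semidefinite by construction; `bend_psd` is
    available to clip any numerically negative eigenvalues.
    """
    if g.n_markers < 2:
        raise ValueError("need at least 2 markers to estimate kinship")
    z = _imputed_centered_dosage(g)
    k = z @ z.T
    mean_diag = np.trace(k) / k.shape[0]
    if mean_diag <= 0:
        raise ValueError("degenerate genotype matrix: zero variance everywhere")
    return KinshipMatrix(list(g.accessions), k / mean_diag)


def bend_psd(k: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues so the matrix is positive semidefinite."""
    w, v = np.linalg.eigh(k)
    if w.min() >= floor:
        return k
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


def structure_components(g: GenotypeMatrix, q: int = 2) -> np.ndarray:
    """Intercept plus the top-q principal components of centered dosages.

    Returns an (n_accessions, q + 1) covariate matrix whose first column
    is constant; q = 0 gives the intercept only.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    n = g.n_accessions
    if q >= n:
        raise ValueError("q must be smaller than the number of accessions")
    cols = [np.ones(n)]
    if q > 0:
        z = _imputed_centered_dosage(g)
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        cols.extend(u[:, i] * s[i] for i in range(q))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Mixed linear model scan
# ---------------------------------------------------------------------------

def _reml_neg_ll(delta: float, s: np.ndarray, ys: np.ndarray, xs: np.ndarray):
    """Negative REML log-likelihood (up to constants) of the variance
    ratio delta = sigma_e^2 / sigma_g^2 in the eigenbasis of K."""
    w = 1.0 / (s + delta)
    xtw = xs.T * w
    a = xtw @ xs
    try:
        beta = np.linalg.solve(a, xtw @ ys)
    except np.linalg.LinAlgError:
        return np.inf, None
    resid = ys - xs @ beta
    rss = float(w @ resid**2)
    if rss <= 0:
        return np.inf, None
    n, p = xs.shape
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return np.inf, None
    nll = 0.5 * ((n - p) * np.log(rss) + np.sum(np.log(s + delta)) + logdet_a)
    return nll, (beta, a, rss)


def _optimize_delta(s, ys, xs, grid=None):
    """Bracketed log-grid search followed by golden-section refinement."""
    if grid is None:
        grid = np.logspace(-5, 5, 61)
    vals = np.array([_reml_neg_ll(d, s, ys, xs)[0] for d in grid])
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    # golden section on log(delta)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = np.log(lo), np.log(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _reml_neg_ll(np.exp(c), s, ys, xs)[0]
    fd = _reml_neg_ll(np.exp(d), s, ys, xs)[0]
    for _ in range(60):
        if b - a < 1e-10:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _reml_neg_ll(np.exp(c), s, ys, xs)[0]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _reml_neg_ll(np.exp(d), s, ys, xs)[0]
    return float(np.exp((a + b) / 2.0))


def mlm_scan(
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    kinship: KinshipMatrix | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-marker mixed-model scan of sex (coded F=1, M=0).

    Model per marker: y = Q gamma + x beta + u + e with
    u ~ N(0, sigma_g^2 K) and e ~ N(0, sigma_e^2 I). The variance ratio
    is re-estimated by REML for every marker (1-D optimisation after one
    spectral decomposition of K); significance of beta is assessed with
    an F test on 1 and n - p denominator degrees of freedom. Missing
    marker dosages are mean-imputed for the scan; markers whose design
    becomes singular (e.g. monomorphic) are skipped with NaN p.

    Returns a DataFrame indexed by marker id with columns
    ``p_mlm, beta, delta``.
    """
    sex = ph.sex_vector(g.accessions)
    keep = sex != "unknown"
    if keep.sum() < 3:
        raise ValueError("need at least 3 sexed accessions for the MLM scan")
    y = (sex[keep] == "F").astype(float)
    if kinship is None:
        kinship = compute_kinship(g)
    if list(kinship.accessions) != list(g.accessions):
        raise ValueError("kinship matrix is over different accessions")
    k = kinship.values[np.ix_(keep, keep)]
    if covariates is None:
        covariates = np.ones((g.n_accessions, 1))
    q = np.asarray(covariates, dtype=float)[keep]

    s, u = np.linalg.eigh(bend_psd(k))
    s = np.clip(s, 0.0, None)
    ys = u.T @ y
    qs = u.T @ q

    dos = g.dosage()[keep]
    col_mean = np.nanmean(dos, axis=0)
    out = np.full((g.n_markers, 3), np.nan)
    n = int(keep.sum())
    for j in range(g.n_markers):
        x = dos[:, j]
        miss = np.isnan(x)
        if miss.all():
            continue
        if miss.any():
            x = np.where(miss, col_mean[j], x)
        if np.ptp(x) == 0:
            logger.debug("marker %s skipped: constant dosage", g.markers.index[j])
            continue
        xs = np.column_stack([qs, u.T @ x])
        delta = _optimize_delta(s, ys, xs)
        nll, aux = _reml_neg_ll(delta, s, ys, xs)
        if aux is None:
            continue
        beta, a, rss = aux
        p_fixed = xs.shape[1]
        sigma2 = rss / (n - p_fixed)
        cov = sigma2 * np.linalg.inv(a)
        f_stat = beta[-1] ** 2 / cov[-1, -1]
        p_val = float(stats.f.sf(f_stat, 1, n - p_fixed))
        out[j] = (p_val, beta[-1], delta)
    return pd.DataFrame(out, index=g.markers.index, columns=["p_mlm", "beta", "delta"])


# ---------------------------------------------------------------------------
# Combined scan
# ---------------------------------------------------------------------------

def _genotype_sex_counts(g: GenotypeMatrix, ph: PhenotypeTable) -> np.ndarray:
    """Counts (2 sexes x 3 genotype classes x markers) in one pass."""
    sex = ph.sex_vector(g.accessions)
    counts = np.zeros((2, 3, g.n_markers), dtype=np.int64)
    for row, s_lab in enumerate(("F", "M")):
        rows = g.codes[sex == s_lab]
        for col, geno in enumerate((GENO_HOM_REF, GENO_HET, GENO_HOM_ALT)):
            counts[row, col] = (rows == geno).sum(axis=0)
    return counts


def fisher_scan(g: GenotypeMatrix, ph: PhenotypeTable) -> pd.DataFrame:
    """Exact genotype-by-sex independence test for every marker."""
    counts = _genotype_sex_counts(g, ph)
    p = np.ones(g.n_markers)
    for j in range(g.n_markers):
        t = counts[:, :, j]
        t = t[:, t.sum(axis=0) > 0]
        p[j] = fisher_exact_rc(t) if t.size else 1.0
    df = pd.DataFrame({"p_fisher": p}, index=g.markers.index)
    for row, s_lab in enumerate(("F", "M")):
        for col, lab in enumerate(GENOTYPE_CLASS_LABELS):
            df[f"n_{s_lab}_{lab}"] = counts[row, col]
    return df


def gwas_sex(
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    alpha: float = 0.05,
    run_mlm: bool = True,
    n_pcs: int = 2,
    kinship: KinshipMatrix | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the exact-test scan and (optionally) the MLM scan.

    Returns a per-marker result table sorted by exact-test p, plus a
    summary dict with significant-marker counts per method and their
    intersection. Note: genotype counts in the table are oriented to the
    VCF REF/ALT alleles; hom_a/hom_b orientation by rarity is applied by
    the segregation module.
    """
    res = fisher_scan(g, ph)
    res.insert(0, "pos", g.markers["pos"].to_numpy())
    res.insert(0, "chrom", g.markers["chrom"].to_numpy())
    m = g.n_markers
    thr = bonferroni_threshold(m, alpha)
    res["significant_fisher"] = res["p_fisher"] < thr
    if run_mlm:
        cov = structure_components(g, n_pcs) if n_pcs > 0 else None
        mlm = mlm_scan(g, ph, kinship=kinship, covariates=cov)
        res["p_mlm"] = mlm["p_mlm"]
        res["significant_mlm"] = res["p_mlm"] < thr
    res["rank_fisher"] = res["p_fisher"].rank(method="first").astype(int)
    res = res.sort_values("p_fisher")
    summary = {
        "n_markers": int(m),
        "alpha": alpha,
        "bonferroni_threshold": thr,
        "n_significant_fisher": int(res["significant_fisher"].sum()),
    }
    if run_mlm:
        summary["n_significant_mlm"] = int(res["significant_mlm"].sum())
        summary["n_significant_both"] = int(
            (res["significant_fisher"] & res["significant_mlm"]).sum()
        )
    return res, summary
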