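"""Heterogamety-diagnostic classification of sex-associated markers.

In a female-heterogametic (ZW) system, an allele on the W chromosome
appears only in females and mostly in heterozygotes, while a Z-linked
polymorphism allows males (ZZ) to be homozygous for the rare allele but
never females (ZW). Counting which pattern dominates among the
significant markers — and whether its mirror image appears when the sex
labels are swapped — determines the heterogametic sex by majority vote.

Alleles are oriented per marker so that ``b`` is the rarer allele among
all called genotypes; the orientation is a function of the genotype
counts only and is therefore consistent across operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from sexlink.gbsio import (
    GENO_HET,
    GENO_HOM_ALT,
    GENO_HOM_REF,
    GENO_MISSING,
    GenotypeMatrix,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

CLASS_LABELS = ("w_strict", "w_loose", "z_poly", "ambiguous")


@dataclass
class SegThresholds:
    """Classification cutoffs (the analysis exposes these because the
    verbal categories "entirely"/"almost entirely" need numbers).

    tau_m : max fraction of males carrying b for a loose W link
    tau_delta : min female-minus-male excess in b-carrier fraction
    tau_z : min fraction of hom-b males for a Z-polymorphism call
    min_carrier_f : min fraction of females carrying b for a strict W link
    """

    tau_m: float = 0.05
    tau_delta: float = 0.3
    tau_z: float = 0.1
    min_carrier_f: float = 0.5


@dataclass
class SegregationProfile:
    """Sex-by-genotype counts with b-allele (rare-allele) orientation."""

    marker_id: str
    counts: np.ndarray  # (2, 3): rows F, M; cols hom_a, het, hom_b
    b_is_alt: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 3):
            raise ValueError("profile counts must be 2 (sex) x 3 (genotype)")

    @property
    def n_f(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n_m(self) -> int:
        return int(self.counts[1].sum())

    def _freqs(self, row: int) -> tuple[float, float, float]:
        tot = self.counts[row].sum()
        if tot == 0:
            return (np.nan, np.nan, np.nan)
        carrier = (self.counts[row, 1] + self.counts[row, 2]) / tot
        het = self.counts[row, 1] / tot
        homb = self.counts[row, 2] / tot
        return (carrier, het, homb)

    @property
    def b_carrier_freq_f(self) -> float:
        return self._freqs(0)[0]

    @property
    def b_carrier_freq_m(self) -> float:
        return self._freqs(1)[0]

    @property
    def het_freq_f(self) -> float:
        return self._freqs(0)[1]

    @property
    def het_freq_m(self) -> float:
        return self._freqs(1)[1]

    @property
    def homb_freq_f(self) -> float:
        return self._freqs(0)[2]

    @property
    def homb_freq_m(self) -> float:
        return self._freqs(1)[2]

    def swapped(self) -> "SegregationProfile":
        """The same counts with the sex rows exchanged."""
        return SegregationProfile(self.marker_id, self.counts[::-1], self.b_is_alt)


def segregation_profile(
    g: GenotypeMatrix, ph: PhenotypeTable, marker_id: str
) -> SegregationProfile:
    """Build the per-sex genotype profile of a marker, orienting alleles
    so that b is the rarer allele among all called genotypes (ties keep
    the ALT allele as b)."""
    j = g.markers.index.get_loc(marker_id)
    codes = g.codes[:, j]
    sex = ph.sex_vector(g.accessions)
    called = codes != GENO_MISSING
    alt_count = int(codes[called].sum())
    total = 2 * int(called.sum())
    b_is_alt = alt_count <= total - alt_count
    counts = np.zeros((2, 3), dtype=np.int64)
    col_order = (
        (GENO_HOM_REF, GENO_HET, GENO_HOM_ALT)
        if b_is_alt
        else (GENO_HOM_ALT, GENO_HET, GENO_HOM_REF)
    )
    for row, s_lab in enumerate(("F", "M")):
        mask = (sex == s_lab) & called
        for col, geno in enumerate(col_order):
            counts[row, col] = int(np.sum(codes[mask] == geno))
    return SegregationProfile(marker_id, counts, b_is_alt)


def classify_segregation(
    profile: SegregationProfile, thresholds: SegThresholds | None = None
) -> str:
    """Assign a heterogamety-diagnostic class to one marker profile.

    - ``w_strict``: no male carries b and at least ``min_carrier_f`` of
      females do (b fully confined to W haplotypes).
    - ``w_loose``: male b-carrier fraction <= tau_m and females exceed
      males by >= tau_delta (rare leakage, e.g. Z-W recombination or
      genotyping error).
    - ``z_poly``: hom-b males at frequency >= tau_z while females are
      (nearly) never hom-b (the polymorphism lives on the Z).
    - otherwise ``ambiguous``.
    """
    th = thresholds or SegThresholds()
    if profile.n_f == 0 or profile.n_m == 0:
        logger.warning("marker %s: one sex entirely missing", profile.marker_id)
        return "ambiguous"
    cf, cm = profile.b_carrier_freq_f, profile.b_carrier_freq_m
    if cm == 0.0 and cf >= th.min_carrier_f:
        return "w_strict"
    if cm <= th.tau_m and (cf - cm) >= th.tau_delta:
        return "w_loose"
    if profile.homb_freq_m >= th.tau_z and profile.homb_freq_f <= th.tau_m:
        return "z_poly"
    return "ambiguous"


@dataclass
class HeterogametyCall:
    verdict: str  # female_heterogametic / male_heterogametic / undetermined
    support: float
    votes_female: int
    votes_male: int
    n_profiles: int


def infer_heterogamety(
    profiles: Iterable[SegregationProfile],
    thresholds: SegThresholds | None = None,
) -> HeterogametyCall:
    """Majority vote over classified significant markers.

    A marker votes female-heterogametic when its profile (as observed)
    falls in a W/Z diagnostic class, and male-heterogametic when the
    sex-swapped profile does — i.e. the same patterns with the roles of
    the sexes mirrored. Support is the winning vote count over the
    number of profiles considered. Invariant under marker order and
    under allele relabelling (profiles orient b by rarity).
    """
    profiles = list(profiles)
    votes_f = votes_m = 0
    for prof in profiles:
        if classify_segregation(prof, thresholds) != "ambiguous":
            votes_f += 1
        elif classify_segregation(prof.swapped(), thresholds) != "ambiguous":
            votes_m += 1
    n = len(profiles)
    if votes_f == votes_m:
        return HeterogametyCall("undetermined", 0.0, votes_f, votes_m, n)
    verdict = "female_heterogametic" if votes_f > votes_m else "male_heterogametic"
    return HeterogametyCall(verdict, max(votes_f, votes_m) / n, votes_f, votes_m, n)


def hwe_chisq(counts) -> tuple[float, float]:
    """One-d.f. chi-square test of Hardy-Weinberg proportions.

    ``counts`` are genotype counts (hom_a, het, hom_b); expectations use
    the observed allele frequencies. A monomorphic marker returns
    (0, 1). The statistic is invariant under allele relabelling.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,) or (c < 0).any():
        raise ValueError("expected three non-negative genotype counts")
    n = c.sum()
    if n == 0:
        return 0.0, 1.0
    p = (2 * c[0] + c[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    stat = float(np.sum((c - expected) ** 2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))


def identify_textbook_markers(
    g: GenotypeMatrix,
    min_maf: float = 0.05,
    hwe_alpha: float = 0.05,
    min_call_rate: float = 1.0,
) -> list[str]:
    """Markers behaving like single-locus SNPs: fully called (100 %
    completeness by default), MAF > ``min_maf``, and consistent with
    Hardy-Weinberg proportions (pooled sexes, chi-square p > alpha).
    These serve as the reference class for read-depth dosage diagnostics.
    """
    call_rate = g.call_rate()
    maf = g.maf()
    out: list[str] = []
    for j in np.flatnonzero((call_rate >= min_call_rate) & (maf > min_maf)):
        codes = g.codes[:, j]
        counts = [
            int((codes == GENO_HOM_REF).sum()),
            int((codes == GENO_HET).sum()),
            int((codes == GENO_HOM_ALT).sum()),
        ]
        _, p = hwe_chisq(counts)
        if p > hwe_alpha:
            out.append(g.markers.index[j])
    if not out:
        logger.warning("no textbook markers found; dosage comparisons will "
                       "need fallback thresholds")
    return out
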