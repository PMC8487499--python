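"""Synthetic ZW/XY populations with GBS-like allele depths and ground truth.

The generator emulates a wild, dioecious association-mapping population
genotyped by GBS: ~265 accessions with a ~60/40 female/male split, ~20k
biallelic tag markers with per-allele read counts, a sex-determining
region carrying fully and partially W-linked alleles, Z-polymorphic
markers, and collapsed-paralog tags where females carry extra hemizygous
W copies of an autosomal fragment so that reads from all copies
superimpose onto a single marker.

Read depth per *locus copy* follows a negative binomial with mean
``mean_depth`` and size ``depth_dispersion`` (Poisson in the limit of
infinite dispersion); at an ordinary diploid locus the two haplotypes
share one locus draw, split binomially between alleles, whereas each
hemizygous W copy of a collapsed paralog is an independent tag locus
contributing a full draw. This makes the expected total depth of a
paralog tag (1 + k) * mean_depth in carriers of k extra copies versus
mean_depth in non-carriers, the signal the dosage module exploits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from sexlink.gbsio import (
    GENO_HOM_REF,
    AlleleDepthMatrix,
    GenotypeMatrix,
    PhenotypeTable,
)

MARKER_CLASSES = ("autosomal", "w_strict", "w_partial", "z_poly", "paralog_collapsed")


class SimConfigError(ValueError):
    """Invalid simulator configuration; the message names the field."""


@dataclass
class SimConfig:
    """Free parameters of the population simulator.

    Defaults emulate the study design this generator was built around:
    265 accessions, 61 % female, ~19.6k biallelic markers of which 18
    are strictly W-linked, 17 partially W-linked, 2 Z-polymorphic and 2
    are collapsed paralog tags with two extra hemizygous W copies in
    females.
    """

    n_accessions: int = 265
    female_fraction: float = 162 / 265
    n_autosomal: int = 19_553
    n_w_strict: int = 18
    n_w_partial: int = 17
    n_z_poly: int = 2
    n_paralog_tags: int = 2
    extra_w_copies: int = 2
    mean_depth: float = 20.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.01
    missing_rate: float = 0.05
    n_subpops: int = 1
    fst_like_divergence: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    w_partial_fraction: float = 0.6
    unknown_sex_rate: float = 0.0
    heterogametic_sex: Literal["F", "M"] = "F"
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_accessions": self.n_accessions,
            "n_autosomal": self.n_autosomal,
            "n_w_strict": self.n_w_strict,
            "n_w_partial": self.n_w_partial,
            "n_z_poly": self.n_z_poly,
            "n_paralog_tags": self.n_paralog_tags,
            "n_subpops": self.n_subpops,
        }
        for name, v in counts.items():
            if int(v) != v or v < 0:
                raise SimConfigError(f"{name} must be a non-negative integer")
        if self.n_accessions < 2:
            raise SimConfigError("n_accessions must be >= 2")
        if not 0.0 < self.female_fraction < 1.0:
            raise SimConfigError("female_fraction must lie in (0, 1)")
        if self.female_fraction * self.n_accessions < 1:
            raise SimConfigError("female_fraction * n_accessions must be >= 1")
        if self.n_subpops < 1:
            raise SimConfigError("n_subpops must be >= 1")
        if self.extra_w_copies < 1:
            raise SimConfigError("extra_w_copies must be >= 1")
        if not self.mean_depth > 0:
            raise SimConfigError("mean_depth must be > 0")
        if not self.depth_dispersion > 0:
            raise SimConfigError("depth_dispersion must be > 0")
        if not 0.0 < self.error_rate < 0.5:
            raise SimConfigError("error_rate must lie in (0, 0.5)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.fst_like_divergence < 1.0:
            raise SimConfigError("fst_like_divergence must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 < self.w_partial_fraction <= 1.0:
            raise SimConfigError("w_partial_fraction must lie in (0, 1]")
        if not 0.0 <= self.unknown_sex_rate < 1.0:
            raise SimConfigError("unknown_sex_rate must lie in [0, 1)")
        if self.heterogametic_sex not in ("F", "M"):
            raise SimConfigError("heterogametic_sex must be 'F' or 'M'")

    @property
    def n_markers(self) -> int:
        return (
            self.n_autosomal
            + self.n_w_strict
            + self.n_w_partial
            + self.n_z_poly
            + self.n_paralog_tags
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated population.

    ``table`` has one row per marker (class label, which allele rides
    the sex-limited chromosome, true extra hemizygous copy number,
    per-subpopulation allele frequencies). ``true_genotypes`` holds the
    underlying single-locus genotypes before depth sampling, read error
    and missingness; for collapsed-paralog tags it is the genotype of
    the shared base locus (hom for the common allele in every
    accession), since the apparent heterozygosity of carriers is an
    artifact of superimposed copies rather than a diploid genotype.
    """

    table: pd.DataFrame
    true_genotypes: GenotypeMatrix = field(repr=False)

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["subpop_freqs"] = [
            ",".join(f"{x:.6g}" for x in row) for row in df["subpop_freqs"]
        ]
        df.to_csv(path, sep="\t", index=True, index_label="marker_id")


def _nb_draw(rng: np.random.Generator, mean, size_param: float, shape) -> np.ndarray:
    """Negative binomial with given mean and size; Poisson if size is inf."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), shape)
    if not np.isfinite(size_param):
        return rng.poisson(mean)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_population(
    config: SimConfig,
) -> tuple[AlleleDepthMatrix, PhenotypeTable, SimTruth]:
    """Simulate a dioecious population with GBS-like allele depths.

    Identical configs (including seed) produce identical output. At
    least one accession of each sex is guaranteed (the Bernoulli sex
    draw is patched if degenerate, so tiny test populations always
    support sex-contrast analyses).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions
    accessions = [f"ACC{i + 1:05d}" for i in range(n)]

    is_female = rng.random(n) < config.female_fraction
    if not is_female.any():
        is_female[0] = True
    if is_female.all():
        is_female[-1] = False
    # carriers of the sex-limited chromosome (W in a ZW system, Y in XY)
    is_het_sex = is_female if config.heterogametic_sex == "F" else ~is_female

    subpop = rng.integers(0, config.n_subpops, n)

    m_auto, m_ws, m_wp, m_zp, m_par = (
        config.n_autosomal,
        config.n_w_strict,
        config.n_w_partial,
        config.n_z_poly,
        config.n_paralog_tags,
    )
    m_total = config.n_markers

    dosage = np.zeros((n, m_total), dtype=np.int8)  # ALT copies at the base locus
    class_labels = np.empty(m_total, dtype=object)
    w_allele = np.full(m_total, "", dtype=object)
    extra_copies = np.zeros(m_total, dtype=np.int64)
    subpop_freqs = np.zeros((m_total, config.n_subpops))

    col = 0

    # --- autosomal markers: Hardy-Weinberg within subpopulations -----------
    if m_auto:
        base = rng.uniform(config.maf_range[0], config.maf_range[1], m_auto)
        flip = rng.random(m_auto) < 0.5
        base = np.where(flip, 1.0 - base, base)  # ALT is the minor allele ~half the time
        fstv = config.fst_like_divergence
        if fstv > 0 and config.n_subpops > 1:
            a = base * (1 - fstv) / fstv
            b = (1 - base) * (1 - fstv) / fstv
            freqs = rng.beta(
                np.repeat(a[:, None], config.n_subpops, axis=1),
                np.repeat(b[:, None], config.n_subpops, axis=1),
            )
        else:
            freqs = np.repeat(base[:, None], config.n_subpops, axis=1)
        per_cell = freqs[:, subpop].T  # (n, m_auto)
        dosage[:, col : col + m_auto] = rng.binomial(2, per_cell)
        class_labels[col : col + m_auto] = "autosomal"
        subpop_freqs[col : col + m_auto] = freqs
        col += m_auto

    carriers = is_het_sex  # accessions with a W (ZW) or Y (XY)

    # --- strictly sex-limited markers: rare allele on every W --------------
    if m_ws:
        dosage[carriers, col : col + m_ws] = 1
        class_labels[col : col + m_ws] = "w_strict"
        w_allele[col : col + m_ws] = "alt"
        subpop_freqs[col : col + m_ws] = np.nan
        col += m_ws

    # --- partially sex-limited: rare allele on a fraction of W haplotypes --
    if m_wp:
        has = rng.random((int(carriers.sum()), m_wp)) < config.w_partial_fraction
        block = np.zeros((n, m_wp), dtype=np.int8)
        block[carriers] = has.astype(np.int8)
        dosage[:, col : col + m_wp] = block
        class_labels[col : col + m_wp] = "w_partial"
        w_allele[col : col + m_wp] = "alt"
        subpop_freqs[col : col + m_wp] = np.nan
        col += m_wp

    # --- Z-polymorphic: rare allele segregates on Z only -------------------
    # Homogametic accessions carry two Z, heterogametic ones a single Z
    # (their W holds the common allele), so only the homogametic sex can
    # be homozygous for the rare allele.
    if m_zp:
        q = rng.uniform(config.maf_range[0], config.maf_range[1], m_zp)
        n_z = np.where(carriers, 1, 2)
        dosage[:, col : col + m_zp] = rng.binomial(
            n_z[:, None], np.broadcast_to(q, (n, m_zp))
        )
        class_labels[col : col + m_zp] = "z_poly"
        w_allele[col : col + m_zp] = ""
        subpop_freqs[col : col + m_zp] = np.nan
        col += m_zp

    # --- collapsed paralog tags --------------------------------------------
    # Base locus monomorphic REF in everyone; carriers additionally hold
    # extra_w_copies hemizygous loci whose reads all carry ALT. Depths of
    # all copies superimpose on the single emitted marker.
    if m_par:
        class_labels[col : col + m_par] = "paralog_collapsed"
        w_allele[col : col + m_par] = "alt"
        extra_copies[col : col + m_par] = config.extra_w_copies
        subpop_freqs[col : col + m_par] = np.nan
    par_slice = slice(col, col + m_par)
    col += m_par
    assert col == m_total

    # --- read depths --------------------------------------------------------
    depth = _nb_draw(rng, config.mean_depth, config.depth_dispersion, (n, m_total))
    alt_true = rng.binomial(depth, dosage / 2.0)
    ref_true = depth - alt_true
    if m_par:
        # overwrite paralog columns: base locus is all-REF; extra copies all-ALT
        ref_true[:, par_slice] = depth[:, par_slice]
        k = config.extra_w_copies
        extra = _nb_draw(
            rng,
            config.mean_depth * k,
            config.depth_dispersion * k,  # sum of k iid NB draws
            (int(carriers.sum()), m_par),
        )
        alt_block = np.zeros((n, m_par), dtype=np.int64)
        alt_block[carriers] = extra
        alt_true[:, par_slice] = alt_block

    # per-read miscalls, symmetric between alleles
    e = config.error_rate
    ref_to_alt = rng.binomial(ref_true, e)
    alt_to_ref = rng.binomial(alt_true, e)
    ref_obs = ref_true - ref_to_alt + alt_to_ref
    alt_obs = alt_true - alt_to_ref + ref_to_alt

    # missingness: drop whole cells
    if config.missing_rate > 0:
        gone = rng.random((n, m_total)) < config.missing_rate
        ref_obs[gone] = 0
        alt_obs[gone] = 0

    depths = np.stack([ref_obs, alt_obs], axis=2).astype(np.int32)

    # --- assemble containers -------------------------------------------------
    chroms, positions, marker_ids = _marker_coordinates(class_labels, rng)
    alleles_ref = rng.choice(np.array(["A", "C", "G", "T"]), m_total)
    shift = rng.integers(1, 4, m_total)
    bases = np.array(["A", "C", "G", "T"])
    base_idx = np.searchsorted(bases, alleles_ref)
    alleles_alt = bases[(base_idx + shift) % 4]

    markers = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": alleles_ref,
            "alt": alleles_alt,
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    adm = AlleleDepthMatrix(accessions, markers, depths)

    sex = np.where(is_female, "F", "M").astype(object)
    if config.unknown_sex_rate > 0:
        unk = rng.random(n) < config.unknown_sex_rate
        sex[unk] = "unknown"
    phen = PhenotypeTable(
        pd.DataFrame(
            {"accession": accessions, "sex": sex, "subpop": subpop.astype(str)}
        )
    )

    true_codes = dosage.copy()  # 0/1/2 ALT copies == genotype codes
    true_codes[:, par_slice] = GENO_HOM_REF  # base-locus genotype
    truth_table = pd.DataFrame(
        {
            "class_label": class_labels,
            "w_allele": w_allele,
            "true_extra_copies": extra_copies,
            "subpop_freqs": list(subpop_freqs),
        },
        index=markers.index,
    )
    truth = SimTruth(
        table=truth_table,
        true_genotypes=GenotypeMatrix(accessions, markers.copy(), true_codes),
    )
    return adm, phen, truth


def _marker_coordinates(class_labels: np.ndarray, rng: np.random.Generator):
    """Assign chromosomes/positions: sex-linked on chr15, paralog tags on
    chr09 (where a collapsed tag's shared base locus maps), autosomal
    markers spread over the remaining chromosomes."""
    m = len(class_labels)
    autosomes = [f"chr{i:02d}" for i in range(1, 20) if i not in (9, 15)]
    chroms = np.empty(m, dtype=object)
    is_auto = class_labels == "autosomal"
    is_par = class_labels == "paralog_collapsed"
    is_sd = ~is_auto & ~is_par
    chroms[is_auto] = np.array(autosomes)[
        rng.integers(0, len(autosomes), int(is_auto.sum()))
    ]
    chroms[is_sd] = "chr15"
    chroms[is_par] = "chr09"
    positions = np.zeros(m, dtype=np.int64)
    for c in np.unique(chroms.astype(str)):
        idx = np.flatnonzero(chroms == c)
        # unique, increasing positions built from random gaps
        positions[idx] = np.cumsum(rng.integers(1, 5000, len(idx)))
    marker_ids = [f"S{chroms[j][3:]}_{positions[j]}" for j in range(m)]
    return chroms, positions, marker_ids
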