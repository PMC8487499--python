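"""VCF ingestion, genotype calling from allele depths, and marker QC filters.

The central containers are :class:`AlleleDepthMatrix` (per accession ×
marker read counts for the two alleles of a biallelic marker) and
:class:`GenotypeMatrix` (diploid calls derived from those counts).
Genotypes are called by maximising a binomial read likelihood under a
symmetric per-read miscall rate, and only where total depth reaches
``min_depth`` (default 5 reads). Two QC filters mirror common GBS
practice: a permissive one for association scans (call rate >= 75 %,
MAF > 5 %) and a stricter one for relatedness estimation (call rate
>= 95 %, MAF >= 1 %).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes; hom_ref/hom_alt refer to the VCF REF/ALT alleles. The
# rare-allele ("b") orientation used by downstream segregation analyses
# is derived per marker from called allele frequencies.
GENO_MISSING = -1
GENO_HOM_REF = 0
GENO_HET = 1
GENO_HOM_ALT = 2

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]

SEX_LABELS = ("F", "M", "unknown")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class AlleleDepthMatrix:
    """Per (accession, marker) read counts for the two alleles.

    Attributes
    ----------
    accessions : list of str
        Sample identifiers, in matrix row order.
    markers : pandas.DataFrame
        Indexed by marker id with columns ``chrom, pos, ref, alt``.
    depths : ndarray of shape (n_accessions, n_markers, 2)
        Non-negative read counts; ``[..., 0]`` is the REF allele,
        ``[..., 1]`` the ALT allele. Missing data is encoded as (0, 0).
    """

    accessions: list[str]
    markers: pd.DataFrame
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.shape != (len(self.accessions), len(self.markers), 2):
            raise ValueError(
                f"depth array shape {self.depths.shape} inconsistent with "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )
        if self.depths.size and self.depths.min() < 0:
            raise ValueError("read depths must be non-negative")
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker table lacks columns {missing}")
        # biallelic markers are unique per site; split multi-allelic
        # records share a position and are distinguished by ALT allele
        dup = self.markers.duplicated(subset=["chrom", "pos", "alt"])
        if dup.any():
            raise ValueError("marker positions must be unique per (chrom, pos, alt)")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def total_depth(self) -> np.ndarray:
        """Total read depth per cell, shape (n_accessions, n_markers)."""
        return self.depths.sum(axis=2)

    def subset_markers(self, keep: np.ndarray | Sequence[str]) -> "AlleleDepthMatrix":
        idx = _marker_indexer(self.markers, keep)
        return AlleleDepthMatrix(
            list(self.accessions), self.markers.iloc[idx].copy(), self.depths[:, idx, :]
        )


@dataclass
class GenotypeMatrix:
    """Called diploid genotypes on the same axes as an AlleleDepthMatrix.

    ``codes`` holds one of ``GENO_HOM_REF``, ``GENO_HET``,
    ``GENO_HOM_ALT`` or ``GENO_MISSING`` per cell.
    """

    accessions: list[str]
    markers: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.accessions), len(self.markers)):
            raise ValueError("genotype code array shape inconsistent with axes")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def call_rate(self) -> np.ndarray:
        """Fraction of accessions with a non-missing call, per marker."""
        return (self.codes != GENO_MISSING).mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """ALT allele frequency among called genotypes, per marker (NaN if none)."""
        called = self.codes != GENO_MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_allele_freq()
        return np.fmin(f, 1.0 - f)

    def dosage(self) -> np.ndarray:
        """ALT dosage in {0,1,2} with missing as NaN, shape (n_acc, n_markers)."""
        d = self.codes.astype(float)
        d[self.codes == GENO_MISSING] = np.nan
        return d

    def subset_markers(self, keep: np.ndarray | Sequence[str]) -> "GenotypeMatrix":
        idx = _marker_indexer(self.markers, keep)
        return GenotypeMatrix(
            list(self.accessions), self.markers.iloc[idx].copy(), self.codes[:, idx]
        )


def _marker_indexer(markers: pd.DataFrame, keep) -> np.ndarray:
    keep = np.asarray(keep)
    if keep.dtype == bool:
        if keep.shape != (len(markers),):
            raise ValueError("boolean marker mask has wrong length")
        return np.flatnonzero(keep)
    return markers.index.get_indexer(keep)


@dataclass
class PhenotypeTable:
    """Accession → sex (F/M/unknown) and optional subpopulation label."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if "accession" not in df.columns or "sex" not in df.columns:
            raise ValueError("phenotype table needs 'accession' and 'sex' columns")
        if df["accession"].duplicated().any():
            raise ValueError("accession identifiers must be unique")
        bad = set(df["sex"]) - set(SEX_LABELS)
        if bad:
            raise ValueError(f"unrecognised sex labels: {sorted(bad)}")
        if "subpop" not in df.columns:
            df = df.assign(subpop="0")
        self.data = df.reset_index(drop=True)

    @property
    def accessions(self) -> list[str]:
        return list(self.data["accession"])

    def sex_vector(self, accessions: Sequence[str]) -> np.ndarray:
        """Sex label aligned to the given accession order ('unknown' if absent)."""
        lookup = dict(zip(self.data["accession"], self.data["sex"]))
        return np.array([lookup.get(a, "unknown") for a in accessions])

    def counts(self) -> dict:
        c = self.data["sex"].value_counts()
        return {s: int(c.get(s, 0)) for s in SEX_LABELS}

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"accession": str, "subpop": str}))


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf_depths(path, split_multiallelic: bool = False) -> AlleleDepthMatrix:
    """Read a VCF with per-sample AD fields into an :class:`AlleleDepthMatrix`.

    Multi-allelic records are skipped by default (with a logged count); with
    ``split_multiallelic`` each ALT allele becomes its own biallelic marker
    (REF depth shared, other ALT depths ignored). A sample without AD gets
    depths (0, 0).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    depth_cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 and not split_multiallelic:
            if len(var.ALT) > 1:
                n_skipped += 1
            continue
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        alts = var.ALT if split_multiallelic else var.ALT[:1]
        for ai, alt in enumerate(alts, start=1):
            if ad is None:
                cell = np.zeros((len(samples), 2), dtype=np.int32)
            else:
                ref_d = ad[:, 0].astype(np.int64)
                alt_d = (
                    ad[:, ai].astype(np.int64)
                    if ad.shape[1] > ai
                    else np.zeros(len(samples), dtype=np.int64)
                )
                cell = np.stack([ref_d, alt_d], axis=1)
                cell[cell < 0] = 0  # cyvcf2 encodes missing AD as negative
            mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
            if split_multiallelic and len(var.ALT) > 1:
                mid = f"{mid}_{alt}"
            rows.append((mid, var.CHROM, var.POS, var.REF, alt))
            depth_cols.append(cell)
    if n_skipped:
        logger.info("skipped %d multi-allelic records", n_skipped)
    if not rows:
        raise VcfParseError(f"no usable biallelic records in {path}")
    markers = pd.DataFrame(
        rows, columns=["marker_id", *MARKER_COLUMNS]
    ).set_index("marker_id")
    depths = np.stack(depth_cols, axis=1)
    return AlleleDepthMatrix(samples, markers, depths)


def write_vcf(path, adm: AlleleDepthMatrix, genotypes: GenotypeMatrix | None = None) -> None:
    """Write a minimal VCF 4.2 with GT and AD FORMAT fields.

    Without a genotype matrix all GT fields are ``./.``.
    """
    gt_strings = {GENO_MISSING: "./.", GENO_HOM_REF: "0/0", GENO_HET: "0/1", GENO_HOM_ALT: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        for chrom in pd.unique(adm.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(adm.accessions)
            + "\n"
        )
        order = np.lexsort((adm.markers["pos"].to_numpy(), adm.markers["chrom"].to_numpy()))
        for j in order:
            row = adm.markers.iloc[j]
            cells = []
            for i in range(adm.n_accessions):
                gt = gt_strings[int(genotypes.codes[i, j])] if genotypes is not None else "./."
                r, a = adm.depths[i, j]
                cells.append(f"{gt}:{r},{a}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{adm.markers.index[j]}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT:AD\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

def call_genotypes(
    adm: AlleleDepthMatrix, error_rate: float = 0.01, min_depth: int = 5
) -> GenotypeMatrix:
    """Maximum-likelihood diploid genotype calls from allele depths.

    With ref/alt read counts (r, a) and per-read miscall rate ``e``, the
    binomial read likelihoods of the three genotypes use per-read alt
    probabilities e (hom ref), 1/2 (het) and 1-e (hom alt); the shared
    binomial coefficient cancels. Cells with total depth < ``min_depth``
    are missing. Exact likelihood ties are resolved toward het (a tie
    between the homozygotes only occurs at r == a, where the het
    likelihood already dominates for any e < 0.5).
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    r = adm.depths[..., 0].astype(np.float64)
    a = adm.depths[..., 1].astype(np.float64)
    log_e, log_1e = np.log(error_rate), np.log1p(-error_rate)
    log_half = np.log(0.5)
    ll_hom_ref = r * log_1e + a * log_e
    ll_het = (r + a) * log_half
    ll_hom_alt = r * log_e + a * log_1e
    codes = np.where(ll_hom_ref >= ll_hom_alt, GENO_HOM_REF, GENO_HOM_ALT).astype(np.int8)
    het_wins = (ll_het >= ll_hom_ref) & (ll_het >= ll_hom_alt)
    codes[het_wins] = GENO_HET
    codes[(r + a) < min_depth] = GENO_MISSING
    return GenotypeMatrix(list(adm.accessions), adm.markers.copy(), codes)


# ---------------------------------------------------------------------------
# Marker filters
# ---------------------------------------------------------------------------

class FilterResult(NamedTuple):
    genotypes: GenotypeMatrix
    report: dict


def _filter_markers(
    g: GenotypeMatrix,
    min_call_rate: float,
    maf_threshold: float,
    maf_strict: bool,
) -> FilterResult:
    call_rate = g.call_rate()
    maf = g.maf()
    ok_rate = call_rate >= min_call_rate
    with np.errstate(invalid="ignore"):
        ok_maf = (maf > maf_threshold) if maf_strict else (maf >= maf_threshold)
    ok_maf = np.where(np.isnan(maf), False, ok_maf)
    keep = ok_rate & ok_maf
    report = {
        "n_input": int(g.n_markers),
        "n_removed_call_rate": int((~ok_rate).sum()),
        "n_removed_maf": int((ok_rate & ~ok_maf).sum()),
        "n_retained": int(keep.sum()),
        "min_call_rate": min_call_rate,
        "maf_threshold": maf_threshold,
        "maf_strict": maf_strict,
    }
    if report["n_retained"] == 0:
        logger.warning("marker filter removed every marker")
    return FilterResult(g.subset_markers(keep), report)


def filter_assoc_markers(g: GenotypeMatrix) -> FilterResult:
    """Association-scan filter: call rate >= 75 % and MAF strictly > 5 %."""
    return _filter_markers(g, min_call_rate=0.75, maf_threshold=0.05, maf_strict=True)


def filter_kinship_markers(g: GenotypeMatrix) -> FilterResult:
    """Relatedness-estimation filter: call rate >= 95 % and MAF >= 1 %."""
    return _filter_markers(g, min_call_rate=0.95, maf_threshold=0.01, maf_strict=False)
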