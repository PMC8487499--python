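"""Scaffold-to-chromosome anchoring and multi-copy tag classification.

Assembly scaffolds are anchored to chromosomes by majority vote over
linkage-map markers located within them (BLAST hits below an e-value
cutoff); the scaffold's representative map position is the median
centimorgan position of the supporting markers. Anchors can be
cross-checked against an external chromosome assignment (e.g. alignment
of the scaffold to a related species' chromosome-scale assembly), with
W/Z sub-labels of a sex chromosome collapsed to the chromosome number
before comparison. Alignment-hit tables for a GBS tag sequence give its
genomic copy number; combined with the dosage diagnostics this
distinguishes a shared single-locus tag from a sex-specific multicopy
(hemizygous) one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexlink.dosage import DosageReport

logger = logging.getLogger(__name__)

BLAST_OUTFMT6_COLUMNS = [
    "query_id",
    "target_scaffold",
    "percent_identity",
    "match_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "target_start",
    "target_end",
    "evalue",
    "bitscore",
]

MAP_MARKER_COLUMNS = ["map_marker_id", "scaffold", "chromosome", "position_cm", "evalue"]


def read_blast_hits(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) hit file."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_OUTFMT6_COLUMNS,
                     dtype={"query_id": str, "target_scaffold": str})
    if (df["evalue"] <= 0).any():
        raise ValueError("e-values must be positive")
    return df


def read_map_markers(path) -> pd.DataFrame:
    """Read a map-marker hit table (marker, scaffold, chromosome, cM, e-value)."""
    df = pd.read_csv(path, sep="\t", dtype={"map_marker_id": str, "scaffold": str,
                                            "chromosome": str})
    missing = [c for c in MAP_MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"map-marker table lacks columns {missing}")
    return df


@dataclass
class ScaffoldAnchor:
    scaffold: str
    chromosome: str | None = None
    center_cm: float | None = None
    n_supporting: int = 0
    n_conflicting: int = 0
    external_chromosome: str | None = None
    conflict: bool = False


def collapse_chromosome_label(label) -> str | None:
    """Normalise a chromosome label to its number, dropping W/Z sub-labels
    and 'Chr' prefixes ('Chr15W' -> '15', '15Z' -> '15', 'Chr05' -> '5')."""
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return None
    s = str(label).strip()
    if not s or s.upper() == "NA":
        return None
    m = re.search(r"(\d+)", s)
    return str(int(m.group(1))) if m else s


def anchor_scaffold(hits: pd.DataFrame, e_threshold: float = 1e-10) -> ScaffoldAnchor:
    """Anchor one scaffold from its map-marker hits by strict majority.

    Hits with e-value >= ``e_threshold`` are discarded. A chromosome
    must account for more than half of the retained hits to win (a
    plurality or tie yields an unanchored NA result, matching how
    ambiguous scaffolds are reported). The center position is the median
    cM of the supporting hits. Order-invariant.
    """
    if len(hits) == 0:
        return ScaffoldAnchor(scaffold="NA")
    scaffolds = hits["scaffold"].unique()
    if len(scaffolds) != 1:
        raise ValueError("anchor_scaffold expects hits for exactly one scaffold")
    scaffold = str(scaffolds[0])
    retained = hits[hits["evalue"] < e_threshold]
    retained = retained[retained["chromosome"].notna()]
    if len(retained) == 0:
        return ScaffoldAnchor(scaffold=scaffold)
    counts = retained["chromosome"].value_counts()
    top_chrom, top_n = counts.index[0], int(counts.iloc[0])
    total = int(counts.sum())
    if 2 * top_n <= total:  # no strict majority
        return ScaffoldAnchor(scaffold=scaffold, n_conflicting=total)
    support = retained[retained["chromosome"] == top_chrom]
    return ScaffoldAnchor(
        scaffold=scaffold,
        chromosome=str(top_chrom),
        center_cm=float(support["position_cm"].median()),
        n_supporting=top_n,
        n_conflicting=total - top_n,
    )


def anchor_scaffolds(
    map_hits: pd.DataFrame,
    external: pd.DataFrame | None = None,
    e_threshold: float = 1e-10,
) -> list[ScaffoldAnchor]:
    """Anchor every scaffold appearing in a map-marker hit table.

    ``external`` optionally maps scaffold -> chromosome from a second
    reference; conflicts are flagged where both assignments exist and
    disagree after collapsing W/Z sub-labels.
    """
    ext = {}
    if external is not None:
        ext = dict(zip(external["scaffold"].astype(str), external["chromosome"]))
    anchors = []
    scaffold_ids = list(pd.unique(map_hits["scaffold"]))
    scaffold_ids += [s for s in ext if s not in set(scaffold_ids)]
    for scaf in scaffold_ids:
        sub = map_hits[map_hits["scaffold"] == scaf]
        anc = (
            anchor_scaffold(sub, e_threshold)
            if len(sub)
            else ScaffoldAnchor(scaffold=str(scaf))
        )
        anc.scaffold = str(scaf)
        ext_chrom = ext.get(str(scaf))
        if ext_chrom is not None and collapse_chromosome_label(ext_chrom) is not None:
            anc.external_chromosome = str(ext_chrom)
        own = collapse_chromosome_label(anc.chromosome)
        other = collapse_chromosome_label(anc.external_chromosome)
        anc.conflict = own is not None and other is not None and own != other
        anchors.append(anc)
    return anchors


def detect_anchor_conflicts(anchors: list[ScaffoldAnchor]) -> list[str]:
    """Scaffolds whose linkage-map and external chromosome assignments
    disagree (W/Z sub-labels collapsed before comparison)."""
    return [a.scaffold for a in anchors if a.conflict]


def anchors_to_frame(anchors: list[ScaffoldAnchor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": a.scaffold,
                "chromosome": a.chromosome if a.chromosome is not None else "NA",
                "center_cm": a.center_cm if a.center_cm is not None else np.nan,
                "n_supporting": a.n_supporting,
                "n_conflicting": a.n_conflicting,
                "external_chromosome": a.external_chromosome or "NA",
                "conflict": a.conflict,
            }
            for a in anchors
        ]
    )


@dataclass
class CopyCount:
    query_id: str
    n_copies: int
    per_scaffold: dict
    multi_copy: bool
    tandem_scaffolds: list = field(default_factory=list)


def count_tag_copies(
    hits: pd.DataFrame, e_threshold: float = 0.05, inclusive: bool = True
) -> CopyCount:
    """Count genomic copies of one tag from its alignment hits.

    Hits pass with e-value <= threshold (inclusive) or < threshold
    (strict). Scaffolds with more than one passing hit are reported as
    tandem-like multi-hit targets.
    """
    queries = hits["query_id"].unique()
    if len(queries) != 1:
        raise ValueError("count_tag_copies expects hits for exactly one query tag")
    ev = hits["evalue"].to_numpy(dtype=float)
    passing = hits[ev <= e_threshold] if inclusive else hits[ev < e_threshold]
    per_scaffold = passing["target_scaffold"].value_counts().to_dict()
    n = int(len(passing))
    return CopyCount(
        query_id=str(queries[0]),
        n_copies=n,
        per_scaffold={str(k): int(v) for k, v in per_scaffold.items()},
        multi_copy=n > 1,
        tandem_scaffolds=[str(k) for k, v in per_scaffold.items() if v > 1],
    )


@dataclass
class CopyModelVerdict:
    verdict: str  # shared_single_locus / female_specific_multicopy / unresolved
    reasons: list


def sex_specific_copy_model(
    tag_copies: CopyCount,
    dosage_report: DosageReport,
    tolerance: float = 1.0,
) -> CopyModelVerdict:
    """Combine reference copy counts with dosage evidence into a verdict.

    ``female_specific_multicopy`` requires: more than one copy in the
    (female-derived) reference, an elevated female/male depth ratio, and
    a depth-based extra-copy estimate of at least one that does not
    exceed what the reference copies can explain (n_copies - 1 plus
    ``tolerance``; the reference count is treated as an upper bound
    because not every assembled copy need recruit reads to the marker).
    ``shared_single_locus`` requires a single reference copy with no
    dosage anomaly. Anything else is unresolved, with reasons.
    """
    reasons: list[str] = []
    n = tag_copies.n_copies
    est = dosage_report.extra_copy_estimate
    elevated = bool(dosage_report.ratio_elevated)
    violated = bool(dosage_report.compensation_violated)
    if n > 1:
        if not elevated:
            reasons.append("multiple reference copies but no depth elevation")
        elif not np.isfinite(est) or est < 1.0 - 1e-9:
            reasons.append("depth ratio does not support an extra copy")
        elif est > (n - 1) + tolerance:
            reasons.append("estimated copies exceed reference copy count")
        else:
            return CopyModelVerdict("female_specific_multicopy", [
                f"{n} reference copies, estimated {est:.2f} extra female copies",
            ])
    else:
        if not elevated and not violated:
            return CopyModelVerdict("shared_single_locus", [
                "single reference copy, no dosage anomaly",
            ])
        reasons.append("single reference copy but dosage anomaly present")
    return CopyModelVerdict("unresolved", reasons)
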