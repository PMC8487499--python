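"""Published *Salix viminalis* reference data used as worked examples.

Two small published tables from the S. viminalis sex-determination
study serve as fixtures for the anchoring module: the scaffold
anchoring table (scaffold, linkage-map chromosome, center position on
the linkage map where on chromosome 15, external chromosome assignment
in the S. purpurea v5.1 assembly, number of sex-associated markers) and
the alignment-hit table of the top sex-associated marker's GBS tag
sequence against the S. viminalis scaffolds. The study's sexed
population (162 females, 103 males) is included as a phenotype fixture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sexlink.gbsio import PhenotypeTable

# scaffold, length_bp, linkage-map chromosome, center cM (chr15 only),
# external (S. purpurea v5.1) chromosome, number of sex-associated markers
SCAFFOLD_ANCHOR_TABLE = [
    ("0702", 768_110, "Chr15", 69.0, "Chr15W", 10),
    ("0535", 622_702, "Chr15", 57.2, "Chr15W", 9),
    ("1391", 539_124, "Chr15", 70.4, "Chr15W", 5),
    ("1541", 2_553_872, "Chr15", 68.0, "Chr15W", 4),
    ("1658", 116_437, None, None, None, 3),
    ("0302", 814_410, "Chr15", 58.0, "Chr15W", 2),
    ("0724", 541_616, None, None, "Chr15W", 2),
    ("1236", 355_459, "Chr15", 67.6, "Chr15W", 2),
    ("0779", 3_309_791, "Chr05", None, "Chr15W", 1),
    ("1114", 392_477, None, None, "Chr15W", 1),
    ("1491", 291_271, None, None, "Chr16", 1),
    ("1649", 120_404, None, None, None, 1),
    ("1730", 2_005_520, "Chr14", None, "Chr14", 1),
    ("1839", 54_690, None, None, None, 1),
    ("2018", 1_314_944, "Chr11", None, "Chr11", 1),
    ("2040", 3_822_569, "Chr02", None, "Chr02", 1),
    ("2041", 1_625_512, "Chr17", None, "Chr17", 1),
    ("2173", 26_877, None, None, None, 1),
    ("2218", 1_126_343, "Chr14", None, "Chr14", 1),
    ("1112", 7_166_859, "Chr09", None, "Chr09", 0),
]

# BLAST hits of the top sex-associated marker's tag sequence
# (scaffold, percent identity, match length, mismatches, target start,
#  target end, e-value, bitscore)
TAG_ALIGNMENT_HITS = [
    ("1114", 100.0, 53, 0, 185_301, 185_249, 7e-20, 96.9),
    ("0535", 100.0, 53, 0, 171_930, 171_982, 7e-20, 96.9),
    ("0535", 100.0, 52, 0, 78_761, 78_710, 2e-19, 95.1),
    ("0535", 98.08, 52, 0, 190_880, 190_830, 1e-16, 86.0),
    ("1112", 96.23, 53, 2, 3_895_886, 3_895_938, 3e-17, 87.8),
]

TAG_QUERY_ID = "S1_198703286"

N_FEMALES = 162
N_MALES = 103


def scaffold_anchor_frame() -> pd.DataFrame:
    """The published scaffold anchoring table as a DataFrame."""
    return pd.DataFrame(
        SCAFFOLD_ANCHOR_TABLE,
        columns=[
            "scaffold",
            "length_bp",
            "chromosome",
            "center_cm",
            "external_chromosome",
            "n_sa_markers",
        ],
    )


def map_marker_hits_fixture() -> pd.DataFrame:
    """Synthetic map-marker hit table reconstructed from the published
    scaffold anchors.

    For each scaffold with a linkage-map chromosome, three concordant
    hits are emitted whose median cM equals the published center
    position (an arbitrary 25.0 cM where the table prints no center);
    scaffolds the linkage map could not place get a 1-vs-1 chromosome
    tie so the majority rule reports NA, plus one hit that fails the
    e-value cutoff.
    """
    rows = []
    k = 0
    for scaf, _len, chrom, center, _ext, _n in SCAFFOLD_ANCHOR_TABLE:
        if chrom is not None:
            cm = center if center is not None else 25.0
            for d_cm in (-1.0, 0.0, 1.0):
                rows.append((f"mm{k:04d}", scaf, chrom, cm + d_cm, 1e-20))
                k += 1
        else:
            rows.append((f"mm{k:04d}", scaf, "Chr01", 10.0, 1e-20)); k += 1
            rows.append((f"mm{k:04d}", scaf, "Chr02", 12.0, 1e-20)); k += 1
            rows.append((f"mm{k:04d}", scaf, "Chr03", 14.0, 1e-5)); k += 1
    return pd.DataFrame(rows, columns=[
        "map_marker_id", "scaffold", "chromosome", "position_cm", "evalue",
    ])


def external_assignment_fixture() -> pd.DataFrame:
    """Scaffold -> external chromosome assignments from the published table."""
    rows = [
        (scaf, ext)
        for scaf, _len, _chrom, _cm, ext, _n in SCAFFOLD_ANCHOR_TABLE
        if ext is not None
    ]
    return pd.DataFrame(rows, columns=["scaffold", "chromosome"])


def tag_hits_fixture() -> pd.DataFrame:
    """The published tag alignment hits in BLAST outfmt-6 column layout."""
    rows = []
    for scaf, pid, length, mism, tstart, tend, ev, bits in TAG_ALIGNMENT_HITS:
        rows.append((TAG_QUERY_ID, scaf, pid, length, mism, 0, 1, length,
                     tstart, tend, ev, bits))
    return pd.DataFrame(rows, columns=[
        "query_id", "target_scaffold", "percent_identity", "match_length",
        "mismatches", "gap_opens", "query_start", "query_end",
        "target_start", "target_end", "evalue", "bitscore",
    ])


def phenotype_fixture() -> PhenotypeTable:
    """The study population's sex counts: 162 females and 103 males."""
    acc = [f"ACC{i + 1:05d}" for i in range(N_FEMALES + N_MALES)]
    sex = np.array(["F"] * N_FEMALES + ["M"] * N_MALES)
    return PhenotypeTable(pd.DataFrame({"accession": acc, "sex": sex}))
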