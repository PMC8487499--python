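"""End-to-end orchestration: simulate/ingest → filter → associate →
classify segregation → dosage diagnostics → anchoring → report.

Every stage writes its intermediate output as plain text (VCF/TSV/JSON)
into the run's output directory, and the run report records per-stage
marker counts, significant-marker counts per method and their
intersection, the heterogamety verdict, and paralog-suspect verdicts.
A fixed seed makes the whole run reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sexlink import anchor as anchor_mod
from sexlink import fixtures as fixtures_mod
from sexlink.assoc import gwas_sex
from sexlink.dosage import (
    DosageParams,
    analyze_marker,
    flag_paralog_suspects,
    textbook_depth_stats,
)
from sexlink.gbsio import (
    PhenotypeTable,
    call_genotypes,
    filter_assoc_markers,
    read_vcf_depths,
    write_vcf,
)
from sexlink.segregation import (
    SegThresholds,
    classify_segregation,
    identify_textbook_markers,
    infer_heterogamety,
    segregation_profile,
)
from sexlink.simulate import SimConfig, simulate_population

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``vcf`` + ``phenotypes`` paths or a simulator config must be
    supplied. Stage toggles allow skipping association (downstream
    stages then operate on all filtered markers), the MLM, dosage or
    anchoring.
    """

    out_dir: str = "sexlink_run"
    seed: int = 0
    vcf: str | None = None
    phenotypes: str | None = None
    sim: SimConfig | None = None
    do_assoc: bool = True
    do_mlm: bool = True
    do_segregation: bool = True
    do_dosage: bool = True
    alpha: float = 0.05
    n_pcs: int = 2
    call_error_rate: float = 0.01
    min_depth: int = 5
    map_markers: str | None = None
    external_assignments: str | None = None
    tag_hits: str | None = None
    anchor_evalue: float = 1e-10
    tag_evalue: float = 0.05
    seg_thresholds: SegThresholds = field(default_factory=SegThresholds)
    dosage_params: DosageParams = field(default_factory=DosageParams)
    max_dosage_markers: int = 200

    def validate(self) -> None:
        have_files = self.vcf is not None and self.phenotypes is not None
        if not have_files and self.sim is None:
            raise ValueError("need either vcf+phenotypes or a simulator config")
        for p in (self.vcf, self.phenotypes, self.map_markers,
                  self.external_assignments, self.tag_hits):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d.get("sim") and isinstance(d["sim"].get("maf_range"), tuple):
            d["sim"]["maf_range"] = list(d["sim"]["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim") is not None:
            sim = d["sim"]
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            d["sim"] = SimConfig(**sim)
        if d.get("seg_thresholds") is not None:
            d["seg_thresholds"] = SegThresholds(**d["seg_thresholds"])
        if d.get("dosage_params") is not None:
            d["dosage_params"] = DosageParams(**d["dosage_params"])
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # --- input stage -------------------------------------------------------
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        adm, phen, truth = simulate_population(sim_cfg)
        truth.to_tsv(out / "sim_truth.tsv")
        sim_cfg.to_yaml(out / "sim_config.yaml")
        report["stages"]["simulate"] = {
            "n_accessions": adm.n_accessions,
            "n_markers": adm.n_markers,
            "sex_counts": phen.counts(),
        }
    else:
        adm = read_vcf_depths(config.vcf)
        phen = PhenotypeTable.from_tsv(config.phenotypes)
        report["stages"]["ingest"] = {
            "n_accessions": adm.n_accessions,
            "n_markers": adm.n_markers,
            "sex_counts": phen.counts(),
        }

    # --- genotype calling and filters --------------------------------------
    genotypes = call_genotypes(adm, error_rate=config.call_error_rate,
                               min_depth=config.min_depth)
    filt = filter_assoc_markers(genotypes)
    g = filt.genotypes
    adm_f = adm.subset_markers(list(g.markers.index))
    write_vcf(out / "filtered.vcf", adm_f, g)
    phen.to_tsv(out / "phenotypes.tsv")
    report["stages"]["filter"] = filt.report

    # --- association --------------------------------------------------------
    if config.do_assoc:
        res, summary = gwas_sex(g, phen, alpha=config.alpha,
                                run_mlm=config.do_mlm, n_pcs=config.n_pcs)
        res.to_csv(out / "association.tsv", sep="\t", index=True,
                   index_label="marker_id")
        report["stages"]["assoc"] = summary
        significant = list(res.index[res["significant_fisher"]])
    else:
        report["stages"]["assoc"] = {"skipped": True}
        significant = list(g.markers.index)

    # --- segregation classification ----------------------------------------
    if config.do_segregation and significant:
        profiles = [segregation_profile(g, phen, m) for m in significant]
        labels = [classify_segregation(p, config.seg_thresholds) for p in profiles]
        seg_df = pd.DataFrame(
            {
                "marker_id": [p.marker_id for p in profiles],
                "class_label": labels,
                "b_carrier_freq_F": [p.b_carrier_freq_f for p in profiles],
                "b_carrier_freq_M": [p.b_carrier_freq_m for p in profiles],
                "het_freq_F": [p.het_freq_f for p in profiles],
                "het_freq_M": [p.het_freq_m for p in profiles],
            }
        )
        seg_df.to_csv(out / "segregation.tsv", sep="\t", index=False)
        call = infer_heterogamety(profiles, config.seg_thresholds)
        verdict = dataclasses.asdict(call)
        with open(out / "heterogamety.json", "w") as fh:
            json.dump(verdict, fh, indent=2)
        report["stages"]["segregation"] = {
            "n_classified": len(labels),
            "class_counts": {c: labels.count(c) for c in set(labels)},
            "heterogamety": verdict,
        }
    else:
        report["stages"]["segregation"] = {"skipped": True}

    # --- dosage diagnostics --------------------------------------------------
    if config.do_dosage:
        textbook = identify_textbook_markers(g)
        tb_reports = [
            analyze_marker(adm_f, g, phen, m, config.dosage_params, seed=config.seed)
            for m in textbook[: config.max_dosage_markers]
        ]
        reference = textbook_depth_stats(tb_reports) if tb_reports else None
        candidates = significant[: config.max_dosage_markers]
        reports = [
            analyze_marker(adm_f, g, phen, m, config.dosage_params, seed=config.seed)
            for m in candidates
        ]
        suspects = flag_paralog_suspects(reports, reference, config.dosage_params)
        dose_df = pd.DataFrame(
            {
                "marker_id": [r.marker_id for r in reports],
                "mean_depth_F": [r.total_f.mean for r in reports],
                "mean_depth_M": [r.total_m.mean for r in reports],
                "sex_depth_ratio": [r.sex_depth_ratio for r in reports],
                "extra_copy_estimate": [r.extra_copy_estimate for r in reports],
                "dose_compensated": [r.dose_compensated for r in reports],
                "paralog_suspect": [r.paralog_suspect for r in reports],
                "flag_reasons": [";".join(r.flag_reasons) for r in reports],
            }
        )
        dose_df.to_csv(out / "dosage.tsv", sep="\t", index=False)
        report["stages"]["dosage"] = {
            "n_textbook": len(textbook),
            "n_examined": len(reports),
            "paralog_suspects": suspects,
        }
    else:
        report["stages"]["dosage"] = {"skipped": True}

    # --- anchoring ------------------------------------------------------------
    if config.map_markers is not None:
        map_hits = anchor_mod.read_map_markers(config.map_markers)
        external = (
            pd.read_csv(config.external_assignments, sep="\t",
                        dtype={"scaffold": str, "chromosome": str})
            if config.external_assignments
            else None
        )
        anchors = anchor_mod.anchor_scaffolds(map_hits, external,
                                              e_threshold=config.anchor_evalue)
        anchor_mod.anchors_to_frame(anchors).to_csv(
            out / "anchors.tsv", sep="\t", index=False
        )
        conflicts = anchor_mod.detect_anchor_conflicts(anchors)
        report["stages"]["anchor"] = {
            "n_scaffolds": len(anchors),
            "n_anchored": sum(a.chromosome is not None for a in anchors),
            "conflicts": conflicts,
        }
        if config.tag_hits is not None:
            hits = anchor_mod.read_blast_hits(config.tag_hits)
            copies = anchor_mod.count_tag_copies(hits, e_threshold=config.tag_evalue)
            report["stages"]["anchor"]["tag_copies"] = {
                "query_id": copies.query_id,
                "n_copies": copies.n_copies,
                "per_scaffold": copies.per_scaffold,
            }
    else:
        report["stages"]["anchor"] = {"skipped": True}

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def make_fixtures(out_dir) -> dict:
    """Write the published worked-example fixtures and a small toy VCF.

    Emits: a map-marker hit table and external scaffold assignments
    reconstructed from the published anchoring table, the published tag
    alignment hits (outfmt-6 TSV), a phenotype table with the study's
    162 female / 103 male accessions, and a 12-accession simulated toy
    VCF that round-trips through the VCF reader.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures_mod.map_marker_hits_fixture().to_csv(
        out / "map_markers.tsv", sep="\t", index=False
    )
    fixtures_mod.external_assignment_fixture().to_csv(
        out / "external_assignments.tsv", sep="\t", index=False
    )
    fixtures_mod.tag_hits_fixture().to_csv(
        out / "tag_hits.tsv", sep="\t", index=False, header=False
    )
    fixtures_mod.phenotype_fixture().to_tsv(out / "phenotypes.tsv")
    toy_cfg = SimConfig(
        n_accessions=12, female_fraction=0.5, n_autosomal=8, n_w_strict=1,
        n_w_partial=0, n_z_poly=0, n_paralog_tags=1, missing_rate=0.0, seed=7,
    )
    adm, phen, _ = simulate_population(toy_cfg)
    write_vcf(out / "toy.vcf", adm, call_genotypes(adm))
    phen.to_tsv(out / "toy_phenotypes.tsv")
    return {
        "map_markers": str(out / "map_markers.tsv"),
        "external_assignments": str(out / "external_assignments.tsv"),
        "tag_hits": str(out / "tag_hits.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "toy_vcf": str(out / "toy.vcf"),
        "toy_phenotypes": str(out / "toy_phenotypes.tsv"),
    }
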