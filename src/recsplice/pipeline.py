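"""End-to-end orchestration: simulate -> map -> filter -> splice -> score
-> prioritize -> assay, with one JSON summary.

The pipeline is deterministic given the configured seed: each stage draws
from its own stream derived from the top-level seed, so any stage can be
re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .assaystats import (carrier_frequency, concordance_check,
                         deficit_homozygote_test)
from .autozygosity import (find_shared_homozygous_segment,
                           haplotype_sharing_scan, interval_length_mb)
from .prioritize import link_and_rank, protein_effect
from .simdata import (SEQ_CASE_IDS, SEQ_CONTROL_IDS, SimConfig,
                      fixture_protein_model, simulate_study)
from .splicing import detect_events
from .varfilter import classify_consequence, filter_cascade

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full pipeline run.

    Threshold defaults: variant quality strictly above 100, junction
    anchors of 8 nt, at least 10 informative reads per splice call, PSI
    below 0.8 to call an exon skip, cryptic shifts up to 10 nt, acceptor
    score drops of at least 1/24 flagged disruptive, and DNA-RNA linking
    within 50 bp of an affected splice site.
    """

    seed: int = 0
    window_markers: int = 20
    qual_min: float = 100.0
    anchor_min: int = 8
    min_reads: int = 10
    psi_max_normal: float = 0.8
    max_shift: int = 10
    disrupt_threshold: float = 1 / 24
    max_link_bp: int = 50
    verbosity: int = 1
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if not 0 < self.psi_max_normal <= 1:
            raise ValueError("psi_max_normal must be in (0, 1]")
        for name in ("anchor_min", "min_reads", "max_shift", "max_link_bp",
                     "window_markers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.qual_min < 0 or self.disrupt_threshold < 0:
            raise ValueError("thresholds must be non-negative")

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run the whole strategy on one simulated study and write outputs.

    Writes the simulated inputs (genotype/map TSV, VCF, GFF3, FASTA,
    junction TSV, assay TSV), the mapped interval BED, the scan track,
    the filter report, splice events, the ranked candidates and a single
    ``summary.json``; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config.sim_config())
    sim = study.config

    # ---- write inputs ------------------------------------------------
    rio.write_genotype_tsv(study.population.matrix,
                           outdir / "genotypes.tsv", outdir / "markers.tsv")
    rio.write_vcf(study.variants, outdir / "variants.vcf",
                  contigs={sim.chrom: sim.region_span})
    rio.write_catalog_tsv(study.catalog, outdir / "catalog.tsv")
    rio.write_gff3(study.model, outdir / "gene.gff3")
    rio.write_fasta({sim.chrom: study.chrom_seq}, outdir / "reference.fa")
    study.junctions.to_tsv(outdir / "junctions.tsv")
    rio.write_assay_tsv(study.assay, outdir / "assay.tsv")

    # ---- map ---------------------------------------------------------
    matrix = study.population.matrix
    cases = matrix.subset(study.population.case_ids)
    controls = matrix.subset(study.population.control_ids)
    segment = find_shared_homozygous_segment(cases, sim.chrom)
    scan = haplotype_sharing_scan(cases, controls, config.window_markers)
    if segment is None:
        raise RuntimeError("no shared homozygous segment found")
    rio.write_bed([segment], outdir / "interval.bed", names=["shared_hom"])
    scan.track.to_csv(outdir / "scan_track.tsv", sep="\t", index=False)

    # ---- filter ------------------------------------------------------
    report = filter_cascade(
        study.variants, segment, SEQ_CASE_IDS, SEQ_CONTROL_IDS,
        known_catalog=study.catalog, qual_min=config.qual_min,
    )
    (outdir / "filter_report.json").write_text(
        json.dumps(report.as_dict(), indent=2)
    )

    # ---- splice ------------------------------------------------------
    events = []
    for sample in study.rna_samples:
        events.extend(
            detect_events(
                study.junctions, study.model, sample,
                min_reads=config.min_reads,
                psi_max_normal=config.psi_max_normal,
                max_shift=config.max_shift,
                chrom_seq=study.chrom_seq,
            )
        )
    (outdir / "events.json").write_text(
        json.dumps([e.as_dict() for e in events], indent=2)
    )

    # ---- score + prioritize -----------------------------------------
    ranked = link_and_rank(
        report.candidates, events, [study.model],
        max_link_bp=config.max_link_bp,
        chrom_seqs={sim.chrom: study.chrom_seq},
    )
    top = ranked[0] if ranked else None
    ranked_rows = []
    for rc in ranked:
        cons = classify_consequence(rc.variant, study.model, study.chrom_seq)
        ranked_rows.append(
            {
                "rank": rc.rank,
                "chrom": rc.variant.chrom,
                "pos": rc.variant.pos,
                "ref": rc.variant.ref,
                "alt": rc.variant.alt,
                "vid": rc.variant.vid,
                "linked": rc.linked,
                "distance_bp": rc.distance_bp,
                "acceptor_delta": rc.acceptor.delta if rc.acceptor else None,
                "disrupts_acceptor": rc.disrupts_acceptor,
                "consequence": cons.klass,
            }
        )
    pd.DataFrame(ranked_rows).to_csv(outdir / "ranked.tsv", sep="\t",
                                     index=False)

    cds_model, domains = fixture_protein_model()
    effect = protein_effect(cds_model, skipped_exon=2, domains=domains)

    # ---- assay -------------------------------------------------------
    conc = concordance_check(study.assay)
    cf = carrier_frequency(study.assay)
    pop = study.assay[study.assay["role"] == "population"]
    het = int((pop["genotype"] == "RA").sum())
    hom = int((pop["genotype"] == "AA").sum())
    hwe = deficit_homozygote_test(len(pop), het, hom)

    top_acceptor = None
    if top is not None and top.acceptor is not None and top.acceptor.applicable:
        top_acceptor = {
            "position": top.acceptor.position,
            "delta": top.acceptor.delta,
            "disrupted": top.acceptor.disrupted,
        }
    summary = {
        "seed": config.seed,
        "interval": {
            "chrom": segment.chrom,
            "start": segment.start,
            "end": segment.end,
            "n_markers": segment.n_markers,
            "length_mb": interval_length_mb(segment),
        },
        "scan": {
            "significant": scan.significant,
            "best_p": float(scan.best_window["p"]) if scan.best_window is not None else None,
            "bonferroni": scan.bonferroni,
        },
        "filter": report.as_dict(),
        "n_events": len(events),
        "top_candidate": None if top is None else {
            "chrom": top.variant.chrom,
            "pos": top.variant.pos,
            "ref": top.variant.ref,
            "alt": top.variant.alt,
            "vid": top.variant.vid,
            "linked": top.linked,
            "distance_bp": top.distance_bp,
            "acceptor": top_acceptor,
        },
        "is_causal_top": bool(
            top is not None
            and top.variant.key == study.variant_truth.causal_key
        ),
        "protein_effect": {
            "deleted_start": effect.deleted_start,
            "deleted_end": effect.deleted_end,
            "deleted_count": effect.deleted_count,
            "remaining_length": effect.remaining_length,
            "in_frame": effect.in_frame,
        },
        "assay": {
            "n_checked": conc.n_checked,
            "n_violations": conc.n_violations,
            "carrier_frequency": cf,
            "hwe_deficit_p": hwe.p_value,
            "expected_hom": hwe.expected_hom,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
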