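"""Integrating DNA candidates with RNA splice events.

The decisive step of the strategy: among the genetically defined
candidates surviving the filter cascade, the causative variant is the one
sitting next to the splice sites of an exon the transcript data shows to
be aberrantly spliced.  Ranking is lexicographic and therefore a total,
auditable order:

1. linked to a splice event (variant within ``max_link_bp`` of a splice
   site of the event's affected exon) before unlinked;
2. acceptor-disrupting before not;
3. smaller distance to the nearest affected splice site;
4. genomic position as the final tie-break.

Also maps an exon skip onto the protein: the residue range removed, the
remaining length, and the overlap with annotated protein domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .acceptor import AcceptorScoreResult, variant_acceptor_delta
from .model import GeneModel
from .splicing import SpliceEvent
from .varfilter import VariantRecord

__all__ = [
    "RankedCandidate",
    "CdsExonModel",
    "ProteinEffect",
    "link_and_rank",
    "protein_effect",
]


@dataclass
class RankedCandidate:
    """One candidate variant with its RNA link and rank evidence."""

    variant: VariantRecord
    linked_event: SpliceEvent | None = None
    distance_bp: int | None = None  # to nearest splice site of the event exon
    acceptor: AcceptorScoreResult | None = None
    rank: int = 0

    @property
    def linked(self) -> bool:
        return self.linked_event is not None

    @property
    def disrupts_acceptor(self) -> bool:
        return bool(self.acceptor and self.acceptor.disrupted)

    def sort_key(self) -> tuple:
        return (
            0 if self.linked else 1,
            0 if self.disrupts_acceptor else 1,
            self.distance_bp if self.distance_bp is not None else math.inf,
            self.variant.chrom,
            self.variant.pos,
        )


def _event_splice_sites(model: GeneModel, exon_1based: int) -> list[int]:
    """Genomic coordinates of the splice sites flanking an exon."""
    i = exon_1based - 1
    sites = []
    if i > 0:
        sites.append(model.acceptor_site(i - 1))
    if i < model.n_exons - 1:
        sites.append(model.donor_site(i))
    return sites


def link_and_rank(
    candidates: list[VariantRecord],
    events: list[SpliceEvent],
    gene_models: list[GeneModel],
    max_link_bp: int = 50,
    chrom_seqs: dict[str, str] | None = None,
) -> list[RankedCandidate]:
    """Link candidates to splice events and rank them.

    A candidate is linked to the event whose affected exon has the nearest
    splice site, provided that distance is <= ``max_link_bp``.  When
    ``chrom_seqs`` (chrom -> plus-strand sequence) is given, each
    candidate's acceptor-disruption score is computed against the gene
    model of its linked (or nearest) event.
    """
    models = {m.gene_id: m for m in gene_models}
    ranked = []
    for v in candidates:
        best_ev, best_d = None, None
        for ev in events:
            model = models.get(ev.gene_id)
            if model is None or ev.chrom != v.chrom:
                continue
            for site in _event_splice_sites(model, ev.exon):
                d = abs(v.pos - site)
                if best_d is None or d < best_d:
                    best_ev, best_d = ev, d
        rc = RankedCandidate(variant=v)
        if best_ev is not None and best_d is not None and best_d <= max_link_bp:
            rc.linked_event = best_ev
            rc.distance_bp = best_d
            if chrom_seqs is not None and v.chrom in chrom_seqs:
                model = models[best_ev.gene_id]
                rc.acceptor = variant_acceptor_delta(
                    model, chrom_seqs[v.chrom], v
                )
        ranked.append(rc)
    ranked.sort(key=RankedCandidate.sort_key)
    for i, rc in enumerate(ranked, start=1):
        rc.rank = i
    return ranked


@dataclass(frozen=True)
class CdsExonModel:
    """CDS architecture in coding coordinates: per-exon CDS nucleotide
    spans (1-based inclusive, stop codon included in the last span) and
    the protein length in residues (stop excluded)."""

    protein_length: int
    exon_cds_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for lo, hi in self.exon_cds_spans:
            if lo != prev_end + 1 or hi < lo:
                raise ValueError("exon CDS spans must tile the CDS contiguously")
            prev_end = hi
        if prev_end != 3 * (self.protein_length + 1):
            raise ValueError(
                "CDS spans must cover protein_length codons plus the stop"
            )


@dataclass(frozen=True)
class DomainOverlap:
    name: str
    start_aa: int
    end_aa: int
    overlap_aa: int


@dataclass(frozen=True)
class ProteinEffect:
    """Residues removed by skipping one CDS exon."""

    deleted_start: int
    deleted_end: int
    deleted_count: int
    remaining_length: int
    in_frame: bool
    domain_overlaps: tuple[DomainOverlap, ...] = ()


def protein_effect(
    cds_model: CdsExonModel,
    skipped_exon: int,
    domains: list[tuple[str, int, int]] | None = None,
) -> ProteinEffect:
    """Protein consequence of skipping one exon of the CDS.

    ``skipped_exon`` is the 1-based index into ``exon_cds_spans``.  Codon
    phase is handled explicitly: a codon counts as deleted only when all
    three of its nucleotides are removed; partially removed codons at the
    junctions recombine into hybrid codons and are counted as retained.
    """
    if not 1 <= skipped_exon <= len(cds_model.exon_cds_spans):
        raise ValueError(f"no CDS exon {skipped_exon}")
    start, end = cds_model.exon_cds_spans[skipped_exon - 1]
    length = end - start + 1
    k_lo = math.ceil((start - 1) / 3) + 1
    k_hi = min(end // 3, cds_model.protein_length)
    if k_lo > k_hi:
        deleted = 0
        k_lo, k_hi = 0, -1
    else:
        deleted = k_hi - k_lo + 1
    overlaps = []
    for name, d_lo, d_hi in domains or []:
        lo, hi = max(k_lo, d_lo), min(k_hi, d_hi)
        if deleted and lo <= hi:
            overlaps.append(DomainOverlap(name, lo, hi, hi - lo + 1))
    return ProteinEffect(
        deleted_start=k_lo,
        deleted_end=k_hi,
        deleted_count=deleted,
        remaining_length=cds_model.protein_length - deleted,
        in_frame=(length % 3 == 0),
        domain_overlaps=tuple(overlaps),
    )
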