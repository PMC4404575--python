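"""Candidate-variant filtering and consequence annotation.

Implements the case/control filter cascade used to reduce the variants
called inside a mapped autozygosity interval to a short candidate list:
keep variants inside the interval, with call quality strictly above a
threshold, homozygous for the alternate allele in every sequenced case,
never showing the alternate allele in any control, and absent from the
known-variant catalog.  Stages 2-5 are pure set predicates, so the final
candidate set is invariant under their order; the report records counts in
the canonical order above.

Also provides SNV consequence classification against a gene model
(missense / nonsense / synonymous / splice-region / intronic / UTR /
intergenic, with signed distance to the nearest exon-intron junction) and
a parser for HGVS-style ``c.`` variant designations such as ``c.211-10C>G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .autozygosity import Interval
from .model import HGVS_C_RE, CdsAnchor, GeneModel

MISSING = -1

CONSEQUENCE_CLASSES = (
    "missense",
    "nonsense",
    "synonymous",
    "canonical_splice_region",
    "intronic",
    "utr",
    "intergenic",
    "indel",
)

__all__ = [
    "VariantRecord",
    "FilterReport",
    "Consequence",
    "HgvsAnchor",
    "filter_cascade",
    "classify_consequence",
    "parse_hgvs_c",
    "CASCADE_STAGE_ORDER",
]


@dataclass
class VariantRecord:
    """One called variant with per-sample alt-allele dosages.

    ``genotypes`` maps sample id -> 0/1/2 dosage of ``alt`` (-1 missing).
    Multi-allelic sites are represented as one record per alternate allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    genotypes: dict[str, int] = field(default_factory=dict)
    vid: str | None = None
    in_known_catalog: bool = False

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class FilterReport:
    """Per-stage survivor counts plus the final candidate list."""

    stage_names: list[str]
    stage_counts: list[int]
    candidates: list[VariantRecord]

    def as_dict(self) -> dict:
        return {
            "stages": dict(zip(self.stage_names, self.stage_counts)),
            "n_candidates": len(self.candidates),
            "candidate_keys": [list(v.key) for v in self.candidates],
        }


@dataclass(frozen=True)
class Consequence:
    """Predicted consequence of an SNV relative to one gene model.

    ``distance_to_junction`` is signed: negative on the intron side,
    positive on the exon side (the junction-adjacent exonic base is +1);
    ``None`` for intergenic variants.  ``affected_exon`` is the 1-based
    index of the nearest exon.
    """

    klass: str
    distance_to_junction: int | None = None
    affected_exon: int | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.klass not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.klass!r}")


CASCADE_STAGE_ORDER = (
    "in_interval",
    "qual",
    "hom_cases",
    "absent_controls",
    "not_in_catalog",
)


def _check_samples(variants, sample_ids):
    for v in variants:
        for s in sample_ids:
            if s not in v.genotypes:
                raise KeyError(
                    f"sample {s!r} has no genotype at {v.chrom}:{v.pos}"
                )


def filter_cascade(
    variants: list[VariantRecord],
    interval: Interval,
    case_ids: list[str],
    control_ids: list[str],
    known_catalog: set[tuple[str, int, str, str]] | None = None,
    qual_min: float = 100.0,
    stage_order: tuple[str, ...] = CASCADE_STAGE_ORDER,
) -> FilterReport:
    """Apply the candidate filter cascade and report per-stage counts.

    Missing case genotypes fail the homozygosity stage (an explicit hom-alt
    call is required); missing control genotypes do not count as observing
    the alternate allele.
    """
    _check_samples(variants, list(case_ids) + list(control_ids))
    catalog = known_catalog or set()

    stages = {
        "in_interval": lambda v: interval.contains(v.chrom, v.pos),
        "qual": lambda v: v.qual > qual_min,
        "hom_cases": lambda v: all(v.genotypes[s] == 2 for s in case_ids),
        "absent_controls": lambda v: all(
            v.genotypes[s] in (0, MISSING) for s in control_ids
        ),
        "not_in_catalog": lambda v: v.key not in catalog,
    }
    if set(stage_order) != set(CASCADE_STAGE_ORDER):
        raise ValueError("stage_order must be a permutation of the five stages")

    for v in variants:
        v.in_known_catalog = v.key in catalog

    surviving = list(variants)
    names, counts = [], []
    for name in stage_order:
        surviving = [v for v in surviving if stages[name](v)]
        names.append(name)
        counts.append(len(surviving))
    return FilterReport(names, counts, surviving)


def _transcribed(base: str, strand: str) -> str:
    return base if strand == "+" else str(Seq(base).complement())


def classify_consequence(
    variant: VariantRecord, model: GeneModel, chrom_seq: str | None = None
) -> Consequence:
    """Classify an SNV against a gene model.

    ``chrom_seq`` (plus-strand chromosome sequence) is required to resolve
    coding changes; without it, CDS variants are reported as ``missense``
    with a detail note.  Indels fall outside the SNV taxonomy and are
    reported as class ``indel``.
    """
    if not variant.is_snv:
        return Consequence("indel", detail="non-SNV allele")
    if variant.chrom != model.chrom:
        return Consequence("intergenic", detail="different chromosome")
    g = variant.pos
    lo, hi = model.span
    if g < lo or g > hi:
        return Consequence("intergenic")

    exon = model.exon_of_genomic(g)
    if exon is not None:
        t = model.g2t(g)
        # exon-side distance to the nearest junction of this exon
        dists = []
        if exon > 0:  # has an acceptor on its transcript-upstream side
            dists.append(abs(g - model.acceptor_site(exon - 1)) + 1)
        if exon < model.n_exons - 1:  # has a donor
            dists.append(abs(model.donor_site(exon) - g) + 1)
        dist = min(dists) if dists else None
        if not (model.cds_start_t <= t <= model.cds_end_t):
            return Consequence("utr", dist, exon + 1)
        if chrom_seq is None:
            return Consequence("missense", dist, exon + 1,
                               detail="no sequence supplied; CDS class unresolved")
        cds = model.cds_seq(chrom_seq)
        c = t - model.cds_start_t  # 0-based CDS offset
        ref_t = _transcribed(variant.ref, model.strand)
        alt_t = _transcribed(variant.alt, model.strand)
        if cds[c].upper() != ref_t.upper():
            raise ValueError(
                f"reference mismatch at {variant.chrom}:{g}: "
                f"model has {cds[c]!r} (transcribed), variant ref {ref_t!r}"
            )
        codon_i = c // 3
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        alt_codon = list(codon)
        alt_codon[c % 3] = alt_t
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq("".join(alt_codon)).translate())
        if aa_ref == aa_alt:
            klass = "synonymous"
        elif aa_alt == "*":
            klass = "nonsense"
        else:
            klass = "missense"
        return Consequence(klass, dist, exon + 1, detail=f"p.{aa_ref}>{aa_alt}")

    intron = model.intron_of_genomic(g)
    if intron is None:
        return Consequence("intergenic")
    d_donor = abs(g - model.donor_site(intron))
    d_accept = abs(model.acceptor_site(intron) - g)
    if d_donor <= d_accept:
        dist, affected = -d_donor, intron + 1
        side = "donor"
    else:
        dist, affected = -d_accept, intron + 2
        side = "acceptor"
    klass = "canonical_splice_region" if abs(dist) <= 3 else "intronic"
    return Consequence(klass, dist, affected, detail=side)


@dataclass(frozen=True)
class HgvsAnchor:
    """Resolved HGVS ``c.`` designation.

    ``ref``/``alt`` are transcribed-strand bases as written in the
    notation; ``ref_fwd``/``alt_fwd`` are the corresponding plus-strand
    bases at ``genomic_pos``.
    """

    anchor: CdsAnchor
    ref: str
    alt: str
    genomic_pos: int
    ref_fwd: str
    alt_fwd: str

    @property
    def cds_pos(self) -> int:
        return self.anchor.base

    @property
    def intron_offset(self) -> int:
        return self.anchor.offset


def parse_hgvs_c(notation: str, model: GeneModel) -> HgvsAnchor:
    """Parse an HGVS-style CDS substitution such as ``c.211-10C>G``.

    Tolerates a missing dot and stray whitespace.  The intron offset is
    signed along the direction of transcription (negative = upstream of the
    anchored exonic base, i.e. on the acceptor side of the intron).
    """
    m = HGVS_C_RE.match(notation.strip())
    if m is None:
        raise ValueError(f"malformed HGVS c. notation: {notation!r}")
    base = int(m.group("base"))
    offset = int(m.group("offset") or 0)
    anchor = CdsAnchor(base, offset)
    g = model.genomic_from_anchor(anchor)  # raises if offset leaves the intron
    ref, alt = m.group("ref"), m.group("alt")
    return HgvsAnchor(
        anchor=anchor,
        ref=ref,
        alt=alt,
        genomic_pos=g,
        ref_fwd=_transcribed(ref, model.strand),
        alt_fwd=_transcribed(alt, model.strand),
    )
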