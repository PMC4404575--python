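"""Gene models and coordinate arithmetic.

A :class:`GeneModel` is a single stranded multi-exon transcript with an
annotated CDS.  It is the coordinate hub of the package: every other module
(consequence classification, splice-junction annotation, acceptor-window
extraction, HGVS ``c.`` parsing) funnels its genomic/transcript conversions
through here so strand handling lives in exactly one place.

Conventions
-----------
* Genomic coordinates are 1-based inclusive (VCF/GFF style).
* Transcript coordinates (``t``) are 1-based along the mature mRNA in the
  direction of transcription.
* CDS coordinates (``c``) follow HGVS: ``c.1`` is the A of the start codon;
  intronic positions are anchored to the nearest exonic base with a signed
  offset (``c.211-10`` = 10 nt upstream, on the intron side, of the exonic
  base at ``c.211``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = ["GeneModel", "CdsAnchor", "HGVS_C_RE"]


@dataclass(frozen=True)
class CdsAnchor:
    """An HGVS-style CDS position: exonic base plus intronic offset.

    ``base`` is the CDS coordinate of the anchoring exonic base (positive
    within the CDS; negative values count into the 5' UTR).  ``offset`` is 0
    for exonic positions, negative for intronic positions upstream of the
    anchor (acceptor side), positive for downstream (donor side).
    """

    base: int
    offset: int = 0

    def __str__(self) -> str:
        off = ""
        if self.offset:
            off = f"{self.offset:+d}"
        return f"c.{self.base}{off}"


class GeneModel:
    """Stranded multi-exon transcript with CDS annotation.

    Parameters
    ----------
    gene_id, chrom, strand :
        Identity of the transcript; ``strand`` is ``'+'`` or ``'-'``.
    exons :
        Genomic ``(start, end)`` pairs, 1-based inclusive, given in
        *transcript* order (descending genomic coordinates on the minus
        strand).
    cds_start_t, cds_end_t :
        Transcript coordinates of the first and last CDS base (the stop
        codon's last base), 1-based.
    """

    def __init__(
        self,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: list[tuple[int, int]],
        cds_start_t: int,
        cds_end_t: int,
    ):
        if strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        for s, e in exons:
            if s > e:
                raise ValueError(f"exon start {s} > end {e}")
        if strand == "+":
            if any(exons[i][1] >= exons[i + 1][0] for i in range(len(exons) - 1)):
                raise ValueError("exons not in ascending transcript order")
        else:
            if any(exons[i][0] <= exons[i + 1][1] for i in range(len(exons) - 1)):
                raise ValueError("exons not in descending transcript order")
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.exons = [tuple(x) for x in exons]
        self.cds_start_t = cds_start_t
        self.cds_end_t = cds_end_t
        if not (1 <= cds_start_t <= cds_end_t <= self.transcript_length):
            raise ValueError("CDS outside transcript")

    # ------------------------------------------------------------------ #
    # basic geometry

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_length(self, i: int) -> int:
        s, e = self.exons[i]
        return e - s + 1

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end_t - self.cds_start_t + 1

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min, max) of the transcript footprint."""
        los = [s for s, _ in self.exons]
        his = [e for _, e in self.exons]
        return min(los), max(his)

    def exon_t_span(self, i: int) -> tuple[int, int]:
        """Transcript-coordinate (first, last) of exon ``i`` (0-based index)."""
        start = 1 + sum(self.exon_length(j) for j in range(i))
        return start, start + self.exon_length(i) - 1

    # ------------------------------------------------------------------ #
    # genomic <-> transcript

    def t2g(self, t: int) -> int:
        """Transcript coordinate to genomic coordinate."""
        if not 1 <= t <= self.transcript_length:
            raise ValueError(f"transcript position {t} out of range")
        for i, (s, e) in enumerate(self.exons):
            t0, t1 = self.exon_t_span(i)
            if t0 <= t <= t1:
                if self.strand == "+":
                    return s + (t - t0)
                return e - (t - t0)
        raise AssertionError("unreachable")

    def g2t(self, g: int) -> int | None:
        """Genomic coordinate to transcript coordinate; None if intronic
        or outside the transcript."""
        for i, (s, e) in enumerate(self.exons):
            if s <= g <= e:
                t0, _ = self.exon_t_span(i)
                if self.strand == "+":
                    return t0 + (g - s)
                return t0 + (e - g)
        return None

    def exon_of_genomic(self, g: int) -> int | None:
        for i, (s, e) in enumerate(self.exons):
            if s <= g <= e:
                return i
        return None

    def intron_of_genomic(self, g: int) -> int | None:
        """Index of the intron containing ``g`` (intron ``i`` lies between
        exons ``i`` and ``i+1`` in transcript order), else None."""
        for i in range(self.n_exons - 1):
            a = self.exons[i]
            b = self.exons[i + 1]
            if self.strand == "+":
                lo, hi = a[1] + 1, b[0] - 1
            else:
                lo, hi = b[1] + 1, a[0] - 1
            if lo <= g <= hi:
                return i
        return None

    # ------------------------------------------------------------------ #
    # splice sites

    def donor_site(self, intron: int) -> int:
        """Genomic coordinate of the last exonic base of the exon upstream
        of ``intron`` (transcript order)."""
        s, e = self.exons[intron]
        return e if self.strand == "+" else s

    def acceptor_site(self, intron: int) -> int:
        """Genomic coordinate of the first exonic base of the exon
        downstream of ``intron``."""
        s, e = self.exons[intron + 1]
        return s if self.strand == "+" else e

    def junction(self, intron: int) -> tuple[int, int]:
        """Genomic (left_end, right_start) of the splice junction across
        ``intron`` on the forward genome axis, as seen in gapped alignments."""
        d, a = self.donor_site(intron), self.acceptor_site(intron)
        return (d, a) if d < a else (a, d)

    def skip_junction(self, exon: int) -> tuple[int, int]:
        """Genomic (left_end, right_start) of the junction that skips an
        internal exon, joining its neighbours directly."""
        if exon <= 0 or exon >= self.n_exons - 1:
            raise ValueError("skip junction requires an internal exon")
        d = self.donor_site(exon - 1)
        a = self.acceptor_site(exon)
        return (d, a) if d < a else (a, d)

    def shift_acceptor(self, g_acceptor: int, shift: int) -> int:
        """Genomic coordinate of an acceptor moved ``shift`` nt in the
        direction of transcription (positive = into the exon)."""
        return g_acceptor + shift if self.strand == "+" else g_acceptor - shift

    # ------------------------------------------------------------------ #
    # CDS / HGVS coordinates

    def c_from_t(self, t: int) -> int:
        """CDS coordinate of an exonic transcript position.

        Positions 5' of the CDS return negative values (HGVS ``c.-n``);
        positions 3' of the stop return ``cds_length + n`` (rendered
        externally as ``c.*n`` is out of scope — the fixture genes keep all
        analysed positions within the CDS).
        """
        if t >= self.cds_start_t:
            return t - self.cds_start_t + 1
        return t - self.cds_start_t  # negative, UTR

    def t_from_c(self, c: int) -> int:
        if c > 0:
            return self.cds_start_t + c - 1
        if c < 0:
            return self.cds_start_t + c
        raise ValueError("c.0 does not exist")

    def anchor_from_genomic(self, g: int) -> CdsAnchor:
        """HGVS-style CDS anchor for any genomic position inside the
        transcript footprint (exonic or intronic)."""
        t = self.g2t(g)
        if t is not None:
            return CdsAnchor(self.c_from_t(t))
        intron = self.intron_of_genomic(g)
        if intron is None:
            raise ValueError(f"position {g} outside transcript footprint")
        donor_g = self.donor_site(intron)
        acceptor_g = self.acceptor_site(intron)
        d_donor = abs(g - donor_g)  # nt into intron from donor side
        d_accept = abs(acceptor_g - g)
        if d_donor <= d_accept:
            base = self.c_from_t(self.g2t(donor_g))
            return CdsAnchor(base, d_donor)
        base = self.c_from_t(self.g2t(acceptor_g))
        return CdsAnchor(base, -d_accept)

    def genomic_from_anchor(self, anchor: CdsAnchor) -> int:
        """Inverse of :meth:`anchor_from_genomic` (strand-corrected)."""
        t = self.t_from_c(anchor.base)
        g_exonic = self.t2g(t)
        if anchor.offset == 0:
            return g_exonic
        step = 1 if self.strand == "+" else -1
        # positive offset walks downstream of a donor, negative upstream
        # of an acceptor, both along the direction of transcription
        g = g_exonic + step * anchor.offset
        if self.intron_of_genomic(g) is None:
            raise ValueError(f"offset {anchor.offset} from c.{anchor.base} "
                             "walks out of the intron")
        return g

    # ------------------------------------------------------------------ #
    # sequence

    def transcript_seq(self, chrom_seq: str) -> str:
        """Spliced mRNA sequence (transcribed strand) from the plus-strand
        chromosome sequence (python string, index 0 = position 1)."""
        parts = []
        for s, e in self.exons:
            block = chrom_seq[s - 1 : e]
            if self.strand == "-":
                block = str(Seq(block).reverse_complement())
            parts.append(block)
        return "".join(parts)

    def cds_seq(self, chrom_seq: str) -> str:
        return self.transcript_seq(chrom_seq)[self.cds_start_t - 1 : self.cds_end_t]

    def protein_seq(self, chrom_seq: str) -> str:
        return str(Seq(self.cds_seq(chrom_seq)).translate(to_stop=False))


HGVS_C_RE = re.compile(
    r"^c\.?\s*(?P<base>-?\d+)(?P<offset>[+-]\d+)?\s*"
    r"(?P<ref>[ACGT])\s*>\s*(?P<alt>[ACGT])$"
)
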