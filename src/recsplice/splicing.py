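"""Splice-aberration detection from RNA-seq junction evidence.

Works entirely from splice-junction read counts — the gapped (``N`` CIGAR)
alignments spanning an intron — without exon-body coverage.  A junction is
keyed by its two flanking exonic bases on the forward genome axis:
``(chrom, donor_end, acceptor_start)`` with ``donor_end < acceptor_start``,
both 1-based, regardless of the transcribed strand.

For an internal exon the percent-spliced-in is

    PSI = inclusion / (inclusion + skip)

where ``inclusion`` summarises the two flanking inclusion junctions (their
average, rounded half-up, so one transcript spanning both junctions is not
counted twice) and ``skip`` counts junctions joining the neighbouring exons
directly.  Cryptic-acceptor usage appears as junctions whose acceptor side
is shifted by a few nucleotides relative to an annotated exon start; a
genuine acceptor must be immediately preceded by AG on the transcribed
strand.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from Bio.Seq import Seq

from .model import GeneModel

__all__ = [
    "JunctionTable",
    "SpliceEvent",
    "Isoform",
    "RtPcrProduct",
    "extract_junctions",
    "junctions_from_cigar",
    "exon_psi",
    "detect_events",
    "insilico_rtpcr",
]

JUNCTION_COLUMNS = ["chrom", "donor_end", "acceptor_start", "sample", "count"]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class JunctionTable:
    """Per-sample splice-junction read counts.

    Backed by a DataFrame with columns ``chrom, donor_end, acceptor_start,
    sample, count`` (coordinates 1-based inclusive exonic bases flanking
    the gap).
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=JUNCTION_COLUMNS)
        missing = set(JUNCTION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"junction table missing columns {sorted(missing)}")
        df = df[JUNCTION_COLUMNS].copy()
        df["donor_end"] = df["donor_end"].astype(int)
        df["acceptor_start"] = df["acceptor_start"].astype(int)
        df["count"] = df["count"].astype(int)
        if (df["donor_end"] >= df["acceptor_start"]).any():
            raise ValueError("donor_end must be < acceptor_start")
        if (df["count"] < 0).any():
            raise ValueError("junction counts must be >= 0")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def add(self, chrom: str, donor_end: int, acceptor_start: int,
            sample: str, count: int = 1) -> None:
        key = (
            (self.df["chrom"] == chrom)
            & (self.df["donor_end"] == donor_end)
            & (self.df["acceptor_start"] == acceptor_start)
            & (self.df["sample"] == sample)
        )
        if key.any():
            self.df.loc[key, "count"] += count
        else:
            self.df.loc[len(self.df)] = [chrom, donor_end, acceptor_start,
                                         sample, count]

    def count(self, sample: str, chrom: str, donor_end: int,
              acceptor_start: int) -> int:
        key = (
            (self.df["chrom"] == chrom)
            & (self.df["donor_end"] == donor_end)
            & (self.df["acceptor_start"] == acceptor_start)
            & (self.df["sample"] == sample)
        )
        return int(self.df.loc[key, "count"].sum())

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.df[self.df["sample"] == sample].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "JunctionTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str,
                                                      "sample": str}))


@dataclass
class SpliceEvent:
    """A called splicing aberration for one sample and one exon."""

    type: str  # "exon_skip" | "cryptic_acceptor"
    gene_id: str
    chrom: str
    exon: int  # 1-based exon index in transcript order
    sample: str
    inclusion_count: int = 0
    skip_count: int = 0
    psi: float = float("nan")
    acceptor_shift: int | None = None  # signed nt, + = into the exon
    ag_upstream: bool | None = None
    isoform_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in ("exon_skip", "cryptic_acceptor"):
            raise ValueError(f"unknown event type {self.type!r}")
        if not math.isnan(self.psi) and not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi {self.psi} outside [0, 1]")

    @property
    def skip_fraction(self) -> float:
        return 1.0 - self.psi

    def as_dict(self) -> dict:
        return {
            "type": self.type,
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "exon": self.exon,
            "sample": self.sample,
            "inclusion_count": self.inclusion_count,
            "skip_count": self.skip_count,
            "psi": None if math.isnan(self.psi) else self.psi,
            "acceptor_shift": self.acceptor_shift,
            "ag_upstream": self.ag_upstream,
            "isoform_fractions": self.isoform_fractions,
        }


def junctions_from_cigar(pos: int, cigar: str, anchor_min: int = 8
                         ) -> list[tuple[int, int]]:
    """Junctions implied by one alignment: (donor_end, acceptor_start) per
    ``N`` gap whose flanking aligned blocks are both >= ``anchor_min``.

    ``pos`` is the 1-based leftmost reference position.  M/=/X consume
    reference and count toward anchors; D consumes reference silently;
    I/S/H/P consume no reference.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or sum(len(n) + 1 for n, _ in ops) != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    junctions = []
    ref = pos
    anchor = 0  # aligned bases since read start or last gap
    pending = None  # (donor_end, acceptor_start, left_anchor)
    for num, op in ops:
        n = int(num)
        if op in "M=X":
            anchor += n
            ref += n
        elif op == "D":
            ref += n
        elif op == "N":
            if pending is not None and pending[2] >= anchor_min and anchor >= anchor_min:
                junctions.append(pending[:2])
            pending = (ref - 1, ref + n, anchor)
            ref += n
            anchor = 0
        # I, S, H, P: no reference consumed, anchors unaffected
    if pending is not None and pending[2] >= anchor_min and anchor >= anchor_min:
        junctions.append(pending[:2])
    return junctions


def extract_junctions(source, anchor_min: int = 8,
                      sample: str | None = None) -> JunctionTable:
    """Build a junction table from gapped alignments or a junction TSV.

    ``source`` may be a path to a SAM file (read group / one sample,
    ``sample`` names it), a path to a junction TSV, or an iterable of
    ``pysam.AlignedSegment``.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix in (".tsv", ".txt"):
            return JunctionTable.from_tsv(path)
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            return _junctions_from_reads(sam, anchor_min, sample or "sample")
    return _junctions_from_reads(source, anchor_min, sample or "sample")


def _junctions_from_reads(reads, anchor_min: int, sample: str) -> JunctionTable:
    counts: dict[tuple[str, int, int], int] = {}
    for read in reads:
        if read.is_unmapped or read.cigarstring is None:
            continue
        chrom = read.reference_name
        for d, a in junctions_from_cigar(read.reference_start + 1,
                                         read.cigarstring, anchor_min):
            counts[(chrom, d, a)] = counts.get((chrom, d, a), 0) + 1
    rows = [
        {"chrom": c, "donor_end": d, "acceptor_start": a,
         "sample": sample, "count": n}
        for (c, d, a), n in sorted(counts.items())
    ]
    return JunctionTable(pd.DataFrame(rows, columns=JUNCTION_COLUMNS))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def exon_psi(junctions: JunctionTable, model: GeneModel, exon: int,
             sample: str) -> SpliceEvent:
    """Percent-spliced-in of an internal exon (1-based index) for one sample.

    Inclusion support is the average of the two flanking inclusion
    junctions, rounded half-up; skip support is the direct
    neighbour-to-neighbour junction.
    """
    i = exon - 1
    if i <= 0 or i >= model.n_exons - 1:
        raise ValueError(f"exon {exon} is terminal; PSI needs an internal exon")
    up = model.junction(i - 1)
    down = model.junction(i)
    skip_j = model.skip_junction(i)
    c = model.chrom
    j_up = junctions.count(sample, c, *up)
    j_down = junctions.count(sample, c, *down)
    skip = junctions.count(sample, c, *skip_j)
    inclusion = _round_half_up((j_up + j_down) / 2)
    total = inclusion + skip
    psi = inclusion / total if total else float("nan")
    return SpliceEvent(
        type="exon_skip",
        gene_id=model.gene_id,
        chrom=c,
        exon=exon,
        sample=sample,
        inclusion_count=inclusion,
        skip_count=skip,
        psi=psi,
    )


def _annotated_junctions(model: GeneModel) -> set[tuple[int, int]]:
    juncs = {model.junction(i) for i in range(model.n_exons - 1)}
    juncs |= {model.skip_junction(i) for i in range(1, model.n_exons - 1)}
    return juncs


def _ag_upstream(model: GeneModel, chrom_seq: str, g_acceptor: int) -> bool:
    """Is the acceptor at genomic position ``g_acceptor`` immediately
    preceded by AG on the transcribed strand?"""
    if model.strand == "+":
        di = chrom_seq[g_acceptor - 3 : g_acceptor - 1]
        return di.upper() == "AG"
    di = chrom_seq[g_acceptor : g_acceptor + 2]
    return str(Seq(di).reverse_complement()).upper() == "AG"


def detect_events(
    junctions: JunctionTable,
    model: GeneModel,
    sample: str,
    min_reads: int = 10,
    psi_max_normal: float = 0.8,
    max_shift: int = 10,
    chrom_seq: str | None = None,
) -> list[SpliceEvent]:
    """Call exon-skip and cryptic-acceptor events for one sample.

    Exon skips are internal exons with PSI below ``psi_max_normal`` at
    coverage >= ``min_reads``.  Cryptic acceptors are unannotated junctions
    sharing a donor with an annotated junction whose acceptor is shifted by
    at most ``max_shift`` nt from an annotated exon start; if ``chrom_seq``
    is supplied, the shifted acceptor is checked for an upstream AG.  The
    exon-skip event carries the fractions of aberrant reads using the plain
    skip vs the skip-plus-cryptic junction.
    """
    events: list[SpliceEvent] = []
    annotated = _annotated_junctions(model)
    known_donors = {model.donor_site(i) for i in range(model.n_exons - 1)}
    sample_df = junctions.for_sample(sample)
    sample_df = sample_df[sample_df["chrom"] == model.chrom]

    # cryptic acceptors -------------------------------------------------
    cryptic: list[SpliceEvent] = []
    cryptic_counts: dict[int, int] = {}  # skipped-exon index -> count
    for _, row in sample_df.iterrows():
        j = (int(row["donor_end"]), int(row["acceptor_start"]))
        if j in annotated or row["count"] == 0:
            continue
        if j[0] not in known_donors and j[1] not in known_donors:
            continue
        # the acceptor side is the end that is NOT the known donor
        acc_obs = j[1] if j[0] in known_donors else j[0]
        donor_obs = j[0] if j[0] in known_donors else j[1]
        for k in range(1, model.n_exons):
            g_acc = model.acceptor_site(k - 1)
            # shift along the direction of transcription (+ = into exon)
            shift = (acc_obs - g_acc) if model.strand == "+" else (g_acc - acc_obs)
            if shift == 0 or abs(shift) > max_shift:
                continue
            ag = (
                _ag_upstream(model, chrom_seq, acc_obs)
                if chrom_seq is not None
                else None
            )
            cryptic.append(
                SpliceEvent(
                    type="cryptic_acceptor",
                    gene_id=model.gene_id,
                    chrom=model.chrom,
                    exon=k + 1,
                    sample=sample,
                    skip_count=int(row["count"]),
                    acceptor_shift=int(shift),
                    ag_upstream=ag,
                )
            )
            # does this junction also skip the intervening exon(s)?
            donor_exon = next(
                (i for i in range(model.n_exons - 1)
                 if model.donor_site(i) == donor_obs), None
            )
            if donor_exon is not None and k - donor_exon == 2:
                skipped = donor_exon + 1  # 0-based internal exon skipped
                cryptic_counts[skipped] = (
                    cryptic_counts.get(skipped, 0) + int(row["count"])
                )
            break

    # exon skips --------------------------------------------------------
    for exon in range(2, model.n_exons):  # 1-based internal exons
        ev = exon_psi(junctions, model, exon, sample)
        extra = cryptic_counts.get(exon - 1, 0)
        skip_total = ev.skip_count + extra
        total = ev.inclusion_count + skip_total
        if total < min_reads or total == 0:
            continue
        psi = ev.inclusion_count / total
        if psi >= psi_max_normal:
            continue
        fractions = {}
        if skip_total:
            fractions = {
                "skip_only": ev.skip_count / skip_total,
                "skip_cryptic": extra / skip_total,
            }
        events.append(
            SpliceEvent(
                type="exon_skip",
                gene_id=model.gene_id,
                chrom=model.chrom,
                exon=exon,
                sample=sample,
                inclusion_count=ev.inclusion_count,
                skip_count=skip_total,
                psi=psi,
                isoform_fractions=fractions,
            )
        )
    events.extend(cryptic)
    return events


@dataclass(frozen=True)
class Isoform:
    """A spliced isoform: retained exons (1-based, transcript order) and
    nucleotides trimmed from an exon's 5' (acceptor) end, as produced by a
    shifted cryptic acceptor."""

    retained_exons: tuple[int, ...]
    acceptor_trim: dict = field(default_factory=dict, hash=False)


@dataclass(frozen=True)
class RtPcrProduct:
    length: int
    sequence: str


def insilico_rtpcr(
    model: GeneModel,
    chrom_seq: str,
    fwd_primer: str,
    rev_primer: str,
    isoform: Isoform,
) -> RtPcrProduct | None:
    """Predict the RT-PCR product for a primer pair on a spliced isoform.

    Primers are given 5'->3': the forward primer matches the transcript
    sense strand, the reverse primer the antisense strand.  Returns the
    product spanning the outer primer ends, or ``None`` when either primer
    has no perfect site on the isoform (e.g. it sits in a skipped exon).
    """
    parts = []
    for e in isoform.retained_exons:
        s, eo = model.exons[e - 1]
        block = chrom_seq[s - 1 : eo]
        if model.strand == "-":
            block = str(Seq(block).reverse_complement())
        trim = isoform.acceptor_trim.get(e, 0)
        parts.append(block[trim:])
    transcript = "".join(parts).upper()

    fwd = fwd_primer.upper()
    rev_rc = str(Seq(rev_primer.upper()).reverse_complement())
    i = transcript.find(fwd)
    j = transcript.find(rev_rc)
    if i < 0 or j < 0:
        return None
    end = j + len(rev_rc)
    if end <= i:
        return None
    product = transcript[i:end]
    return RtPcrProduct(length=len(product), sequence=product)
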