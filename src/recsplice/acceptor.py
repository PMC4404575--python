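"""Acceptor splice-site scoring and cross-species conservation.

A canonical GT-AG acceptor ends an intron with a polypyrimidine tract
followed by the invariant AG dinucleotide.  The score used here is a
deliberately transparent one: the fraction of pyrimidines (C/T) over the
tract positions -16..-5, gated to zero when the AG at -2/-1 is lost.  It
makes the effect of a single pyrimidine->purine substitution in the tract
exact (a drop of 1/12) and auditable, which is the point — the question it
answers is "does this intronic variant weaken the acceptor", not "what is
the spliceosome's binding energy".

Windows are taken on the transcribed strand over positions -20..+3
relative to the acceptor junction (+1 = first exonic base), 23 nt total.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .model import GeneModel
from .varfilter import VariantRecord

WINDOW_UP = 20  # intronic positions -20..-1
WINDOW_DOWN = 3  # exonic positions +1..+3
WINDOW_LEN = WINDOW_UP + WINDOW_DOWN
TRACT = (-16, -5)  # inclusive offsets scored for pyrimidine content
TRACT_LEN = TRACT[1] - TRACT[0] + 1
DEFAULT_DISRUPT_THRESHOLD = 1 / 24

PYRIMIDINES = frozenset("CT")

__all__ = [
    "AcceptorWindow",
    "AcceptorScoreResult",
    "score_acceptor",
    "acceptor_window",
    "variant_acceptor_delta",
    "conservation_fraction",
]


@dataclass(frozen=True)
class AcceptorWindow:
    """Transcribed-strand sequence over -20..+3 around an acceptor."""

    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != WINDOW_LEN:
            raise ValueError(
                f"acceptor window must be {WINDOW_LEN} nt, got {len(self.seq)}"
            )
        if set(self.seq.upper()) - set("ACGTN"):
            raise ValueError(f"invalid characters in window {self.seq!r}")

    def base(self, offset: int) -> str:
        """Base at a signed offset (-20..-1 intronic, +1..+3 exonic)."""
        if offset == 0 or not -WINDOW_UP <= offset <= WINDOW_DOWN:
            raise ValueError(f"offset {offset} outside window")
        idx = offset + WINDOW_UP if offset < 0 else WINDOW_UP + offset - 1
        return self.seq[idx].upper()

    def with_base(self, offset: int, base: str) -> "AcceptorWindow":
        idx = offset + WINDOW_UP if offset < 0 else WINDOW_UP + offset - 1
        s = list(self.seq)
        s[idx] = base
        return AcceptorWindow("".join(s))

    @property
    def ag_intact(self) -> bool:
        return self.base(-2) == "A" and self.base(-1) == "G"


def score_acceptor(window: AcceptorWindow) -> float:
    """Pyrimidine fraction of the tract, gated by the AG dinucleotide.

    N counts as purine (conservatively weakening).  Range [0, 1].
    """
    if not window.ag_intact:
        return 0.0
    pyr = sum(
        window.base(o) in PYRIMIDINES for o in range(TRACT[0], TRACT[1] + 1)
    )
    return pyr / TRACT_LEN


@dataclass(frozen=True)
class AcceptorScoreResult:
    """Effect of a variant on one acceptor window.

    ``position`` is the signed offset of the variant within the window
    (-20..+3); ``delta = alt_score - ref_score``; ``applicable`` is False
    when the variant touches no acceptor window of the model.
    """

    applicable: bool
    intron: int | None = None  # 1-based intron whose acceptor is scored
    position: int | None = None
    ref_score: float | None = None
    alt_score: float | None = None
    delta: float | None = None
    ag_intact_ref: bool | None = None
    ag_intact_alt: bool | None = None
    disrupted: bool = False


def acceptor_window(model: GeneModel, chrom_seq: str, intron: int
                    ) -> AcceptorWindow:
    """Extract the -20..+3 window around the acceptor of ``intron``
    (0-based index) on the transcribed strand."""
    g = model.acceptor_site(intron)
    if model.strand == "+":
        seq = chrom_seq[g - 1 - WINDOW_UP : g - 1 + WINDOW_DOWN]
    else:
        block = chrom_seq[g - WINDOW_DOWN : g + WINDOW_UP]
        seq = str(Seq(block).reverse_complement())
    return AcceptorWindow(seq.upper())


def _window_offset(model: GeneModel, intron: int, g: int) -> int | None:
    """Signed window offset of genomic position ``g`` relative to the
    acceptor of ``intron``, or None if outside -20..+3."""
    acc = model.acceptor_site(intron)
    off = (g - acc) if model.strand == "+" else (acc - g)
    # off = 0 at the first exonic base -> offset +1; negative = intronic
    offset = off + 1 if off >= 0 else off
    if -WINDOW_UP <= offset <= WINDOW_DOWN and offset != 0:
        return offset
    return None


def variant_acceptor_delta(
    model: GeneModel,
    chrom_seq: str,
    variant: VariantRecord,
    disrupt_threshold: float = DEFAULT_DISRUPT_THRESHOLD,
) -> AcceptorScoreResult:
    """Score the reference and alternate acceptor windows for a variant.

    Flags ``disrupted`` when the score drops by at least
    ``disrupt_threshold`` or the AG dinucleotide is lost.  Variants outside
    every acceptor window of the model return an inapplicable result.
    """
    if variant.chrom != model.chrom or not variant.is_snv:
        return AcceptorScoreResult(applicable=False)
    for intron in range(model.n_exons - 1):
        offset = _window_offset(model, intron, variant.pos)
        if offset is None:
            continue
        ref_w = acceptor_window(model, chrom_seq, intron)
        ref_t = (
            variant.ref if model.strand == "+"
            else str(Seq(variant.ref).complement())
        ).upper()
        alt_t = (
            variant.alt if model.strand == "+"
            else str(Seq(variant.alt).complement())
        ).upper()
        if ref_w.base(offset) != ref_t:
            raise ValueError(
                f"reference mismatch in acceptor window: window has "
                f"{ref_w.base(offset)!r} at {offset}, variant ref {ref_t!r}"
            )
        alt_w = ref_w.with_base(offset, alt_t)
        ref_score = score_acceptor(ref_w)
        alt_score = score_acceptor(alt_w)
        delta = alt_score - ref_score
        ag_lost = ref_w.ag_intact and not alt_w.ag_intact
        return AcceptorScoreResult(
            applicable=True,
            intron=intron + 1,
            position=offset,
            ref_score=ref_score,
            alt_score=alt_score,
            delta=delta,
            ag_intact_ref=ref_w.ag_intact,
            ag_intact_alt=alt_w.ag_intact,
            disrupted=bool(delta <= -disrupt_threshold or ag_lost),
        )
    return AcceptorScoreResult(applicable=False)


def conservation_fraction(
    column: dict[str, str] | list[str],
    reference_base: str,
    gaps_as_mismatch: bool = False,
) -> tuple[int, int]:
    """(matching, total) species whose aligned base equals the reference.

    Gap characters are excluded from the denominator by default; with
    ``gaps_as_mismatch`` they count as non-matching.  Comparison is
    case-insensitive; N never matches.
    """
    bases = list(column.values()) if isinstance(column, dict) else list(column)
    if not bases:
        raise ValueError("empty alignment column")
    ref = reference_base.upper()
    match = total = 0
    for b in bases:
        b = b.upper()
        if b in "-.":
            if gaps_as_mismatch:
                total += 1
            continue
        total += 1
        if b == ref and b != "N":
            match += 1
    return match, total
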