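"""Autozygosity mapping of a recessive locus from SNP-array genotypes.

In an inbred livestock population, all individuals affected by a recessive
defect descend from one carrier founder through both parents and are
therefore homozygous identical-by-descent (autozygous) for the founder's
chromosome segment around the causal mutation.  Locating the (usually
unique) segment at which every case is homozygous for the *same* allele at
every marker maps the locus; contrasting the frequency of that
haplotype-homozygosity against healthy controls scores its significance.

Two complementary views are provided:

* :func:`find_shared_homozygous_segment` — the direct autozygosity view:
  the longest run of consecutive markers at which all cases are homozygous
  for one shared allele.
* :func:`haplotype_sharing_scan` — a sliding-window case/control scan using
  a one-sided Fisher exact test per window with a Bonferroni threshold.
  This is a transparent substitute for mixed-model haplotype association
  software: it produces the same qualitative output (a single significant
  peak plus a shared segment) without the variance-component machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "Interval",
    "ScanResult",
    "find_shared_homozygous_segment",
    "haplotype_sharing_scan",
    "interval_length_mb",
]


@dataclass
class GenotypeMatrix:
    """Samples x markers genotype matrix with its marker map.

    ``genotypes`` holds alt-allele dosages 0/1/2 with :data:`MISSING` (-1)
    for no-calls, one row per sample.  ``markers`` is a DataFrame with
    columns ``id, chrom, pos, ref, alt``, sorted by (chrom, pos).
    """

    samples: list[str]
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or -1 (missing)")
        m = self.markers
        order = np.lexsort((m["pos"].to_numpy(), m["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(m))):
            raise ValueError("markers must be sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = []
        lookup = {s: i for i, s in enumerate(self.samples)}
        for s in sample_ids:
            if s not in lookup:
                raise KeyError(f"unknown sample id {s!r}")
            idx.append(lookup[s])
        return GenotypeMatrix(list(sample_ids), self.markers,
                              self.genotypes[idx, :])

    def subset_chrom(self, chrom: str) -> "GenotypeMatrix":
        mask = (self.markers["chrom"] == chrom).to_numpy()
        return GenotypeMatrix(
            self.samples,
            self.markers.loc[mask].reset_index(drop=True),
            self.genotypes[:, mask],
        )


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval covering ``n_markers`` markers."""

    chrom: str
    start: int
    end: int
    n_markers: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ScanResult:
    """Sliding-window haplotype-sharing scan output.

    ``track`` has one row per window: ``start, end, n_markers,
    cases_shared, control_hom, p, neg_log10_p``.  ``best`` is the index of
    the most significant window (smallest p, leftmost on ties) and
    ``bonferroni`` the adjusted significance threshold on the p scale.
    """

    chrom: str
    track: pd.DataFrame
    best: int | None
    bonferroni: float

    @property
    def best_window(self) -> pd.Series | None:
        return None if self.best is None else self.track.iloc[self.best]

    @property
    def significant(self) -> bool:
        bw = self.best_window
        return bw is not None and bool(bw["p"] <= self.bonferroni)


def _hom_shared_mask(genos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker: is every sample homozygous for one shared allele?

    Missing calls are treated as compatible; a marker where every sample is
    missing cannot establish a shared allele and does not qualify.
    Returns (qualifies, shared_allele) arrays over markers.
    """
    het = genos == 1
    miss = genos == MISSING
    any_het = het.any(axis=0)
    has_ref = (genos == 0).any(axis=0)
    has_alt = (genos == 2).any(axis=0)
    all_missing = miss.all(axis=0)
    qualifies = ~any_het & ~(has_ref & has_alt) & ~all_missing
    shared = np.where(has_alt, 2, 0).astype(np.int8)
    return qualifies, shared


def find_shared_homozygous_segment(
    cases: GenotypeMatrix, chrom: str
) -> Interval | None:
    """Longest run of consecutive markers at which all cases are homozygous
    for the same allele.

    Ties on run length are broken toward the leftmost start; the interval
    spans from the first to the last qualifying marker position.  Returns
    ``None`` when no marker qualifies.
    """
    sub = cases.subset_chrom(chrom)
    if sub.n_markers == 0:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    if sub.n_samples == 0:
        raise ValueError("no case samples supplied")
    qual, _ = _hom_shared_mask(sub.genotypes)
    best_len, best_start = 0, -1
    run_start = None
    for j, q in enumerate(np.append(qual, False)):
        if q and run_start is None:
            run_start = j
        elif not q and run_start is not None:
            length = j - run_start
            if length > best_len:
                best_len, best_start = length, run_start
            run_start = None
    if best_len == 0:
        return None
    pos = sub.markers["pos"].to_numpy()
    return Interval(
        chrom=chrom,
        start=int(pos[best_start]),
        end=int(pos[best_start + best_len - 1]),
        n_markers=best_len,
    )


def _window_shared_haplotype(
    genos: np.ndarray, max_missing_frac: float
) -> np.ndarray | None:
    """Shared homozygous haplotype carried by *all* samples in the window,
    or None if any sample is heterozygous, discordant, or too incomplete.

    The returned vector holds the shared allele (0/2) per marker, with
    :data:`MISSING` marking markers at which every sample is missing
    (wildcard positions).
    """
    n, w = genos.shape
    miss = genos == MISSING
    if (miss.sum(axis=1) > max_missing_frac * w).any():
        return None
    if (genos == 1).any():
        return None
    has_ref = (genos == 0).any(axis=0)
    has_alt = (genos == 2).any(axis=0)
    if (has_ref & has_alt).any():
        return None
    shared = np.full(w, MISSING, dtype=np.int8)
    shared[has_ref] = 0
    shared[has_alt] = 2
    return shared


def _matches_haplotype(
    genos: np.ndarray, shared: np.ndarray, max_missing_frac: float
) -> np.ndarray:
    """Boolean per sample: homozygous for ``shared`` across the window."""
    n, w = genos.shape
    miss = genos == MISSING
    ok_missing = miss.sum(axis=1) <= max_missing_frac * w
    fixed = shared != MISSING
    agree = (genos[:, fixed] == shared[fixed]) | miss[:, fixed]
    hom_only = ~(genos == 1).any(axis=1)
    return ok_missing & hom_only & agree.all(axis=1)


def haplotype_sharing_scan(
    cases: GenotypeMatrix,
    controls: GenotypeMatrix,
    window_size_markers: int = 20,
    alpha: float = 0.05,
    max_missing_frac: float = 0.05,
) -> ScanResult:
    """Sliding-window case/control scan for shared haplotype homozygosity.

    For each window of ``window_size_markers`` consecutive markers the test
    asks whether all cases are homozygous for one shared window haplotype;
    when they are, a one-sided Fisher exact test compares the count of
    haplotype-homozygotes among cases vs controls.  Windows where the cases
    do not share a homozygous haplotype score p = 1.

    Cases and controls must be on the same marker map (same chromosome,
    same positions).
    """
    if not cases.markers["pos"].equals(controls.markers["pos"]):
        raise ValueError("cases and controls must share the same marker map")
    chroms = cases.markers["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("scan expects markers from a single chromosome")
    chrom = str(chroms[0])
    w = window_size_markers
    m = cases.n_markers
    if w < 1 or w > m:
        raise ValueError(f"window of {w} markers exceeds the {m} available")
    n_windows = m - w + 1
    pos = cases.markers["pos"].to_numpy()
    n_cases, n_ctrl = cases.n_samples, controls.n_samples

    rows = []
    for j in range(n_windows):
        cg = cases.genotypes[:, j : j + w]
        shared = _window_shared_haplotype(cg, max_missing_frac)
        if shared is None:
            rows.append((pos[j], pos[j + w - 1], w, False, 0, 1.0))
            continue
        ctrl_hom = int(
            _matches_haplotype(
                controls.genotypes[:, j : j + w], shared, max_missing_frac
            ).sum()
        )
        table = [[n_cases, 0], [ctrl_hom, n_ctrl - ctrl_hom]]
        p = float(fisher_exact(table, alternative="greater")[1])
        rows.append((pos[j], pos[j + w - 1], w, True, ctrl_hom, p))

    track = pd.DataFrame(
        rows,
        columns=["start", "end", "n_markers", "cases_shared", "control_hom", "p"],
    )
    track["neg_log10_p"] = -np.log10(np.maximum(track["p"].to_numpy(), 1e-300))
    best = int(track["p"].idxmin()) if n_windows else None
    return ScanResult(
        chrom=chrom, track=track, best=best, bonferroni=alpha / n_windows
    )


def interval_length_mb(interval: Interval) -> float:
    """Interval length in megabases, rounded half-up to one decimal.

    Matches the convention of reporting a mapped region by the distance
    between its outermost marker positions.
    """
    mb = (interval.end - interval.start) / 1e6
    return math.floor(mb * 10 + 0.5) / 10
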