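"""Windowed depth, 1B/0B and 2B/0B coverage ratios, and B-block detection.

The B chromosome is absent from the reference assembly, but its building
blocks are A-complement regions duplicated to high copy number.  Reads from
those extra copies pile onto the source loci, so the library-normalised
depth ratio of a B-carrying sample over a 0B sample rises above 1 there,
and it rises roughly twice as far in 2B as in 1B samples.  This module
computes windowed depth profiles, forms those ratios, and merges runs of
jointly elevated windows into candidate blocks ranked by how well their
enrichment follows the linear gene-dose model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mapping import Placement

__all__ = [
    "DepthProfile",
    "CoverageRatioTrack",
    "CandidateBlock",
    "Region",
    "window_depth",
    "normalize",
    "ratio_track",
    "detect_blocks",
    "rank_blocks",
    "block_size",
    "jaccard",
]

DEFAULT_WINDOW = 1_000
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_THETA = 1.5
DEFAULT_MIN_WINDOWS = 3
DEFAULT_MAX_GAP = 1


@dataclass(frozen=True)
class Region:
    """A plain genomic interval, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass
class DepthProfile:
    """Per-window read-start counts for one sample."""

    sample_id: str
    window_size: int
    counts: dict[str, np.ndarray]
    ref_lengths: dict[str, int]
    library_size: int
    genotype: str | None = None

    def check(self) -> None:
        total = int(sum(int(c.sum()) for c in self.counts.values()))
        if total != self.library_size:
            raise ValueError("window counts do not sum to library_size")


@dataclass
class CoverageRatioTrack:
    """Aligned normalized depths and B/0B ratios per window."""

    window_size: int
    pseudocount: float
    ref_lengths: dict[str, int]
    nd0: dict[str, np.ndarray]
    nd1: dict[str, np.ndarray]
    nd2: dict[str, np.ndarray]
    r1: dict[str, np.ndarray]
    r2: dict[str, np.ndarray]


@dataclass(frozen=True)
class CandidateBlock:
    """A run of windows jointly elevated in the 1B and 2B samples.

    ``dose_consistency`` is |(mean_r2 - 1) - 2*(mean_r1 - 1)|: under a
    linear gene-dose model the excess coverage in a 2B sample is twice the
    excess in a 1B sample, so values near 0 mark blocks whose signal
    behaves like a true B duplication.
    """

    scaffold: str
    start: int
    end: int
    n_windows: int
    mean_r1: float
    mean_r2: float
    cv_r2: float
    dose_consistency: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("block end must exceed start")

    @property
    def size(self) -> int:
        return self.end - self.start


def window_depth(
    alignments: Iterable[Placement | tuple[str, int]],
    ref_lengths: Mapping[str, int],
    w: int = DEFAULT_WINDOW,
    *,
    sample_id: str = "sample",
    genotype: str | None = None,
) -> DepthProfile:
    """Count primary read starts per fixed window.

    Each mapped read increments exactly one window: the one containing its
    leftmost aligned base.  Counting read starts (rather than fractional
    overlap) conserves the total — window counts sum to the library size.
    """
    if w < 50:
        raise ValueError("window size must be >= 50 bp")
    counts = {
        name: np.zeros(max(1, math.ceil(length / w)), dtype=np.int64)
        for name, length in ref_lengths.items()
    }
    total = 0
    for rec in alignments:
        if isinstance(rec, Placement):
            name, pos = rec.scaffold, rec.start
        else:
            name, pos = rec
        if name not in counts:
            raise ValueError(f"alignment to unknown reference {name!r} at position {pos}")
        counts[name][pos // w] += 1
        total += 1
    return DepthProfile(
        sample_id=sample_id,
        window_size=w,
        counts=counts,
        ref_lengths=dict(ref_lengths),
        library_size=total,
        genotype=genotype,
    )


def normalize(profile: DepthProfile) -> dict[str, np.ndarray]:
    """Reads-per-million scaling: count * 1e6 / library_size per window."""
    if profile.library_size <= 0:
        raise ValueError("cannot normalize a profile with zero library size")
    scale = 1e6 / profile.library_size
    return {name: counts * scale for name, counts in profile.counts.items()}


def _check_compatible(p0: DepthProfile, p1: DepthProfile, p2: DepthProfile) -> None:
    if not (p0.window_size == p1.window_size == p2.window_size):
        raise ValueError("profiles have mismatched window sizes")
    keys = set(p0.counts)
    if set(p1.counts) != keys or set(p2.counts) != keys:
        raise ValueError("profiles cover different scaffold sets")
    for name in keys:
        if not (len(p0.counts[name]) == len(p1.counts[name]) == len(p2.counts[name])):
            raise ValueError(f"profiles have mismatched windowing on {name}")


def ratio_track(
    p0: DepthProfile,
    p1: DepthProfile,
    p2: DepthProfile,
    alpha: float = DEFAULT_PSEUDOCOUNT,
) -> CoverageRatioTrack:
    """Per-window (nd + alpha) / (nd0 + alpha) ratios for the 1B and 2B samples.

    The pseudocount keeps empty windows finite and drives the ratio of two
    empty windows to exactly 1.
    """
    if alpha <= 0:
        raise ValueError("pseudocount alpha must be > 0")
    _check_compatible(p0, p1, p2)
    nd0, nd1, nd2 = normalize(p0), normalize(p1), normalize(p2)
    r1 = {name: (nd1[name] + alpha) / (nd0[name] + alpha) for name in nd0}
    r2 = {name: (nd2[name] + alpha) / (nd0[name] + alpha) for name in nd0}
    return CoverageRatioTrack(
        window_size=p0.window_size,
        pseudocount=alpha,
        ref_lengths=dict(p0.ref_lengths),
        nd0=nd0,
        nd1=nd1,
        nd2=nd2,
        r1=r1,
        r2=r2,
    )


def detect_blocks(
    track: CoverageRatioTrack,
    theta: float = DEFAULT_THETA,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[CandidateBlock]:
    """Merge runs of windows with r1 >= theta AND r2 >= theta into blocks.

    Requiring both ratios encodes "elevated in every B-carrying sample".
    Qualifying windows separated by at most ``max_gap`` sub-threshold
    windows join one run; runs with fewer than ``min_windows`` qualifying
    windows are dropped.  Block coordinates are window-aligned (the last
    block of a scaffold is clipped to the scaffold end).
    """
    if theta <= 1:
        raise ValueError("ratio threshold theta must be > 1")
    w = track.window_size
    blocks: list[CandidateBlock] = []
    for scaffold in track.r1:
        r1, r2 = track.r1[scaffold], track.r2[scaffold]
        qual = np.flatnonzero((r1 >= theta) & (r2 >= theta))
        if qual.size == 0:
            continue
        runs: list[list[int]] = [[int(qual[0])]]
        for idx in qual[1:]:
            if int(idx) - runs[-1][-1] - 1 <= max_gap:
                runs[-1].append(int(idx))
            else:
                runs.append([int(idx)])
        for run in runs:
            if len(run) < min_windows:
                continue
            first, last = run[0], run[-1]
            span = slice(first, last + 1)
            mean_r1 = float(np.mean(r1[span]))
            mean_r2 = float(np.mean(r2[span]))
            spread = float(np.std(r2[span], ddof=1)) if last > first else 0.0
            cv = spread / mean_r2 if mean_r2 > 0 else 0.0
            blocks.append(
                CandidateBlock(
                    scaffold=scaffold,
                    start=first * w,
                    end=min((last + 1) * w, track.ref_lengths[scaffold]),
                    n_windows=len(run),
                    mean_r1=mean_r1,
                    mean_r2=mean_r2,
                    cv_r2=cv,
                    dose_consistency=abs((mean_r2 - 1.0) - 2.0 * (mean_r1 - 1.0)),
                )
            )
    return blocks


def rank_blocks(blocks: Sequence[CandidateBlock]) -> list[CandidateBlock]:
    """Order candidate blocks from most to least assay-worthy.

    Stable sort by ascending dose consistency, then ascending within-block
    CV of r2, then descending mean r2, with genomic coordinate as the final
    tie-break.  An empty input returns an empty list.
    """
    return sorted(
        blocks,
        key=lambda b: (b.dose_consistency, b.cv_r2, -b.mean_r2, b.scaffold, b.start),
    )


def block_size(block: CandidateBlock | Region | tuple[int, int]) -> int:
    """Interval size in bp: end - start (0-based half-open coordinates)."""
    if isinstance(block, tuple):
        start, end = block
    else:
        start, end = block.start, block.end
    if end <= start:
        raise ValueError("end must exceed start")
    return end - start


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two half-open intervals on one scaffold."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0
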