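"""Exact-seed read mapper for synthetic cohorts.

A deliberately simple single-end mapper: a read is placed at the unique
reference position whose k-prefix matches exactly and whose full-length
Hamming distance is within ``max_mismatches``.  Reads with several equally
good placements are discarded as ambiguous (and counted); reads with no
acceptable placement are counted as unmapped.  This is sufficient for the
substitution-only synthetic world and keeps the coverage stage free of any
external aligner; real data should arrive as SAM/BAM instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .simulate import FastqRead

__all__ = ["Placement", "MappingResult", "build_seed_index", "map_reads_exact"]


@dataclass(frozen=True)
class Placement:
    read_name: str
    scaffold: str
    start: int  # 0-based leftmost aligned base
    mismatches: int


@dataclass
class MappingResult:
    placements: list[Placement]
    n_mapped: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0

    def summary(self) -> dict[str, int]:
        return {
            "mapped": self.n_mapped,
            "ambiguous": self.n_ambiguous,
            "unmapped": self.n_unmapped,
        }


def build_seed_index(reference: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    """Index every k-mer of the reference by its start position."""
    if k < 1:
        raise ValueError("seed length k must be >= 1")
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in reference.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Hamming distance, or limit+1 as soon as it is exceeded."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return mism
    return mism


def map_reads_exact(
    reads: Iterable[FastqRead],
    reference: Mapping[str, str],
    *,
    k: int = 20,
    max_mismatches: int = 2,
    index: dict[str, list[tuple[str, int]]] | None = None,
) -> MappingResult:
    """Place reads by exact k-prefix seeding plus bounded Hamming check.

    Candidate positions are those whose first k bases match the read's
    prefix exactly; among candidates with distance <= ``max_mismatches``
    the minimum-distance one wins, ties are discarded as ambiguous.
    """
    if index is None:
        index = build_seed_index(reference, k)
    result = MappingResult(placements=[])
    for read in reads:
        seq = read.sequence
        if len(seq) < k:
            raise ValueError(f"read {read.name} shorter than seed length {k}")
        best: tuple[str, int] | None = None
        best_dist = max_mismatches + 1
        tie = False
        for name, pos in index.get(seq[:k], ()):
            window = reference[name][pos : pos + len(seq)]
            if len(window) < len(seq):
                continue
            dist = _hamming_within(seq, window, max_mismatches)
            if dist < best_dist:
                best, best_dist, tie = (name, pos), dist, False
            elif dist == best_dist and best is not None and (name, pos) != best:
                tie = True
        if best is None or best_dist > max_mismatches:
            result.n_unmapped += 1
        elif tie:
            result.n_ambiguous += 1
        else:
            result.placements.append(Placement(read.name, best[0], best[1], best_dist))
            result.n_mapped += 1
    return result
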