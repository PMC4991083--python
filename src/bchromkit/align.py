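"""Seeded, banded Smith–Waterman local alignment for contig placement.

Contigs from the (B-derived) assembly are placed on reference or consensus
sequences by exact k-mer seeding followed by banded affine-gap local
alignment (Gotoh recurrences) around each seeded diagonal.  Scoring is
match +1, mismatch -2, gap open -4 (charged on the first gapped base) and
gap extend -1.  Both orientations are tried; the mismatch list of the best
alignment feeds diagnostic-variant calling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .seq import revcomp

__all__ = ["Scoring", "Mismatch", "LocalAlignment", "align_contig"]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4  # cost of a gap of length 1
    gap_extend: int = -1  # each additional gapped base


@dataclass(frozen=True)
class Mismatch:
    """A substitution column of the alignment (0-based coordinates)."""

    ref_pos: int
    query_pos: int
    ref_base: str
    query_base: str


@dataclass
class LocalAlignment:
    """Best local alignment of a (possibly reverse-complemented) query.

    ``query_start/end`` refer to the oriented query (the reverse complement
    of the input contig when ``strand`` is '-'); ``ops`` is a CIGAR-like
    list of ('M'|'I'|'D', length) with I consuming query and D consuming
    reference bases.
    """

    score: int
    strand: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    ops: list[tuple[str, int]] = field(default_factory=list)
    mismatches: list[Mismatch] = field(default_factory=list)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


_NEG = float("-inf")


def _banded_gotoh(query: str, ref: str, diag: int, band: int, sc: Scoring):
    """Gotoh local DP restricted to |(j - i) - diag| <= band.

    Returns (best_score, traceback path) where the path is a list of
    (op, i, j) triples from alignment start to end.
    """
    m, n = len(query), len(ref)
    H: list[dict[int, float]] = [dict() for _ in range(m + 1)]
    E: list[dict[int, float]] = [dict() for _ in range(m + 1)]
    F: list[dict[int, float]] = [dict() for _ in range(m + 1)]
    ptr: dict[tuple[int, int], tuple[str, str]] = {}
    best_score, best_cell = 0.0, None

    for i in range(0, m + 1):
        lo = max(0, i + diag - band)
        hi = min(n, i + diag + band)
        for j in range(lo, hi + 1):
            if i == 0 or j == 0:
                H[i][j] = 0.0
                E[i][j] = _NEG
                F[i][j] = _NEG
                continue
            h_diag = H[i - 1].get(j - 1, _NEG)
            e = max(
                H[i].get(j - 1, _NEG) + sc.gap_open,
                E[i].get(j - 1, _NEG) + sc.gap_extend,
            )
            f = max(
                H[i - 1].get(j, _NEG) + sc.gap_open,
                F[i - 1].get(j, _NEG) + sc.gap_extend,
            )
            sub = sc.match if query[i - 1] == ref[j - 1] else sc.mismatch
            d = h_diag + sub if h_diag > _NEG else _NEG
            h = max(0.0, d, e, f)
            H[i][j], E[i][j], F[i][j] = h, e, f
            if h > 0:
                if h == d:
                    ptr[(i, j)] = ("M", "H")
                elif h == e:
                    src = "H" if e == H[i].get(j - 1, _NEG) + sc.gap_open else "E"
                    ptr[(i, j)] = ("D", src)
                else:
                    src = "H" if f == H[i - 1].get(j, _NEG) + sc.gap_open else "F"
                    ptr[(i, j)] = ("I", src)
            if h > best_score:
                best_score, best_cell = h, (i, j)

    if best_cell is None:
        return 0, []
    # walk back through H/E/F until a zero H cell
    path: list[tuple[str, int, int]] = []
    i, j = best_cell
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i].get(j, 0.0) <= 0:
                break
            op, src = ptr[(i, j)]
            if op == "M":
                path.append(("M", i, j))
                i, j = i - 1, j - 1
                state = "H"
            elif op == "D":
                path.append(("D", i, j))
                state = src
                j -= 1
            else:
                path.append(("I", i, j))
                state = src
                i -= 1
        elif state == "E":
            # continuing a gap in the query (consumes ref)
            e_here = E[i].get(j, _NEG)
            if e_here == H[i].get(j - 1, _NEG) + sc.gap_open:
                path.append(("D", i, j))
                j -= 1
                state = "H"
            else:
                path.append(("D", i, j))
                j -= 1
                state = "E"
        else:  # F
            f_here = F[i].get(j, _NEG)
            if f_here == H[i - 1].get(j, _NEG) + sc.gap_open:
                path.append(("I", i, j))
                i -= 1
                state = "H"
            else:
                path.append(("I", i, j))
                i -= 1
                state = "F"
    path.reverse()
    return int(best_score), path


def _path_to_alignment(query: str, ref: str, strand: str, score: int, path) -> LocalAlignment:
    ops: list[tuple[str, int]] = []
    mismatches: list[Mismatch] = []
    for op, i, j in path:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
        if op == "M" and query[i - 1] != ref[j - 1]:
            mismatches.append(Mismatch(j - 1, i - 1, ref[j - 1], query[i - 1]))
    first_op, last_op = path[0], path[-1]
    q_start = first_op[1] - 1 if first_op[0] != "D" else first_op[1]
    r_start = first_op[2] - 1 if first_op[0] != "I" else first_op[2]
    return LocalAlignment(
        score=score,
        strand=strand,
        ref_start=r_start,
        ref_end=last_op[2],
        query_start=q_start,
        query_end=last_op[1],
        ops=ops,
        mismatches=mismatches,
    )


def _seed_diagonals(query: str, ref_index: Mapping[str, list[int]], k: int, band: int) -> list[int]:
    diags: set[int] = set()
    for i in range(0, len(query) - k + 1):
        for j in ref_index.get(query[i : i + k], ()):
            diags.add(j - i)
    if not diags:
        return []
    # cluster nearby diagonals so each banded pass covers one seed cluster
    ordered = sorted(diags)
    centers = [ordered[0]]
    for d in ordered[1:]:
        if d - centers[-1] > band:
            centers.append(d)
    return centers


def _index_kmers(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def align_contig(
    contig: str,
    reference: str,
    *,
    k: int = 11,
    band: int = 32,
    scoring: Scoring = Scoring(),
) -> LocalAlignment | None:
    """Best local alignment of a contig against one reference sequence.

    Seeds with exact k-mers in both orientations, then runs a banded
    affine-gap local alignment around each seeded diagonal cluster and
    keeps the highest-scoring result.  Returns None when neither
    orientation produces a seed ("no alignment" is a result here, not an
    error — unrelated contigs are expected input).
    """
    if len(contig) < k:
        raise ValueError(f"contig shorter than seed length k={k}")
    ref_index = _index_kmers(reference, k)
    best: LocalAlignment | None = None
    for strand in "+-":
        query = contig if strand == "+" else revcomp(contig)
        for diag in _seed_diagonals(query, ref_index, k, band):
            score, path = _banded_gotoh(query, reference, diag, band, scoring)
            if not path:
                continue
            if best is None or score > best.score:
                best = _path_to_alignment(query, reference, strand, score, path)
    return best
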