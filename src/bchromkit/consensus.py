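"""Consensus of reference panels and B-diagnostic variant calling.

Markers for chromosome presence are anchored on nucleotide positions where
the B-derived sequence differs from a consensus of related reference
sequences while the surrounding columns are perfectly conserved: the
conserved flanks guarantee that control primers bind every template, and
the diagnostic substitution anchors the allele-specific primer's 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .align import LocalAlignment
from .seq import iupac_code

__all__ = ["ConsensusAlignment", "DiagnosticVariant", "build_consensus", "call_diagnostic_variants"]


@dataclass
class ConsensusAlignment:
    """Column-wise consensus over >= 2 aligned reference sequences."""

    sequences: list[str]
    consensus: str
    conserved_mask: list[bool]

    def conserved_run(self, pos: int, direction: int) -> int:
        """Length of the conserved column run adjacent to ``pos``."""
        run, i = 0, pos + direction
        while 0 <= i < len(self.conserved_mask) and self.conserved_mask[i]:
            run += 1
            i += direction
        return run


@dataclass(frozen=True)
class DiagnosticVariant:
    """A substitution separating the B sequence from the panel consensus.

    ``position`` is on consensus coordinates; ``contig_pos`` is the same
    column on the (oriented) contig, kept so primers can be cut from the
    contig sequence.  ``flank_conservation`` is (left, right) run lengths
    of conserved columns.
    """

    template_id: str
    position: int
    consensus_base: str
    b_base: str
    flank_conservation: tuple[int, int]
    contig_pos: int = -1
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.b_base == self.consensus_base:
            raise ValueError("diagnostic variant must differ from the consensus base")


def build_consensus(sequences: Sequence[str]) -> ConsensusAlignment:
    """Majority-rule consensus with strict conservation mask.

    Sequences must be pre-aligned (equal length; the substitution-only
    model used throughout means panels generated here are gap-free — align
    externally first otherwise).  Ties become IUPAC ambiguity codes and are
    never conserved; a column is conserved only where all sequences agree.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences to build a consensus")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be pre-aligned to equal length")
    consensus = []
    mask = []
    for col in zip(*sequences):
        counts: dict[str, int] = {}
        for base in col:
            counts[base] = counts.get(base, 0) + 1
        top = max(counts.values())
        winners = frozenset(b for b, c in counts.items() if c == top)
        if len(winners) == 1:
            consensus.append(next(iter(winners)))
        else:
            consensus.append(iupac_code(winners))
        mask.append(len(counts) == 1)
    return ConsensusAlignment(list(sequences), "".join(consensus), mask)


def call_diagnostic_variants(
    contig_id: str,
    alignment: LocalAlignment,
    contig_oriented: str,
    consensus: ConsensusAlignment,
    min_flank: int = 20,
) -> list[DiagnosticVariant]:
    """B-diagnostic substitutions from a contig-vs-consensus alignment.

    A mismatch column qualifies only when the consensus column is conserved
    across all panel members and at least ``min_flank`` conserved columns
    flank it on both sides — indel columns never qualify (the alignment's
    mismatch list holds substitutions only).
    """
    if alignment is None:
        return []
    variants: list[DiagnosticVariant] = []
    for mm in alignment.mismatches:
        pos = mm.ref_pos
        if not consensus.conserved_mask[pos]:
            continue
        left = consensus.conserved_run(pos, -1)
        right = consensus.conserved_run(pos, +1)
        if left < min_flank or right < min_flank:
            continue
        variants.append(
            DiagnosticVariant(
                template_id=contig_id,
                position=pos,
                consensus_base=mm.ref_base,
                b_base=mm.query_base,
                flank_conservation=(left, right),
                contig_pos=mm.query_pos,
                strand=alignment.strand,
            )
        )
    return variants
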