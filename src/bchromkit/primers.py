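"""Allele-specific (ARMS) and control primer design for the B multiplex.

The presence/absence marker is a three-primer multiplex: a control forward
and a shared reverse primer sit entirely in columns conserved between the
B sequence and the reference panel, so a control product amplifies in
every sample; a third, B-specific forward primer places its 3'-terminal
base exactly on a B-diagnostic substitution, so extension — and hence the
longer B product — occurs only when B-chromosome template is present.  On
a gel this reads out as one band (B-negative) versus two bands
(B-positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .consensus import ConsensusAlignment, DiagnosticVariant
from .seq import DNA_ALPHABET, complement, gc_fraction, revcomp

__all__ = [
    "Primer",
    "MultiplexAssay",
    "DesignFailure",
    "is_failure",
    "melting_temp",
    "design_allele_specific_primer",
    "design_control_pair",
    "assemble_multiplex",
    "three_prime_dimer_run",
    "MIN_PRIMER_LEN",
    "MAX_PRIMER_LEN",
]

# primer length bounds observed across validated assays of this marker class
MIN_PRIMER_LEN = 18
MAX_PRIMER_LEN = 40

DEFAULT_TM_WINDOW = (55.0, 65.0)
DEFAULT_GEL_GAP = 40
DEFAULT_TM_SPAN = 5.0
DIMER_RUN_LIMIT = 5  # a 3' cross-complementary run this long rejects the assay

# Unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K) for
# Watson-Crick dimer stacks, plus terminal initiation terms.
_NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# unlisted dimers use their reverse complement's stack
for _dimer in ("TT", "AG", "TC", "AC", "TG", "CC"):
    _NN_PARAMS[_dimer] = _NN_PARAMS[revcomp(_dimer)]

_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_GAS_CONSTANT = 1.987  # cal / (K mol)


@dataclass(frozen=True)
class Primer:
    """An oligo on a template coordinate system.

    ``three_prime`` is the 0-based template position of the 3'-terminal
    base; for '-' strand primers this is the leftmost template position of
    the primer footprint.
    """

    id: str
    sequence: str
    strand: str
    three_prime: int
    tm: float
    gc: float

    def __post_init__(self) -> None:
        if set(self.sequence) - DNA_ALPHABET:
            raise ValueError(f"primer {self.id}: alphabet must be A/C/G/T")
        if not MIN_PRIMER_LEN <= len(self.sequence) <= MAX_PRIMER_LEN:
            raise ValueError(
                f"primer {self.id}: length {len(self.sequence)} outside "
                f"[{MIN_PRIMER_LEN}, {MAX_PRIMER_LEN}]"
            )
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def template_start(self) -> int:
        """Leftmost template position of the footprint."""
        return self.three_prime - self.length + 1 if self.strand == "+" else self.three_prime

    @property
    def template_end(self) -> int:
        """One past the rightmost template position of the footprint."""
        return self.three_prime + 1 if self.strand == "+" else self.three_prime + self.length


@dataclass
class DesignFailure:
    """A design step that found no feasible oligo; lists what failed."""

    stage: str
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # failures are falsy so `if result:` reads naturally
        return False


def is_failure(obj: object) -> bool:
    return isinstance(obj, DesignFailure)


@dataclass
class MultiplexAssay:
    """The validated three-primer marker with its expected band sizes."""

    b_forward: Primer
    control_forward: Primer
    shared_reverse: Primer
    expected_control_length: int
    expected_b_length: int
    constraint_report: dict[str, float | int | str] = field(default_factory=dict)

    @property
    def primers(self) -> tuple[Primer, Primer, Primer]:
        return (self.b_forward, self.control_forward, self.shared_reverse)


def melting_temp(
    sequence: str,
    mode: str = "nearest_neighbor",
    *,
    na_molar: float = 0.05,
    oligo_molar: float = 0.25e-6,
) -> float:
    """Oligo melting temperature in degrees Celsius.

    ``wallace`` is the 2(A+T) + 4(G+C) rule; ``nearest_neighbor`` sums
    unified Watson-Crick stack enthalpies/entropies with terminal
    initiation terms, an entropic salt correction of
    0.368 (N-1) ln[Na+], and the excess-primer concentration term
    R ln(C).  Defaults: 50 mM monovalent salt, 0.25 uM oligo.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if set(sequence) - DNA_ALPHABET:
        raise ValueError("melting temperature requires an unambiguous A/C/G/T sequence")
    if mode == "wallace":
        at = sequence.count("A") + sequence.count("T")
        gc = sequence.count("G") + sequence.count("C")
        return float(2 * at + 4 * gc)
    if mode != "nearest_neighbor":
        raise ValueError(f"unknown Tm mode {mode!r}")
    if len(sequence) < 8:
        raise ValueError("nearest-neighbor model needs >= 8 nt")
    dh, ds = 0.0, 0.0
    for end in (sequence[0], sequence[-1]):
        inc = _INIT_AT if end in "AT" else _INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(sequence) - 1):
        inc = _NN_PARAMS[sequence[i : i + 2]]
        dh += inc[0]
        ds += inc[1]
    ds += 0.368 * (len(sequence) - 1) * math.log(na_molar)
    tm_kelvin = (dh * 1000.0) / (ds + _GAS_CONSTANT * math.log(oligo_molar))
    return tm_kelvin - 273.15


def design_allele_specific_primer(
    variant: DiagnosticVariant,
    contig_sequence: str,
    *,
    length_range: tuple[int, int] = (MIN_PRIMER_LEN, MAX_PRIMER_LEN),
    tm_window: tuple[float, float] = DEFAULT_TM_WINDOW,
    tm_mode: str = "nearest_neighbor",
) -> Primer | DesignFailure:
    """Forward primer whose 3'-terminal base sits on the B allele.

    ``contig_sequence`` must be in the orientation that aligned to the
    consensus (so position ``variant.contig_pos`` carries ``b_base``).
    Among lengths in range whose Tm falls inside the window, the one
    closest to the window midpoint wins (shorter on ties).
    """
    pos = variant.contig_pos
    if pos < 0 or pos >= len(contig_sequence):
        raise ValueError("variant.contig_pos outside the contig")
    if contig_sequence[pos] != variant.b_base:
        raise ValueError("contig base at the variant position is not the B allele")
    lo, hi = tm_window
    mid = (lo + hi) / 2.0
    violations: list[str] = []
    best: tuple[float, int, str, float] | None = None
    for length in range(length_range[0], length_range[1] + 1):
        if pos + 1 < length:
            violations.append(f"L={length}: insufficient upstream contig sequence")
            continue
        seq = contig_sequence[pos - length + 1 : pos + 1]
        tm = melting_temp(seq, tm_mode)
        if not lo <= tm <= hi:
            violations.append(f"L={length}: Tm {tm:.1f} outside [{lo}, {hi}]")
            continue
        key = (abs(tm - mid), length)
        if best is None or key < (best[0], best[1]):
            best = (abs(tm - mid), length, seq, tm)
    if best is None:
        return DesignFailure("allele_specific_primer", violations)
    _, length, seq, tm = best
    return Primer(
        id=f"{variant.template_id}B-F",
        sequence=seq,
        strand="+",
        three_prime=variant.position,
        tm=tm,
        gc=gc_fraction(seq),
    )


def _conserved_clear(
    consensus: ConsensusAlignment, start: int, length: int, avoid: frozenset[int]
) -> bool:
    if start < 0 or start + length > len(consensus.consensus):
        return False
    for i in range(start, start + length):
        if not consensus.conserved_mask[i] or i in avoid:
            return False
    return True


def _candidate_primers(
    consensus: ConsensusAlignment,
    positions: range,
    lengths: range,
    avoid: frozenset[int],
    tm_window: tuple[float, float],
    tm_mode: str,
    strand: str,
    end_max: int | None = None,
) -> list[tuple[float, int, int, str, float]]:
    """Feasible (score, start, length, seq, tm) candidates, best first."""
    lo, hi = tm_window
    mid = (lo + hi) / 2.0
    out = []
    for start in positions:
        for length in lengths:
            if end_max is not None and start + length > end_max:
                continue
            if not _conserved_clear(consensus, start, length, avoid):
                continue
            site = consensus.consensus[start : start + length]
            seq = site if strand == "+" else revcomp(site)
            tm = melting_temp(seq, tm_mode)
            if lo <= tm <= hi:
                out.append((abs(tm - mid), start, length, seq, tm))
    out.sort(key=lambda c: (c[0], c[2], c[1]))
    return out


def design_control_pair(
    consensus: ConsensusAlignment,
    b_site: int,
    *,
    tm_window: tuple[float, float] = DEFAULT_TM_WINDOW,
    length_range: tuple[int, int] = (MIN_PRIMER_LEN, 30),
    product_range: tuple[int, int] = (120, 220),
    avoid_positions: frozenset[int] | set[int] = frozenset(),
    min_forward_gap_from: int | None = None,
    min_forward_gap: int = 0,
    within: tuple[int, int] | None = None,
    tm_mode: str = "nearest_neighbor",
    id_prefix: str = "assay",
) -> tuple[Primer, Primer] | DesignFailure:
    """Control forward and shared reverse primers over conserved columns.

    Both primers lie entirely in conserved (and ``avoid_positions``-free)
    columns; the reverse sits downstream of ``b_site`` so it closes both
    the control and the B-specific product; the control product length
    falls in ``product_range``.  When ``min_forward_gap_from`` is given,
    the control forward start must differ from it by at least
    ``min_forward_gap`` bp — that start-offset equals the eventual band
    size gap, since both products share the reverse primer.  ``within``
    restricts both footprints to a half-open interval: in practice the
    region covered by the B-derived contig, the only columns whose
    conservation is verified against the B sequence itself.
    """
    avoid = frozenset(avoid_positions)
    lengths = range(length_range[0], length_range[1] + 1)
    n = len(consensus.consensus)
    span_lo, span_hi = within if within is not None else (0, n)
    reverse_candidates = _candidate_primers(
        consensus,
        range(max(b_site + 1, span_lo), min(n, span_hi)),
        lengths,
        avoid,
        tm_window,
        tm_mode,
        "-",
        end_max=span_hi,
    )
    if not reverse_candidates:
        return DesignFailure(
            "control_pair", ["no feasible reverse primer downstream of the variant"]
        )
    violations = ["no (forward, reverse) placement satisfied the product constraints"]
    for _, r_start, r_len, r_seq, r_tm in reverse_candidates[:50]:
        rev_five = r_start + r_len - 1
        # product = [t, rev_five]; length = rev_five - t + 1
        t_lo = max(span_lo, rev_five + 1 - product_range[1])
        t_hi = min(r_start - lengths.start, rev_five + 1 - product_range[0])
        if t_hi < t_lo:
            continue
        forward_candidates = _candidate_primers(
            consensus, range(t_lo, t_hi + 1), lengths, avoid, tm_window, tm_mode, "+"
        )
        for _, f_start, f_len, f_seq, f_tm in forward_candidates:
            if f_start + f_len > r_start:
                continue  # footprints must not overlap
            product = rev_five - f_start + 1
            if not product_range[0] <= product <= product_range[1]:
                continue
            if (
                min_forward_gap_from is not None
                and abs(f_start - min_forward_gap_from) < min_forward_gap
            ):
                continue
            forward = Primer(
                id=f"{id_prefix}C-F",
                sequence=f_seq,
                strand="+",
                three_prime=f_start + f_len - 1,
                tm=f_tm,
                gc=gc_fraction(f_seq),
            )
            reverse = Primer(
                id=f"{id_prefix}-R",
                sequence=r_seq,
                strand="-",
                three_prime=r_start,
                tm=r_tm,
                gc=gc_fraction(r_seq),
            )
            return forward, reverse
    return DesignFailure("control_pair", violations)


def three_prime_dimer_run(a: str, b: str) -> int:
    """Length of the contiguous 3'-end-aligned complementary run."""
    run = 0
    limit = min(len(a), len(b))
    while run < limit and a[-1 - run] == complement(b[-1 - run]):
        run += 1
    return run


def assemble_multiplex(
    b_forward: Primer,
    control_forward: Primer,
    shared_reverse: Primer,
    *,
    delta_gel: int = DEFAULT_GEL_GAP,
    tm_span_limit: float = DEFAULT_TM_SPAN,
    dimer_run_limit: int = DIMER_RUN_LIMIT,
) -> MultiplexAssay | DesignFailure:
    """Validate the three-primer set and compute expected band sizes.

    Checks: both products positive; band size gap >= ``delta_gel`` so a 1%
    agarose gel resolves them; pairwise Tm span <= ``tm_span_limit``; no 3'
    cross-complementarity run of ``dimer_run_limit`` or more between any
    primer pair (self-pairs included).
    """
    violations: list[str] = []
    rev_five = shared_reverse.three_prime + shared_reverse.length - 1
    l_control = rev_five - control_forward.template_start + 1
    l_b = rev_five - b_forward.template_start + 1
    if l_control <= 0 or l_b <= 0:
        violations.append("a primer lies downstream of the shared reverse site")
    gap = abs(l_b - l_control)
    if gap < delta_gel:
        violations.append(f"band gap {gap} bp < gel resolvability {delta_gel} bp")
    tms = [p.tm for p in (b_forward, control_forward, shared_reverse)]
    span = max(tms) - min(tms)
    if span > tm_span_limit:
        violations.append(f"Tm span {span:.1f} C exceeds limit {tm_span_limit:.1f} C")
    primer_list = [b_forward, control_forward, shared_reverse]
    for i, p in enumerate(primer_list):
        for q in primer_list[i:]:
            run = three_prime_dimer_run(p.sequence, q.sequence)
            if run >= dimer_run_limit:
                violations.append(
                    f"3' cross-dimer run {run} nt between {p.id} and {q.id}"
                )
    if violations:
        return DesignFailure("assemble_multiplex", violations)
    return MultiplexAssay(
        b_forward=b_forward,
        control_forward=control_forward,
        shared_reverse=shared_reverse,
        expected_control_length=l_control,
        expected_b_length=l_b,
        constraint_report={
            "band_gap_bp": gap,
            "tm_span_c": span,
            "control_length_bp": l_control,
            "b_length_bp": l_b,
        },
    )
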