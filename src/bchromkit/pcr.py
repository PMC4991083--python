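"""In-silico PCR: primer-site scanning, amplicon prediction, presence calls.

The priming model is the standard ARMS assumption: extension requires an
exact match at the primer's 3'-terminal base, tolerates at most one
mismatch elsewhere in the 3'-terminal 5 nt, and at most ``m_internal``
mismatches in the remainder.  Any forward/reverse site pair on opposite
strands with a positive product no longer than ``max_product`` yields an
amplicon; distinct (forward, reverse, length) classes are the "bands" a
gel would show.  IUPAC-ambiguous template positions count as mismatches
(conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .primers import MultiplexAssay, Primer
from .seq import revcomp

__all__ = [
    "PrimerSite",
    "AmpliconHit",
    "PresenceCall",
    "find_primer_sites",
    "in_silico_pcr",
    "bands",
    "call_presence",
]

DEFAULT_MAX_PRODUCT = 2_000
DEFAULT_INTERNAL_MISMATCHES = 2
CONTROL_LENGTH_TOL = 5  # bp tolerance when matching a band to its expected size


@dataclass(frozen=True)
class PrimerSite:
    """One place a primer can prime on the template.

    ``start``/``end`` delimit the primer footprint on the template (0-based
    half-open); '+' sites extend rightward, '-' sites leftward.
    """

    primer_id: str
    strand: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    template_id: str
    start: int
    end: int
    forward_id: str
    reverse_id: str
    forward_mismatches: int
    reverse_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PresenceCall:
    """Genotype readout of the multiplex: one band means B-negative, two
    bands mean B-positive, and a missing control band voids the test."""

    value: str  # B_positive | B_negative | invalid
    supporting: list[AmpliconHit] = field(default_factory=list)


def _site_ok(primer_seq: str, window: str, m_internal: int) -> int | None:
    """Mismatch count if the window primes under the ARMS rules, else None.

    ``primer_seq`` and ``window`` are both written 5'->3' of the primer,
    i.e. index -1 is the 3'-terminal base.
    """
    length = len(primer_seq)
    mism_3p = 0
    mism_internal = 0
    # 3'-terminal base must match exactly
    if primer_seq[-1] != window[-1]:
        return None
    for i in range(2, min(5, length) + 1):
        if primer_seq[-i] != window[-i]:
            mism_3p += 1
            if mism_3p > 1:
                return None
    for i in range(length - 5):
        if primer_seq[i] != window[i]:
            mism_internal += 1
            if mism_internal > m_internal:
                return None
    return mism_3p + mism_internal


def find_primer_sites(
    template: str, primer: Primer | tuple[str, str], m_internal: int = DEFAULT_INTERNAL_MISMATCHES
) -> list[PrimerSite]:
    """All positions where a primer primes, on either template strand."""
    if isinstance(primer, Primer):
        pid, seq = primer.id, primer.sequence
    else:
        pid, seq = primer
    length = len(seq)
    sites: list[PrimerSite] = []
    for i in range(len(template) - length + 1):
        window = template[i : i + length]
        # plus orientation: primer equals the top strand, extends right
        mism = _site_ok(seq, window, m_internal)
        if mism is not None:
            sites.append(PrimerSite(pid, "+", i, i + length, mism))
        # minus orientation: primer anneals to the top strand, extends left;
        # the footprint equals revcomp(primer), whose 5'->3' reading of the
        # primer is the reverse complement of the window
        mism = _site_ok(seq, revcomp(window), m_internal)
        if mism is not None:
            sites.append(PrimerSite(pid, "-", i, i + length, mism))
    return sites


def in_silico_pcr(
    template: str,
    primers: Sequence[Primer | tuple[str, str]],
    *,
    template_id: str = "template",
    max_product: int = DEFAULT_MAX_PRODUCT,
    m_internal: int = DEFAULT_INTERNAL_MISMATCHES,
) -> list[AmpliconHit]:
    """Predict every amplicon a primer set produces on one template.

    Each '+' site pairs with each '-' site to its right; the product spans
    both primer footprints and must satisfy 0 < length <= ``max_product``.
    """
    plus: list[PrimerSite] = []
    minus: list[PrimerSite] = []
    for primer in primers:
        for site in find_primer_sites(template, primer, m_internal):
            (plus if site.strand == "+" else minus).append(site)
    hits: list[AmpliconHit] = []
    for f in plus:
        for r in minus:
            length = r.end - f.start
            if 0 < length <= max_product:
                hits.append(
                    AmpliconHit(
                        template_id=template_id,
                        start=f.start,
                        end=r.end,
                        forward_id=f.primer_id,
                        reverse_id=r.primer_id,
                        forward_mismatches=f.mismatches,
                        reverse_mismatches=r.mismatches,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end, h.forward_id, h.reverse_id))
    return hits


def bands(hits: Iterable[AmpliconHit]) -> set[tuple[str, str, int]]:
    """Distinct gel bands: (forward primer, reverse primer, product length).

    A high-copy template yields one hit per copy; a gel shows them as a
    single band, which is what presence calls count.
    """
    return {(h.forward_id, h.reverse_id, h.length) for h in hits}


def pcr_sample(
    templates: Mapping[str, str],
    assay: MultiplexAssay,
    *,
    max_product: int = DEFAULT_MAX_PRODUCT,
    m_internal: int = DEFAULT_INTERNAL_MISMATCHES,
) -> list[AmpliconHit]:
    """Run the multiplex over every template in one sample's genome."""
    hits: list[AmpliconHit] = []
    for name, seq in templates.items():
        hits.extend(
            in_silico_pcr(
                seq,
                assay.primers,
                template_id=name,
                max_product=max_product,
                m_internal=m_internal,
            )
        )
    return hits


def call_presence(
    hits: Sequence[AmpliconHit],
    assay: MultiplexAssay,
    *,
    length_tolerance: int = CONTROL_LENGTH_TOL,
) -> PresenceCall:
    """Genotype a sample from its predicted amplicons.

    Control band (control forward + shared reverse, length within
    tolerance of the expected control size) AND B band present ->
    B_positive; control only -> B_negative; no control -> invalid
    regardless of other products (the internal control failed).
    """
    control = [
        h
        for h in hits
        if h.forward_id == assay.control_forward.id
        and h.reverse_id == assay.shared_reverse.id
        and abs(h.length - assay.expected_control_length) <= length_tolerance
    ]
    b_specific = [
        h
        for h in hits
        if h.forward_id == assay.b_forward.id
        and h.reverse_id == assay.shared_reverse.id
        and abs(h.length - assay.expected_b_length) <= length_tolerance
    ]
    if not control:
        return PresenceCall("invalid", list(b_specific))
    if b_specific:
        return PresenceCall("B_positive", control[:1] + b_specific[:1])
    return PresenceCall("B_negative", control[:1])
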