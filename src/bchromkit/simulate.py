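"""Synthetic 0B/1B/2B cohorts for B-chromosome marker development.

B chromosomes are dispensable supernumerary chromosomes carried by 0, 1 or 2
copies per individual on top of the standard (A) karyotype.  In the species
modelled here the B is largely built from blocks of A-complement sequence
that were duplicated to high copy number and accumulated B-diagnostic point
substitutions.  This module builds a miniature version of that world:

* a random reference genome (the A complement),
* a B chromosome made of A-derived blocks repeated ``copies_on_b`` times,
  each copy carrying the same planted diagnostic substitutions,
* per-genotype short-read sets whose depth over B blocks scales with the
  number of Bs,
* contigs sampled from the B sequence (standing in for assembled reads from
  a microdissected chromosome),
* qPCR Ct tables following the log2 template-dose model
  ``Ct = C0 - log2(copies) + noise``.

Everything is driven by one integer seed; per-stage streams are derived
deterministically so outputs are byte-identical across runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BBlock",
    "TruthSpec",
    "SimulatedCohort",
    "FastqRead",
    "stage_rng",
    "make_reference",
    "make_b_sequence",
    "simulate_reads",
    "simulate_b_contigs",
    "simulate_ct",
    "simulate_ortholog_panel",
    "simulate_cohort",
    "GENOTYPES",
]

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")
GENOTYPES = ("0B", "1B", "2B")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream for a named stage."""
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass(frozen=True)
class BBlock:
    """An A-complement interval duplicated onto the B chromosome.

    Coordinates are 0-based, half-open; ``copies_on_b`` is the number of
    tandem copies of the block carried by one B chromosome.
    """

    scaffold: str
    start: int
    end: int
    copies_on_b: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid block interval [{self.start}, {self.end})")
        if self.copies_on_b < 1:
            raise ValueError("copies_on_b must be >= 1")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthSpec:
    """Parameters of the synthetic study design.

    Defaults are the desk-scale study conditions used throughout the test
    suite: a diploid A complement (``a_complement_copies = 2``), one
    high-copy B block, 20x depth per haploid genome copy, 1% diagnostic
    substitution rate inside B blocks, error-free reads, and triplicate
    qPCR with 0.2-cycle noise.
    """

    seed: int = 0
    scaffold_lengths: tuple[int, ...] = (20_000,)
    b_blocks: tuple[BBlock, ...] = (BBlock("scaffold_1", 8_000, 11_000, 10),)
    snv_rate_in_blocks: float = 0.01
    read_length: int = 100
    depth_per_haploid_copy: float = 20.0
    read_error_rate: float = 0.0
    ct_baseline: float = 28.0
    ct_noise_sd: float = 0.2
    a_complement_copies: int = 2

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.scaffold_lengths):
            raise ValueError("scaffold lengths must be >= 1")
        for rate in (self.snv_rate_in_blocks, self.read_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_per_haploid_copy <= 0:
            raise ValueError("depth_per_haploid_copy must be > 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.a_complement_copies < 1:
            raise ValueError("a_complement_copies must be >= 1")
        sizes = {f"scaffold_{i + 1}": n for i, n in enumerate(self.scaffold_lengths)}
        for blk in self.b_blocks:
            if blk.scaffold not in sizes:
                raise ValueError(f"block scaffold {blk.scaffold!r} not in reference")
            if blk.end > sizes[blk.scaffold]:
                raise ValueError(f"block {blk} exceeds scaffold bounds")

    def with_seed(self, seed: int) -> "TruthSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str


@dataclass
class SimulatedCohort:
    """All artifacts of one synthetic study, plus the planted truth."""

    spec: TruthSpec
    reference: dict[str, str]
    b_sequence: str
    truth_blocks: list[BBlock]
    truth_variants: list[tuple[str, int, str, str]]
    read_sets: dict[str, list[FastqRead]]
    b_contigs: dict[str, str]
    ct_table: pd.DataFrame
    ct_genotypes: dict[str, str] = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASE_ARR, size=length).tobytes().decode()


def make_reference(seed: int, scaffold_lengths: Sequence[int]) -> dict[str, str]:
    """Generate a random uniform-composition reference genome.

    Returns an ordered mapping ``scaffold_1 .. scaffold_n`` -> sequence.
    """
    if any(n < 1 for n in scaffold_lengths):
        raise ValueError("scaffold lengths must be >= 1")
    rng = stage_rng(seed, "reference")
    return {
        f"scaffold_{i + 1}": _random_sequence(rng, int(n))
        for i, n in enumerate(scaffold_lengths)
    }


def make_b_sequence(
    reference: Mapping[str, str], spec: TruthSpec
) -> tuple[str, list[BBlock], list[tuple[str, int, str, str]]]:
    """Build the B-chromosome sequence from the spec's blocks.

    Each block is copied out of the reference, B-diagnostic substitutions
    are planted once per site at ``snv_rate_in_blocks`` (never equal to the
    reference base), and the mutated block is concatenated ``copies_on_b``
    times.  Every copy carries the same substitutions, mirroring a
    duplication that post-dates the divergence of the B allele.

    Returns ``(b_sequence, truth_blocks, truth_variants)`` with variants as
    ``(scaffold, position, reference_base, b_base)`` in 0-based reference
    coordinates.
    """
    by_scaffold: dict[str, list[BBlock]] = {}
    for blk in spec.b_blocks:
        if blk.scaffold not in reference:
            raise ValueError(f"block scaffold {blk.scaffold!r} not in reference")
        if blk.end > len(reference[blk.scaffold]):
            raise ValueError(f"block {blk} exceeds scaffold bounds")
        by_scaffold.setdefault(blk.scaffold, []).append(blk)
    for scaffold, blocks in by_scaffold.items():
        blocks = sorted(blocks, key=lambda b: b.start)
        for prev, nxt in zip(blocks, blocks[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping blocks on {scaffold}: {prev} / {nxt}")

    rng = stage_rng(spec.seed, "b_sequence")
    parts: list[str] = []
    variants: list[tuple[str, int, str, str]] = []
    for blk in spec.b_blocks:
        seg = list(reference[blk.scaffold][blk.start : blk.end])
        hit = np.flatnonzero(rng.random(len(seg)) < spec.snv_rate_in_blocks)
        for i in hit:
            ref_base = seg[i]
            alt = BASES.replace(ref_base, "")[rng.integers(3)]
            seg[i] = alt
            variants.append((blk.scaffold, blk.start + int(i), ref_base, alt))
        parts.append("".join(seg) * blk.copies_on_b)
    return "".join(parts), list(spec.b_blocks), variants


def _parse_genotype(genotype: str | int) -> int:
    if isinstance(genotype, str):
        if genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {genotype!r}")
        return int(genotype[0])
    if genotype not in (0, 1, 2):
        raise ValueError(f"genotype must be 0, 1 or 2, got {genotype!r}")
    return int(genotype)


def simulate_reads(
    reference: Mapping[str, str],
    b_sequence: str,
    genotype: str | int,
    spec: TruthSpec,
) -> list[FastqRead]:
    """Draw single-end reads from the genotype's template pool.

    The pool holds ``a_complement_copies`` copies of every reference
    scaffold plus ``nB`` copies of the B sequence.  The read count is
    ``N = round(total_pool_bases * depth_per_haploid_copy / read_length)``,
    start positions are uniform over each template copy, and substitution
    errors are applied per base at ``read_error_rate``.  Read names encode
    the template of origin and 0-based start (``r<i>|<template>|<start>``)
    so truth is recoverable in tests.
    """
    n_b = _parse_genotype(genotype)
    label = f"{n_b}B"
    templates: list[tuple[str, str, int]] = [
        (name, seq, spec.a_complement_copies) for name, seq in reference.items()
    ]
    if n_b > 0:
        if not b_sequence:
            raise ValueError("b_sequence is empty but genotype carries Bs")
        templates.append(("B", b_sequence, n_b))
    length = spec.read_length
    if min(len(seq) for _, seq, _ in templates) < length:
        raise ValueError("read_length exceeds the shortest template")

    total_bases = sum(len(seq) * copies for _, seq, copies in templates)
    n_reads = round(total_bases * spec.depth_per_haploid_copy / length)

    rng = stage_rng(spec.seed, f"reads_{label}")
    weights = np.array(
        [copies * (len(seq) - length + 1) for _, seq, copies in templates], dtype=float
    )
    choice = rng.choice(len(templates), size=n_reads, p=weights / weights.sum())
    qual = "I" * length
    reads: list[FastqRead] = []
    for i, t in enumerate(choice):
        name, seq, _ = templates[t]
        start = int(rng.integers(0, len(seq) - length + 1))
        bases = seq[start : start + length]
        if spec.read_error_rate > 0:
            err = np.flatnonzero(rng.random(length) < spec.read_error_rate)
            if err.size:
                mutable = list(bases)
                for j in err:
                    mutable[j] = BASES.replace(mutable[j], "")[rng.integers(3)]
                bases = "".join(mutable)
        reads.append(FastqRead(f"r{i}|{name}|{start}", bases, qual))
    return reads


def simulate_b_contigs(
    b_sequence: str,
    n: int,
    *,
    seed: int = 0,
    mean_length: float = 372.0,
    sd_length: float = 100.0,
    min_length: int = 100,
    max_length: int = 1000,
    fixed_length: int | None = None,
) -> dict[str, str]:
    """Sample contigs (exact substrings) from the B sequence.

    Lengths follow a truncated normal (default mean 372 bp, sd 100 bp,
    truncated to [100, 1000] bp), echoing the fragment sizes a low-pass
    assembly of a microdissected chromosome produces.  ``fixed_length``
    overrides the distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = stage_rng(seed, "b_contigs")
    limit = min(max_length, len(b_sequence))
    if fixed_length is not None:
        if not 1 <= fixed_length <= len(b_sequence):
            raise ValueError("fixed_length out of range")
        lengths = np.full(n, fixed_length)
    else:
        if min_length > limit:
            raise ValueError("b_sequence shorter than min contig length")
        lengths = np.empty(n, dtype=int)
        filled = 0
        while filled < n:
            draw = rng.normal(mean_length, sd_length, size=2 * (n - filled))
            keep = draw[(draw >= min_length) & (draw <= limit)]
            take = min(keep.size, n - filled)
            lengths[filled : filled + take] = keep[:take].astype(int)
            filled += take
    contigs: dict[str, str] = {}
    for i, length in enumerate(lengths):
        start = int(rng.integers(0, len(b_sequence) - int(length) + 1))
        contigs[f"contig_{i + 1}|{start}"] = b_sequence[start : start + int(length)]
    return contigs


def simulate_ct(
    genotypes: Mapping[str, str | int],
    *,
    a: int = 2,
    c: int = 100,
    a_ref: int = 2,
    c0: float = 28.0,
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table under the log2 template-dose model.

    For a sample with ``nB`` B chromosomes the target assay sees
    ``a + nB*c`` template copies (``a`` in the A complement, ``c`` added per
    B) and the single-copy reference gene (HPRT) sees ``a_ref``; each
    replicate draws ``Ct = C0 - log2(copies) + Normal(0, noise_sd)``.
    Reactions are run in triplicate by default.

    Returns a tidy DataFrame with columns
    ``sample_id, genotype, assay, replicate, ct``.
    """
    if a < 1 or c < 1 or a_ref < 1:
        raise ValueError("copy numbers a, c and a_ref must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = stage_rng(seed, "ct")
    rows = []
    for sample_id, genotype in genotypes.items():
        n_b = _parse_genotype(genotype)
        for assay, copies in (("target", a + n_b * c), ("HPRT", a_ref)):
            base = c0 - np.log2(copies)
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append((sample_id, f"{n_b}B", assay, rep, base + noise))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "assay", "replicate", "ct"])


def simulate_ortholog_panel(
    region: str,
    *,
    n_species: int = 3,
    divergence: float = 0.005,
    protected: Iterable[int] = (),
    seed: int = 0,
) -> list[str]:
    """Emulate orthologous sequences of the region from related species.

    Each panel member is the region with independent substitutions at the
    ``divergence`` rate; positions in ``protected`` (e.g. B-diagnostic
    sites) always keep the reference allele so the panel consensus carries
    the A-complement state there.  Used to build the conserved-consensus
    backdrop against which B-diagnostic variants are called.
    """
    if n_species < 2:
        raise ValueError("need at least two species for a consensus panel")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = stage_rng(seed, "orthologs")
    shield = set(protected)
    panel = []
    for _ in range(n_species):
        seq = list(region)
        hit = np.flatnonzero(rng.random(len(seq)) < divergence)
        for i in hit:
            if int(i) in shield:
                continue
            seq[i] = BASES.replace(seq[i], "")[rng.integers(3)]
        panel.append("".join(seq))
    return panel


def default_ct_genotypes(
    *, controls_per_class: int = 3, unknowns_per_class: int = 0
) -> dict[str, str]:
    """Standard qPCR sample sheet: known controls plus optional unknowns."""
    sheet: dict[str, str] = {}
    for genotype in GENOTYPES:
        for i in range(1, controls_per_class + 1):
            sheet[f"ctrl_{genotype}_{i}"] = genotype
        for i in range(1, unknowns_per_class + 1):
            sheet[f"sample_{genotype}_{i}"] = genotype
    return sheet


def simulate_cohort(
    spec: TruthSpec,
    *,
    n_contigs: int = 40,
    ct_genotypes: Mapping[str, str] | None = None,
    ct_copies_per_b: int = 100,
) -> SimulatedCohort:
    """Generate every artifact of one synthetic study from a single spec."""
    reference = make_reference(spec.seed, spec.scaffold_lengths)
    b_sequence, truth_blocks, truth_variants = make_b_sequence(reference, spec)
    read_sets = {
        genotype: simulate_reads(reference, b_sequence, genotype, spec)
        for genotype in GENOTYPES
    }
    contigs = simulate_b_contigs(b_sequence, n_contigs, seed=spec.seed)
    genos = dict(ct_genotypes) if ct_genotypes is not None else default_ct_genotypes()
    ct = simulate_ct(
        genos,
        a=spec.a_complement_copies,
        c=ct_copies_per_b,
        a_ref=spec.a_complement_copies,
        c0=spec.ct_baseline,
        noise_sd=spec.ct_noise_sd,
        seed=spec.seed,
    )
    return SimulatedCohort(
        spec=spec,
        reference=reference,
        b_sequence=b_sequence,
        truth_blocks=truth_blocks,
        truth_variants=truth_variants,
        read_sets=read_sets,
        b_contigs=contigs,
        ct_table=ct,
        ct_genotypes=genos,
    )
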