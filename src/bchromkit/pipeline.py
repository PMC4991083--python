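"""End-to-end workflows binding simulation, scanning, design and dosage.

Two workflows mirror how the markers are used in practice:

* presence/absence — design the three-primer multiplex from B-derived
  contigs against a reference-panel consensus, then genotype samples by
  the one-band/two-band in-silico PCR readout;
* B count — coverage-ratio scan for candidate high-copy regions, then
  qPCR gene-dose calling calibrated on known 0B/1B/2B controls.

``run_pipeline`` executes both on a synthetic cohort and writes every
intermediate artifact plus a JSON report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from . import io
from .align import align_contig
from .config import PipelineConfig
from .consensus import ConsensusAlignment, build_consensus, call_diagnostic_variants
from .coverage import (
    CandidateBlock,
    Region,
    detect_blocks,
    rank_blocks,
    ratio_track,
    window_depth,
)
from .dosage import calibrate, call_copies, cohort_fold_change, dose_table
from .mapping import map_reads_exact
from .pcr import bands, call_presence, pcr_sample
from .primers import (
    DesignFailure,
    MultiplexAssay,
    assemble_multiplex,
    design_allele_specific_primer,
    design_control_pair,
    is_failure,
)
from .seq import revcomp
from .simulate import (
    GENOTYPES,
    SimulatedCohort,
    TruthSpec,
    BBlock,
    default_ct_genotypes,
    simulate_cohort,
    simulate_ct,
    simulate_ortholog_panel,
)

__all__ = [
    "AssayDesign",
    "spec_from_config",
    "design_assay_for_cohort",
    "scan_cohort",
    "run_presence_workflow",
    "run_dose_workflow",
    "run_pipeline",
]


@dataclass
class AssayDesign:
    """A designed multiplex plus the context needed to interpret it."""

    assay: MultiplexAssay
    consensus: ConsensusAlignment
    region: Region
    contig_id: str
    variant_position: int
    b_base: str


def spec_from_config(config: PipelineConfig) -> TruthSpec:
    blocks = tuple(BBlock(s, int(a), int(b), int(c)) for s, a, b, c in config.b_blocks)
    return TruthSpec(
        seed=config.seed,
        scaffold_lengths=tuple(int(n) for n in config.scaffold_lengths),
        b_blocks=blocks,
        snv_rate_in_blocks=config.snv_rate_in_blocks,
        read_length=config.read_length,
        depth_per_haploid_copy=config.depth_per_haploid_copy,
        read_error_rate=config.read_error_rate,
        ct_baseline=config.ct_baseline,
        ct_noise_sd=config.ct_noise_sd,
        a_complement_copies=config.a_complement_copies,
    )


def design_assay_for_cohort(
    cohort: SimulatedCohort,
    *,
    min_flank: int = 20,
    tm_window: tuple[float, float] = (55.0, 65.0),
    gel_gap: int = 40,
    tm_span: float = 5.0,
    divergence: float = 0.005,
) -> AssayDesign | DesignFailure:
    """Design the three-primer multiplex from the cohort's B contigs.

    Builds an ortholog-panel consensus over the first planted block,
    aligns each contig to it, calls B-diagnostic variants, and returns the
    first variant whose allele-specific primer, control pair and assembly
    constraints are all satisfiable.
    """
    blk = cohort.truth_blocks[0]
    region_seq = cohort.reference[blk.scaffold][blk.start : blk.end]
    protected = [
        pos - blk.start
        for (sc, pos, _, _) in cohort.truth_variants
        if sc == blk.scaffold and blk.start <= pos < blk.end
    ]
    panel = simulate_ortholog_panel(
        region_seq,
        n_species=3,
        divergence=divergence,
        protected=protected,
        seed=cohort.spec.seed,
    )
    cons = build_consensus(panel)
    failures: list[str] = []
    for contig_id, contig_seq in cohort.b_contigs.items():
        aln = align_contig(contig_seq, cons.consensus)
        if aln is None:
            continue
        oriented = contig_seq if aln.strand == "+" else revcomp(contig_seq)
        # primer ids use the bare contig name; the |start suffix is
        # simulator truth-tracking, not part of the assay
        bare_id = contig_id.split("|")[0]
        variants = call_diagnostic_variants(bare_id, aln, oriented, cons, min_flank)
        avoid = {mm.ref_pos for mm in aln.mismatches}
        for variant in variants:
            b_primer = design_allele_specific_primer(variant, oriented, tm_window=tm_window)
            if is_failure(b_primer):
                failures.extend(f"{contig_id}@{variant.position}: {v}" for v in b_primer.violations[:1])
                continue
            pair = design_control_pair(
                cons,
                variant.position,
                tm_window=tm_window,
                avoid_positions=avoid,
                min_forward_gap_from=b_primer.template_start,
                min_forward_gap=gel_gap,
                # stay inside the contig-covered interval: only there is
                # conservation verified against the B sequence itself
                within=(aln.ref_start, aln.ref_end),
                id_prefix=bare_id,
            )
            if is_failure(pair):
                failures.extend(f"{contig_id}@{variant.position}: {v}" for v in pair.violations[:1])
                continue
            assay = assemble_multiplex(
                b_primer, pair[0], pair[1], delta_gel=gel_gap, tm_span_limit=tm_span
            )
            if is_failure(assay):
                failures.extend(f"{contig_id}@{variant.position}: {v}" for v in assay.violations[:1])
                continue
            return AssayDesign(
                assay=assay,
                consensus=cons,
                region=Region(blk.scaffold, blk.start, blk.end, "design_region"),
                contig_id=contig_id,
                variant_position=variant.position,
                b_base=variant.b_base,
            )
    return DesignFailure("design_assay_for_cohort", failures or ["no alignable contig"])


def genotype_templates(cohort: SimulatedCohort, genotype: str) -> dict[str, str]:
    """The template pool the multiplex sees in one sample's genomic DNA."""
    templates = dict(cohort.reference)
    if genotype != "0B":
        templates["B"] = cohort.b_sequence
    return templates


def run_presence_workflow(
    cohort: SimulatedCohort,
    *,
    min_flank: int = 20,
    tm_window: tuple[float, float] = (55.0, 65.0),
    gel_gap: int = 40,
    tm_span: float = 5.0,
    divergence: float = 0.005,
    max_product: int = 2_000,
    m_internal: int = 2,
) -> dict:
    """Design the multiplex, then genotype 0B/1B/2B in-silico samples."""
    design = design_assay_for_cohort(
        cohort,
        min_flank=min_flank,
        tm_window=tm_window,
        gel_gap=gel_gap,
        tm_span=tm_span,
        divergence=divergence,
    )
    if is_failure(design):
        raise RuntimeError(
            "presence workflow: no feasible assay design: " + "; ".join(design.violations[:5])
        )
    per_genotype = {}
    n_correct = 0
    for genotype in GENOTYPES:
        hits = pcr_sample(
            genotype_templates(cohort, genotype),
            design.assay,
            max_product=max_product,
            m_internal=m_internal,
        )
        call = call_presence(hits, design.assay)
        expected = "B_negative" if genotype == "0B" else "B_positive"
        n_correct += call.value == expected
        per_genotype[genotype] = {
            "n_bands": len(bands(hits)),
            "call": call.value,
            "expected": expected,
        }
    return {
        "assay": {
            "contig": design.contig_id,
            "variant_position": design.variant_position,
            "b_base": design.b_base,
            "control_length": design.assay.expected_control_length,
            "b_length": design.assay.expected_b_length,
            "primers": {
                p.id: p.sequence for p in design.assay.primers
            },
        },
        "calls": per_genotype,
        "concordance": n_correct / len(GENOTYPES),
    }


def scan_cohort(
    cohort: SimulatedCohort,
    *,
    window: int = 1_000,
    alpha: float = 0.5,
    theta: float = 1.5,
    min_windows: int = 3,
    max_gap: int = 1,
    k: int = 20,
    max_mismatches: int = 2,
) -> tuple[list[CandidateBlock], dict]:
    """Map reads, window depth, form ratios and detect candidate blocks."""
    ref_lengths = {name: len(seq) for name, seq in cohort.reference.items()}
    profiles = {}
    mapping_summary = {}
    for genotype in GENOTYPES:
        result = map_reads_exact(
            cohort.read_sets[genotype], cohort.reference, k=k, max_mismatches=max_mismatches
        )
        profiles[genotype] = window_depth(
            result.placements, ref_lengths, window, sample_id=genotype, genotype=genotype
        )
        mapping_summary[genotype] = result.summary()
    track = ratio_track(profiles["0B"], profiles["1B"], profiles["2B"], alpha)
    blocks = rank_blocks(detect_blocks(track, theta, min_windows, max_gap))
    return blocks, {"mapping": mapping_summary}


def run_dose_workflow(
    *,
    seed: int = 0,
    a: int = 2,
    c: int = 100,
    noise_sd: float = 0.2,
    c0: float = 28.0,
    controls_per_class: int = 3,
    unknowns_per_class: int = 10,
    epsilon: float = 0.25,
    sd_flag: float = 0.5,
) -> dict:
    """Simulate a qPCR plate, calibrate on controls, call the unknowns."""
    sheet = default_ct_genotypes(
        controls_per_class=controls_per_class, unknowns_per_class=unknowns_per_class
    )
    ct = simulate_ct(sheet, a=a, c=c, a_ref=a, c0=c0, noise_sd=noise_sd, seed=seed)
    estimates = dose_table(ct, sd_flag=sd_flag)
    control_truth = {s: g for s, g in sheet.items() if s.startswith("ctrl_")}
    calibration = calibrate(
        [e for e in estimates if e.sample_id in control_truth], control_truth
    )
    unknowns = [e for e in estimates if not e.sample_id.startswith("ctrl_")]
    calls = {e.sample_id: call_copies(e, calibration, epsilon=epsilon) for e in unknowns}
    n_correct = sum(calls[s].genotype == sheet[s] for s in calls)
    gdr_by_class = {g: [e.gdr for e in unknowns if sheet[e.sample_id] == g] for g in GENOTYPES}
    report = {
        "calibration_centers_log2": calibration.log2_centers,
        "n_unknowns": len(unknowns),
        "concordance": n_correct / len(unknowns) if unknowns else None,
        "calls": {s: c.genotype for s, c in calls.items()},
    }
    if gdr_by_class["1B"] and gdr_by_class["2B"]:
        ratio, ci = cohort_fold_change(gdr_by_class["2B"], gdr_by_class["1B"], seed=seed)
        report["fold_change_2b_vs_1b"] = ratio
        report["fold_change_ci95"] = ci
    return report


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Full synthetic demonstration: simulate, scan, design, PCR, dose.

    Writes FASTA/FASTQ/BED/CSV artifacts plus ``report.json`` under
    ``outdir`` and returns the report.  Any stage failure raises with the
    stage name; nothing is written until its inputs validated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec_from_config(config)
    cohort = simulate_cohort(
        spec, n_contigs=config.n_contigs, ct_copies_per_b=config.ct_copies_per_b
    )

    io.write_fasta(cohort.reference, outdir / "reference.fa")
    io.write_fasta({"B": cohort.b_sequence}, outdir / "b_sequence.fa")
    io.write_fasta(cohort.b_contigs, outdir / "b_contigs.fa")
    for genotype, reads in cohort.read_sets.items():
        io.write_fastq(reads, outdir / f"reads_{genotype}.fastq")
    io.write_bed(
        (Region(b.scaffold, b.start, b.end, f"truth_block_{i}") for i, b in enumerate(cohort.truth_blocks)),
        outdir / "truth_blocks.bed",
    )
    io.write_ct_csv(cohort.ct_table, outdir / "ct_table.csv")

    blocks, scan_info = scan_cohort(
        cohort,
        window=config.window,
        alpha=config.alpha,
        theta=config.theta,
        min_windows=config.min_windows,
        max_gap=config.max_gap,
    )
    io.write_bed(
        (
            Region(b.scaffold, b.start, b.end, f"block_{i}", round(b.mean_r2, 3))
            for i, b in enumerate(blocks)
        ),
        outdir / "candidate_blocks.bed",
    )

    presence = run_presence_workflow(
        cohort,
        min_flank=config.min_flank,
        tm_window=(config.tm_lo, config.tm_hi),
        gel_gap=config.gel_gap,
        tm_span=config.tm_span,
        divergence=config.ortholog_divergence,
        max_product=config.max_product,
        m_internal=config.m_internal,
    )
    dose = run_dose_workflow(
        seed=config.seed,
        a=config.a_complement_copies,
        c=config.ct_copies_per_b,
        noise_sd=config.ct_noise_sd,
        c0=config.ct_baseline,
        controls_per_class=config.dose_controls_per_class,
        unknowns_per_class=config.dose_unknowns_per_class,
        epsilon=config.epsilon,
        sd_flag=config.sd_flag,
    )

    report = {
        "config": config.to_dict(),
        "scan": {
            "n_blocks": len(blocks),
            "blocks": [
                {
                    "scaffold": b.scaffold,
                    "start": b.start,
                    "end": b.end,
                    "mean_r1": round(b.mean_r1, 4),
                    "mean_r2": round(b.mean_r2, 4),
                    "dose_consistency": round(b.dose_consistency, 4),
                }
                for b in blocks
            ],
            **scan_info,
        },
        "presence": presence,
        "dose": dose,
    }
    io.write_report_json(report, outdir / "report.json")
    return report
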