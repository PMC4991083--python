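# Methods

## The genetic model

A B chromosome is modelled as a concatenation of A-complement blocks, each
duplicated to `copies_on_b` tandem copies, with point substitutions
("B-diagnostic variants") planted once per site at rate
`snv_rate_in_blocks` and shared by every copy — the substitutions are taken
to pre-date the amplification of the block.  The A complement itself is
diploid by default (`a_complement_copies = 2`), uniform in base
composition, and free of other repeats.  Three genotype classes exist: 0B,
1B and 2B.

Everything downstream exploits two consequences of this model:

1. **Dose**: a locus inside a block is present at `a + n·c` copies in a
   genome with `n` Bs (`a` A-complement copies, `c` copies per B), so read
   depth and qPCR template dose scale linearly with `n`;
2. **Sequence**: the B-borne copies carry alleles absent from the
   A complement, so a primer whose 3′ end sits on such an allele extends
   only when B template is present.

## Synthetic cohorts

`TruthSpec` fixes the study conditions; the defaults used throughout the
tests are one 20 kb scaffold, one 3 kb block at 10 copies per B, 1 %
diagnostic-substitution rate, 100 bp single-end error-free reads at 20×
depth per haploid genome copy, and triplicate qPCR with 0.2-cycle Gaussian
Ct noise around `Ct = C0 − log2(copies)`, `C0 = 28`.  These sizes resolve
kilobase-scale candidate regions with 1 kb windows while keeping a full
simulate–map–scan–design–genotype cycle under two seconds on one CPU core.
Read counts follow `N = round(pool_bases · depth / read_length)` exactly;
start positions are uniform; a single integer seed drives every stage
through independently derived substreams, so identical specs give
byte-identical FASTA/FASTQ/CSV output (the shipped frozen cohort's
checksum manifest pins this property).

Contigs standing in for a microdissected-chromosome assembly are exact
substrings of the B sequence with truncated-normal lengths
(mean 372 bp, sd 100, range 100–1000) — the scale of a low-pass 454-style
assembly.  For consensus building, an "ortholog panel" emulates related
species: copies of the block region mutated independently at 0.5 % per
site, with B-diagnostic positions held at the reference allele (the panel
species do not carry the B allele).

What the simulator deliberately omits: paired ends, indels, GC and
positional bias, platform error profiles, repeat families beyond the
planted blocks, mosaicism, and qPCR efficiency below 100 %.  Green tests
therefore demonstrate the correctness of the computations under the
declared model, not robustness to every artefact of real libraries; the
SAM/BAM entry point exists precisely so real alignments can replace the
built-in mapper.

## Coverage scan

Reads are counted per window by the leftmost aligned base — a conserving,
order-independent rule (window sums equal the library size by
construction).  Depths are normalised to reads per million and compared as
`(nd + α)/(nd0 + α)` with `α = 0.5`, which pins empty-versus-empty windows
at ratio 1.  Note that RPM normalisation makes the *background* ratio the
inverse of the library-size ratio: on desk-scale genomes where the B is a
large fraction of the 1B/2B read pools, background sits below 1 and block
ratios land below the raw copy ratios (the seed-1 example: `r̄1 = 2.87`
against a 6× copy ratio).  Real genomes, where the B is a few percent of
the pool, are much closer to the raw ratios.  Detection requires both `r1`
and `r2` to clear `θ = 1.5` — "elevated in every B-carrying sample" —
over ≥ 3 windows with ≤ 1 sub-threshold gap; all four knobs are exposed.
Candidate blocks are ranked by dose consistency, then within-block CV of
`r2`, then mean `r2`: regions whose 1B and 2B enrichments disagree with the
linear dose model, or fluctuate wildly, made poor qPCR targets in practice.

The built-in mapper places a read at the unique position whose k-prefix
(k = 20) matches exactly with total Hamming distance ≤ 2; ambiguous
best-hits are discarded and counted.  It exists so the synthetic loop needs
no external aligner and is checked against an exhaustive Hamming scan; it
is not intended for real reads.

## Contig placement and variant calling

Contigs are placed by exact 11-mer seeding plus banded affine-gap local
alignment (match +1, mismatch −2, gap open −4, gap extend −1, band 32
around each seeded diagonal cluster, both orientations).  On mutated-copy
pairs the banded score equals the full quadratic Smith–Waterman score
(property-tested against an independent full-DP oracle).  A mismatch
column becomes a diagnostic variant only if the consensus column is
unanimous across the panel and ≥ `min_flank = 20` conserved columns flank
it on both sides — enough room for a primer body in sequence shared by B
and non-B templates.  Consensus building requires pre-aligned
(equal-length) panels, consistent with the substitution-only model; ties
become IUPAC codes and are never conserved.

## Multiplex design and in-silico PCR

The allele-specific primer is cut from the contig so its 3′-terminal base
is the B allele; its length (18–40 nt, the range spanned by the shipped
assay tables) is chosen to put the nearest-neighbour melting temperature
closest to the middle of the 55–65 °C window.  Tm uses the unified
Watson–Crick stack parameters with terminal-initiation terms, the
`0.368·(N−1)·ln[Na+]` entropic salt correction at 50 mM monovalent salt,
and an excess-primer concentration term at 0.25 µM (verified against an
independent implementation of the same parameter set); the Wallace
`2(A+T)+4(G+C)` rule is available for quick estimates and accepts any
non-empty sequence, while the thermodynamic mode requires ≥ 8 nt.

Control forward and shared reverse primers must lie entirely in conserved,
variant-free columns **inside the contig-covered interval** — outside it,
conservation against the B sequence is unverified, and an unseen B variant
under a primer's 3′ end would silently kill the B product (this exact
failure appeared in validation and motivated the constraint).  The shared
reverse sits downstream of the variant so one primer closes both products;
because of that geometry the band-size gap equals the offset between the
two forward starts, and the control-forward search enforces it directly.
Assembly checks: band gap ≥ 40 bp (1 % agarose resolvability), pairwise Tm
span ≤ 5 °C, and no 3′-aligned cross-complementary run ≥ 5 nt between any
primer pair.  Failures are returned as structured results naming every
violated constraint, not exceptions — infeasible designs are an expected
outcome on short contigs.

In-silico PCR encodes the standard ARMS assumption: a site primes only if
the 3′-terminal base matches exactly, at most one mismatch falls in the
3′-terminal 5 nt, and at most `m_internal = 2` elsewhere; IUPAC-ambiguous
template positions count as mismatches.  Every forward/reverse site pair
with a positive product ≤ 2 kb is reported; distinct
(forward, reverse, length) classes are the bands a gel would show, which
collapses the per-copy hits of a high-copy template into one band.  The
presence call requires the control band (within ±5 bp of its expected
size): control + B band → B-positive, control alone → B-negative, no
control → invalid, regardless of other products.

## Dose calling

Replicates aggregate by mean with a sample-SD flag at 0.5 cycles (no
outlier rejection).  `GDR = 2^−ΔCt` with efficiency fixed at 2.0 per
cycle and no calibrator sample — the direct gene-dose-ratio form, not
ΔΔCt.  Calibration demands strictly increasing mean GDR across
0B < 1B < 2B and fails loudly otherwise, since an inversion invalidates
dose discrimination.  Classification is nearest-center in log2 space
(dosage is multiplicative, so log space makes the 1B/2B threshold
symmetric), with an ambiguity flag when the two nearest centers differ by
< 0.25 log2 units in distance; separability requires `c > a`, which any
useful marker satisfies.  The cohort fold change is the ratio of mean
GDRs with a seeded 1000-resample percentile bootstrap; noise-free cohorts
reproduce `(a + 2c)/(a + c)` to machine precision, and the B-exclusive
limit `a = 0` gives exactly 2.

## Design choices that were genuinely open

* **Normalisation**: reads-per-million was chosen over median-of-ratios
  because the detection statistic is a ratio of normalised tracks and only
  relative scaling matters; the background offset it introduces on
  desk-scale genomes is documented above and absorbed by `θ`.
* **Both-ratios threshold** (`r1 ≥ θ` AND `r2 ≥ θ`) rather than a joint
  statistic: it is the direct encoding of "elevated in every B-positive
  sample" and keeps each sample's evidence auditable.
* **Block ranking** by dose consistency first: among candidate regions,
  agreement with the linear dose model predicts qPCR usability better than
  raw enrichment does.
* **One shared reverse primer** rather than two independent pairs: it
  forces both products into one amplicon family, halves the dimer surface,
  and makes the band gap a pure geometry parameter.
* **Ct model** `C0 − log2(copies) + ε` with shared `C0` across assays: the
  simplest inverse of the quantity the dose caller estimates; systematic
  per-assay efficiency differences are out of scope (no efficiency
  correction is applied anywhere).

## Known limitations

The mapper and aligner are exact-seed methods for substitution-dominated,
desk-scale problems; the consensus builder does not align; segmentation is
run-merging, not an HMM or CBS, and breakpoints are window-resolution; the
priming model ignores secondary structure and thermodynamic competition;
dose calling assumes the reference gene's copy number is constant across
genotypes.  Each of these is behind a narrow interface so a heavier
replacement can be swapped in without touching the rest of the pipeline.
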