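# Methods

This note records the models, parameter choices, and numerical decisions
behind `lorespl`, and what the synthetic tests do and do not establish.

## Read model and demultiplexing

First-strand cDNA from barcoded oligo-dT priming is modelled as
`[barcode][poly-T][revcomp(insert)][common primer]`, emitted on either
strand with uniform per-base substitution errors. Demultiplexing probes
both strands:

- **Poly-T detector.** Longest window of ≥ 12 nt with ≥ 90 % T content,
  extended maximally and then trimmed back to its outermost T (the 90 %
  rule alone would absorb flanking non-T bases). The thresholds are
  declared defaults: 12 nt rejects genomic T-runs while two substitutions
  in a short tract still leave a detectable ≥ 90 % window.
- **Primer search.** Semi-global (infix) edit distance, ≤ 3 edits,
  leftmost minimal hit. Implemented as a numpy dynamic program
  (`lorespl._align`); "mismatches" are unit-cost edits (substitutions and
  indels), matching the edit-distance aligner semantics of the original
  protocol.
- **Barcode window.** 40 nt 5' of the poly-T start, extended 8 nt into
  the tract (its fuzzy boundary can absorb T-adjacent barcode bases); if
  only the primer anchors the read, the window is the first
  `barcode length + 40` nt. A read is assigned iff exactly one sample's
  barcode matches within 3 edits across both strands; zero matches →
  UNASSIGNED, two or more samples → AMBIGUOUS (including conflicting
  strands), both excluded downstream.
- **Trimming.** The insert between the poly-T end and the primer start is
  reverse complemented to mRNA sense. When an insert borders the tract
  with its own T/A bases the boundary is intrinsically ambiguous; the
  trim tests therefore allow edit-distance slack proportional to the
  error rate plus a 15-nt boundary allowance.

Default barcodes are 24 nt (native nanopore barcode length), generated
with pairwise edit distance ≥ 7 so a ≤ 3-edit matcher cannot confuse two
intact barcodes.

## Gene assignment

Score = overlap_bp / max(gene length, alignment reference span), computed
on 0-based half-open intervals (GTF converted on read). Strand is
ignored; ties break to the lexicographically smallest gene_id; secondary
and supplementary alignments are skipped. These tie/zero-overlap rules
are this package's declared defaults.

## PSI pileup and segmentation

- **CIGAR simplification** drops insertions, folds =/X into M, merges any
  reference-consuming segment < 10 bp into the preceding segment (taking
  its type; a run of leading short segments merges into the first long
  one), and coalesces same-type neighbours. Reference span is always
  preserved; the merge-type choice (type from the absorbing segment) is
  one of two defensible readings and is asserted by tests only through
  the span invariant and examples.
- **80 % filter.** Reads are kept iff aligned bases (M + I) / full read
  length (soft clips included) is strictly greater than 0.8. The source
  description is self-contradictory ("reads that were more than 80%
  aligned ... were excluded" vs its stated purpose of removing short
  spurious alignments); the evident intent is implemented, and
  `literal_eighty_percent_rule=True` honors the literal sentence.
- **Pileup.** Interior segments only (first and last segment of each read
  are ignored, suppressing 3'/5' end noise): M adds included + spanning,
  N and long D add spanning only — inclusion means "a base is present at
  the position", which a deletion does not provide. A consequence worth
  knowing: a retained intron merges with its flanking exons into one M
  segment, so retention is only measurable where that segment is
  interior, i.e. for introns whose neighbours are excised in the same
  molecule. Genes need ≥ 4 exons for a middle intron to carry retention
  signal; this mirrors the method being reimplemented, not a simulator
  artifact.
- **Coverage mask.** Exclude positions with spanning < 5 in any sample or
  replicate-mean spanning < 20. Masked positions are skipped by the
  segmentation without resetting the running mean (no gap rule is stated
  by the source method).
- **Segmentation.** Greedy left-to-right over usable positions of the
  pooled (positionwise-summed) pileup: close the region when
  |PSI(pos) − cumulative mean| > 0.1, restart the mean at PSI(pos). The
  pooled track spans all samples in the analysis so all conditions share
  one region set.
- **Region counts.** Per-sample means of included and spanning over the
  region's unmasked positions, rounded half away from zero. Regions whose
  mean PSI is < 0.05 in every sample are dropped (strict inequality:
  exactly 0.05 is kept).

## Differential retention

Retained counts k_i with totals n_i are modelled as NB with mean
μ_i = π·n_i and variance μ_i + α·μ_i², size r = 1/α; α < 1e-8 is
evaluated as the Poisson limit so the likelihood is continuous at the
α lower bound. Fits minimize the NLL with analytic gradients (L-BFGS-B,
π ∈ [1e-6, 1−1e-6], α ∈ [1e-9, 10]) from the multi-start grid
{0.1, 0.5, 0.9} × {0.01, 1} plus the Poisson closed form Σk/Σn.

Λ = exp(−nll_joint + nll_A + nll_B), clamped to (0, 1]. The χ²(df = 2)
tail of −2 ln Λ is co-reported; note sf_χ²(2)(x) = exp(−x/2), so this
"calibrated" transform equals Λ itself — the probability-scale score and
the nominal p-value coincide. **Calibration caveat:** with 3 replicates
per condition and freely fit per-condition dispersions the statistic is
anticonservative (empirical type-I ≈ 0.12–0.18 at nominal 0.05 for
totals ≈ 100; near-nominal only by ~12 replicates). The Welch t test on
replicate PSI values is calibrated at these sample sizes and is co-run
(`method="both"`); which statistic to trust for small designs is a user
decision the output table leaves open. Welch uses a machine-epsilon
variance floor for degenerate zero-variance inputs. BH adjustment is the
standard step-up with monotonicity enforcement, applied to the regions
whose component fits converged.

## Synthetic data: what it emulates, what it does not

The generator emulates barcoded read structure, either-strand emission,
uniform substitution errors, NB-dispersed per-(gene, sample) molecule
counts (variance μ + αμ², default α = 0.1 — typical cell-line replicate
dispersion), independent per-molecule Bernoulli intron retention (no
linkage model), uniform 15–30 nt poly-T tracts, optional soft clips
(0–8 nt) and short internal indels. Defaults: 150–300 bp exons, 80–150 bp
introns, 100 expected reads per gene per sample, 2 % error rate.

It does **not** emulate nanopore's homopolymer/indel-biased error
profile, truncated or chimeric reads, alignment errors (alignments are
emitted directly from the truth, with configurable decorations), or
transcript-level coverage bias. A green end-to-end test therefore
establishes correctness of the pipeline's logic and statistics under a
clean generative model, not robustness to every real-world artifact.

Region-level statistical tests sample counts directly
(`simulate_region_counts`): totals NB around 100, retained counts
binomial given totals (the read simulator's world) or NB-dispersed when a
test prescribes overdispersed retention.

## qPCR

The amplification model is the mechanistic MAK-style recurrence
D_{c+1} = D_c + k·ln(1 + D_c/k), fluorescence = baseline + D_c: early
cycles double per cycle, saturating as D approaches k, and D_0 is the
starting quantity in arbitrary units (the model cited by the original
protocol could not be identified; this choice is the package's own, with
the model isolated behind `qpcr_fit` for substitution). The fit is
Levenberg–Marquardt least squares in log(D_0), log(k), baseline, with D_0
multi-started across decades. Flat curves (amplitude below 10× the
scatter of the first five cycles) raise an error rather than returning a
quantity; fits with RMSE above a quarter of the curve amplitude are
rejected as non-converged. Relative expression: technical-duplicate mean
→ divide by same-replicate reference-gene mean → divide by the baseline
sample's normalized value → mean ± sample SE across biological
replicates.

Targeted intron assay defaults: a read spans the intron when its
simplified alignment covers 10 nt on both flanks and lacks it when ≥ 90 %
of intron positions fall in skip/deletion segments (partially spliced
molecules are a judgement call; both knobs are configurable). Replicate
splice fractions are summarized as mean ± 1 SD in logit space, with 0/1
clamped to [1/(N+1), N/(N+1)] for spanning count N.

## Known limitations

- Pileups are dense per-chromosome arrays: appropriate for targeted loci
  and synthetic genomes, memory-hungry for a whole mammalian genome.
- Gene-level log2 fold changes in the report stage are a deliberately
  simple library-size-normalized stand-in, not a dispersion-shrinkage DE
  engine; the counts matrix is exported for dedicated tools.
- The likelihood-ratio score should be treated as a ranking statistic at
  3 replicates (see calibration caveat above).
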