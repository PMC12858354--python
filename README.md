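# lorespl

Long-read nanopore cDNA splicing analysis: barcode demultiplexing,
overlap-ratio gene assignment, percent-spliced-in (PSI) pileups with
cumulative-average region segmentation, negative-binomial differential
intron-retention testing, targeted XBP1-style splicing readouts, and qPCR
relative quantification — together with a ground-truthed synthetic-data
generator so the entire pipeline is verifiable offline.

## Who this is for

Groups running multiplexed Oxford Nanopore cDNA experiments (barcoded
oligo-dT priming, strand-switch common primer) who want to quantify
intron retention and its change between conditions — for example IRE1/XBP1
unfolded-protein-response readouts, where removal of a short intron is the
signal of interest — without committing to exon-centric short-read tools.

## The method

**Demultiplexing.** Each read carries
`[barcode][poly-T][revcomp(insert)][common primer]` on one strand or the
other. The poly-T tract (longest window ≥ 12 nt at ≥ 90 % T) and the
common primer (best infix edit-distance hit) anchor a 40-nt window that is
searched for every sample barcode by semi-global edit distance; a read is
assigned when exactly one barcode matches within 3 edits, and excluded as
`UNASSIGNED`/`AMBIGUOUS` otherwise.

**Gene assignment.** A primary alignment is assigned to the gene
maximizing `overlap / max(gene length, alignment span)`; counts form a
genes × samples matrix loadable by DE tools.

**Splicing.** Simplified CIGARs (insertions dropped, segments < 10 bp
merged into the preceding segment) yield two per-position counts per
sample: *included* (a base is present, mismatches count) and *spanning*
(the alignment crosses the position). Reads ≤ 80 % aligned are dropped and
terminal segments are ignored. Positions with spanning < 5 in any sample
or replicate-mean < 20 are masked. PSI = included/spanning; the pooled
track is segmented greedily, closing a region when a position's PSI
deviates from the running cumulative mean by more than 0.1.

**Differential retention.** Per region and condition, replicate retained
counts k_i with totals n_i are fit by maximum likelihood under
NB(mean π·n_i, variance μ + αμ²). The likelihood ratio
Λ = L(joint)/(L(A)·L(B)) scores the same-retention-rate null (with its
χ²(df = 2) tail probability — numerically identical to Λ — co-reported),
alongside Welch's t on replicate PSI and Benjamini–Hochberg FDR.
Reporting uses the thresholds FDR ≤ 0.05 and |log2FC| ≥ 0.5.

**Targeted assays.** The intron splice fraction is
(reads lacking the intron)/(reads spanning it); gel densitometry uses
(XBP1s + hybrid/2)/(XBP1u + XBP1s + hybrid); qPCR starting quantities
come from a least-squares fit of the MAK-style amplification recurrence
F_{c+1} = F_c + k·ln(1 + F_c/k), then technical-duplicate averaging,
beta-actin normalization, and division by the baseline sample.

## Worked example

The numbered scripts under `analysis/` run the full demonstration; every
input is synthesized with known ground truth:

```bash
python analysis/01_simulate.py           # 3 genes, 6 samples, planted signal
python analysis/02_demux_and_count.py
python analysis/03_segment_regions.py
python analysis/04_differential_retention.py
python analysis/05_targeted_assays.py
```

`01` plants one differential intron (gene002 intron 2, retention 0.05 in
control vs 0.45 in treated) among eight null introns/exon regions and
prints its coordinates (`chrS:2814-2961`). `03` recovers that exact
interval as its own region:

```
  region00005: chrS:2814-2961  mean PSI 0.24
```

and `04` ranks it first with the planted effect size:

```
  region_id  start  end  delta_psi  pi_a   pi_b   lambda   p_welch      fdr
region00005   2814 2961      0.387 0.433 0.0513 8.03e-06   0.00109 7.22e-05
...
1 region(s) significant at FDR <= 0.05
```

`delta_psi` 0.387 matches the planted 0.40 difference, the fitted
retention rates `pi_a`/`pi_b` match the planted 0.45/0.05, and no null
region reaches significance. `05` reports the targeted splice fraction per
condition (0.944 control vs 0.541 treated; truth 0.95/0.55) and a qPCR
relative expression of 3.50 ± 0.09 for a true 4-fold induction with 15 %
quantity noise.

The same stages are exposed as a CLI (`lorespl simulate|demux|count|
pileup|test|xbp1|qpcr|report`) for use on real FASTQ/SAM/GTF inputs.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main computation from scratch: a full synthetic
pipeline run (simulation → demultiplexing → counts → pileup →
segmentation → differential testing → targeted assays) plus a
region-level differential-retention benchmark, logging stage summaries to
stderr and writing the results JSON to `--out`.
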