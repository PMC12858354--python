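"""End-to-end orchestration of the synthetic splicing pipeline.

``run_pipeline`` executes simulate -> demultiplex -> gene assignment ->
splice pileup -> region segmentation -> differential retention ->
targeted assays on a fully synthetic experiment, writing every
intermediate table plus a checksummed manifest, so one config + seed
reproduces the whole result bundle bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import assays, demux, genes, pileup, reporting, retention, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialized verbatim into outdir."""

    outdir: str = "lorespl_run"
    seed: int = 0
    design: Dict = field(default_factory=dict)  # SimulationDesign overrides
    condition_a: str = "treated"
    condition_b: str = "control"
    fdr_max: float = 0.05
    min_abs_log2fc: float = 0.5
    segment_threshold: float = pileup.SEGMENT_THRESHOLD
    min_cov_sample: int = pileup.MIN_COV_SAMPLE
    min_cov_mean: float = pileup.MIN_COV_MEAN
    min_region_psi: float = pileup.MIN_REGION_PSI
    min_aligned_fraction: float = pileup.MIN_ALIGNED_FRACTION
    literal_eighty_percent_rule: bool = False
    method: str = "both"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run every stage on a synthetic experiment; returns the result bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    design = simulate.SimulationDesign(**{"seed": config.seed, **config.design})
    reference = simulate.make_reference(design)
    reference.write_fasta(outdir / "genome.fasta")
    reference.write_gtf(outdir / "annotation.gtf")
    simulate.write_barcode_manifest(design, outdir / "barcodes.tsv")

    logger.info("simulate: %d genes, %d samples", design.n_genes, len(design.samples))
    records, truth = simulate.simulate_reads(design, reference)
    simulate.write_fastq(records, outdir / "reads.fastq")
    truth.write_tsv(outdir / "ground_truth.tsv")
    alignments, header, _ = simulate.simulate_alignments(design, reference)
    simulate.write_sam(alignments, header, outdir / "alignments.sam")

    barcode_set = demux.BarcodeSet(design.barcode_set, design.common_primer)
    report = demux.demultiplex_fastq(outdir / "reads.fastq", barcode_set, outdir / "demux")
    logger.info("demux: %d/%d reads assigned", int(report["sample"].isin(design.samples).sum()),
                len(report))

    gene_models = genes.read_gtf_genes(outdir / "annotation.gtf")
    sample_of = dict(zip(report["read_id"],
                         report["sample"].where(report["sample"].isin(design.samples), "")))
    assignments = genes.assign_alignments(alignments, gene_models, sample_of=sample_of)
    counts = genes.count_genes(assignments, gene_models, samples=design.samples)
    counts.to_csv(outdir / "gene_counts.tsv", sep="\t")

    chrom_len = len(reference.sequence)
    pileups = []
    for sample in design.samples:
        per_sample = [a for a in alignments if a.get_tag("RG") == sample]
        pileups.append(pileup.build_pileup(
            per_sample, design.chromosome, chrom_len, sample_id=sample,
            min_aligned_fraction=config.min_aligned_fraction,
            literal_eighty_percent_rule=config.literal_eighty_percent_rule))
    excluded = pileup.coverage_mask(pileups, config.min_cov_sample, config.min_cov_mean)
    pooled = pileups[0]
    for p in pileups[1:]:
        pooled = pooled + p
    regions = pileup.segment_regions(pooled, excluded, config.segment_threshold)
    regions = pileup.filter_regions(regions, pileups, config.min_region_psi)
    pileup.regions_to_bed(regions, outdir / "regions.bed")
    logger.info("segmentation: %d regions after filters", len(regions))

    cond_of = design.sample_condition
    rows = []
    for i, region in enumerate(regions, 1):
        rc = pileup.region_counts(region, pileups)
        for rec in rc.itertuples():
            rows.append({"region_id": f"region{i:05d}", "chromosome": region.chromosome,
                         "start": region.start, "end": region.end,
                         "sample": rec.sample, "condition": cond_of[rec.sample],
                         "retained_avg": rec.retained_avg, "total_avg": rec.total_avg})
    region_table = pd.DataFrame(rows, columns=[
        "region_id", "chromosome", "start", "end", "sample", "condition",
        "retained_avg", "total_avg"])
    region_table.to_csv(outdir / "region_counts.tsv", sep="\t", index=False)

    results = retention.test_regions(region_table, config.condition_a, config.condition_b,
                                     method=config.method)
    results.to_csv(outdir / "retention_tests.tsv", sep="\t", index=False)
    if not results.empty:
        volcano = reporting.export_volcano_table(results)
        volcano.to_csv(outdir / "volcano_regions.tsv", sep="\t", index=False)

    samples_a = [s for s in design.samples if cond_of[s] == config.condition_a]
    samples_b = [s for s in design.samples if cond_of[s] == config.condition_b]
    fc = reporting.gene_log2fc(counts, samples_a, samples_b)
    welch_p = []
    lib = counts.sum(axis=0).astype(float).replace(0, np.nan)
    norm = counts / lib * lib.mean()
    for gene_id in counts.index:
        try:
            _, p = retention.welch_psi_test(norm.loc[gene_id, samples_a],
                                            norm.loc[gene_id, samples_b])
        except ValueError:
            p = np.nan
        welch_p.append(p)
    fc["p_welch"] = welch_p
    ok = fc["p_welch"].notna()
    fc["fdr"] = np.nan
    if ok.any():
        fc.loc[ok, "fdr"] = retention.bh_fdr(fc.loc[ok, "p_welch"].to_numpy())
    fc = reporting.apply_significance(
        fc, reporting.SignificanceFilter(config.fdr_max, config.min_abs_log2fc))
    fc.to_csv(outdir / "gene_fold_changes.tsv", sep="\t")

    # targeted assay on the first gene's first intron
    target_gene = reference.genes[0]
    intron = target_gene.introns[0]
    target = assays.IntronTarget(design.chromosome, intron[0], intron[1])
    xbp1_rows = []
    for sample in design.samples:
        per_sample = [a for a in alignments if a.get_tag("RG") == sample]
        frac, spliced, spanning = assays.intron_splice_fraction(per_sample, target)
        xbp1_rows.append({"sample": sample, "condition": cond_of[sample],
                          "fraction": frac, "spliced": spliced, "spanning": spanning})
    xbp1 = pd.DataFrame(xbp1_rows)
    xbp1.to_csv(outdir / "targeted_intron.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.rglob("*")) if p.is_file()
                    and p.name != "manifest.json"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "design": design, "reference": reference, "truth": truth,
        "demux_report": report, "counts": counts, "regions": regions,
        "region_counts": region_table, "results": results,
        "gene_fold_changes": fc, "targeted_intron": xbp1,
        "manifest": manifest,
    }
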