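"""Gene assignment by the overlap-ratio rule and gene counting.

Each primary alignment is assigned to the gene whose annotation maximizes
``overlap_bp / max(gene length, alignment reference span)`` — a score in
[0, 1] that penalizes both reads dwarfed by a long gene and reads running
far past a short one.  Assignments are tallied into a genes x samples
counts matrix in a layout directly loadable as a DE-analysis counts table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam


@dataclass(frozen=True)
class GeneModel:
    """Gene-level interval; coordinates 0-based half-open internally."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gtf_genes(path: str | Path) -> List[GeneModel]:
    """Gene features from a GTF (1-based inclusive on disk)."""
    genes: List[GeneModel] = []
    seen: set = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                (kv.split(" ", 1)[0], kv.split(" ", 1)[1].strip('"'))
                for kv in (p.strip() for p in fields[8].split(";")) if " " in kv)
            gene_id = attrs.get("gene_id", f"{fields[0]}:{fields[3]}-{fields[4]}")
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id}")
            seen.add(gene_id)
            genes.append(GeneModel(
                gene_id=gene_id, chromosome=fields[0], strand=fields[6],
                start=int(fields[3]) - 1, end=int(fields[4])))
    return genes


def reference_span(alignment: pysam.AlignedSegment) -> int:
    return alignment.reference_end - alignment.reference_start


def overlap_score(chrom: str, ref_start: int, ref_end: int, gene: GeneModel) -> float:
    """Overlap ratio: shared bp over the longer of gene and alignment span."""
    if chrom != gene.chromosome:
        return 0.0
    overlap = min(ref_end, gene.end) - max(ref_start, gene.start)
    if overlap <= 0:
        return 0.0
    return overlap / max(gene.length, ref_end - ref_start)


def assign_gene(chrom: str, ref_start: int, ref_end: int,
                gene_models: Sequence[GeneModel]) -> Optional[str]:
    """Gene with maximal overlap score; ties go to the smallest gene_id."""
    best_id: Optional[str] = None
    best_score = 0.0
    for gene in gene_models:
        score = overlap_score(chrom, ref_start, ref_end, gene)
        if score > best_score or (score == best_score and score > 0
                                  and (best_id is None or gene.gene_id < best_id)):
            best_score, best_id = score, gene.gene_id
    return best_id


def assign_alignments(alignments: Iterable[pysam.AlignedSegment],
                      gene_models: Sequence[GeneModel],
                      sample_of: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Assign primary alignments to genes.

    Sample labels are taken from the RG tag unless ``sample_of`` maps
    read_id -> sample.  Secondary and supplementary alignments are
    skipped so each read yields at most one assignment.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chromosome, []).append(g)
    rows = []
    for a in alignments:
        if a.is_unmapped or a.is_secondary or a.is_supplementary:
            continue
        if sample_of is not None:
            sample = sample_of.get(a.query_name, "")
        else:
            sample = a.get_tag("RG") if a.has_tag("RG") else ""
        gene = assign_gene(a.reference_name, a.reference_start, a.reference_end,
                           by_chrom.get(a.reference_name, ()))
        rows.append({"read_id": a.query_name, "sample": sample,
                     "gene_id": gene if gene is not None else ""})
    return pd.DataFrame(rows, columns=["read_id", "sample", "gene_id"])


def count_genes(assignments: pd.DataFrame, gene_models: Sequence[GeneModel],
                samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Genes x samples integer counts matrix; unassigned reads excluded."""
    gene_index = [g.gene_id for g in gene_models]
    if samples is None:
        samples = sorted(s for s in assignments["sample"].unique() if s)
    counts = pd.DataFrame(0, index=pd.Index(gene_index, name="gene_id"),
                          columns=list(samples), dtype=int)
    assigned = assignments[(assignments["gene_id"] != "") & (assignments["sample"] != "")]
    tally = assigned.groupby(["gene_id", "sample"]).size()
    for (gene, sample), n in tally.items():
        if gene in counts.index and sample in counts.columns:
            counts.loc[gene, sample] = int(n)
    return counts
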