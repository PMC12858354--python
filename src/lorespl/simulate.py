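"""Synthetic long-read experiments with known ground truth.

Generates a small genome of intron-containing genes, barcoded oligo-dT
cDNA reads, spliced alignments whose CIGARs encode condition-specific
intron retention, negative-binomially dispersed per-gene read counts, and
qPCR amplification curves — everything the downstream stages consume, so
the whole pipeline is testable offline against the emitted ground truth.

Read layout (cDNA orientation): ``[barcode][poly-T][revcomp(insert)]
[common primer]``, with uniform substitution errors.  Intron retention is
independent per intron per molecule at the design's PSI; per-(gene,
sample) molecule counts are NB(mean = abundance, variance = mu + alpha *
mu^2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from ._align import levenshtein, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default strand-switch (common) primer, 5'->3' as it appears at the read 3' end
DEFAULT_COMMON_PRIMER = "AAGCAGTGGTATCAACGCAGAG"

#: minimum pairwise edit distance between generated barcodes; a <=3-edit
#: matcher then cannot confuse two intact barcodes
MIN_BARCODE_DISTANCE = 7

DEFAULT_BARCODE_LEN = 24  # matches native nanopore barcode length


class ConfigurationError(ValueError):
    pass


def generate_barcodes(n: int, rng: np.random.Generator,
                      length: int = DEFAULT_BARCODE_LEN,
                      min_distance: int = MIN_BARCODE_DISTANCE) -> List[str]:
    """Random barcodes with pairwise edit distance >= ``min_distance``."""
    barcodes: List[str] = []
    attempts = 0
    while len(barcodes) < n:
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if all(levenshtein(cand, b) >= min_distance for b in barcodes):
            barcodes.append(cand)
        attempts += 1
        if attempts > 1000 * n:
            raise ConfigurationError("cannot satisfy barcode distance constraint")
    return barcodes


@dataclass
class SimulationDesign:
    """Full specification of a synthetic multiplexed splicing experiment.

    ``psi`` has shape (n_introns, n_conditions) with introns numbered
    gene-major (gene 0 intron 0, gene 0 intron 1, ..., gene 1 intron 0).
    ``abundance`` is the expected read count per gene per sample, either a
    scalar or an (n_genes, n_samples) array.
    """

    n_genes: int = 4
    exons_per_gene: int = 3
    exon_len: Tuple[int, int] = (150, 300)
    intron_len: Tuple[int, int] = (80, 150)
    conditions: Tuple[str, ...] = ("control", "treated")
    replicates_per_condition: int = 3
    psi: Optional[np.ndarray] = None
    abundance: float | np.ndarray = 100.0
    nb_dispersion: float = 0.1
    read_error_rate: float = 0.02
    barcode_set: Optional[Dict[str, str]] = None
    common_primer: str = DEFAULT_COMMON_PRIMER
    seed: int = 0
    polyt_len: Tuple[int, int] = (15, 30)
    soft_clip: Tuple[int, int] = (0, 8)
    indel_rate: float = 0.0  # per-molecule probability of one short internal indel
    fraction_reverse: float = 0.5  # reads emitted on the opposite strand
    intergenic_gap: int = 500
    chromosome: str = "chrS"
    chromosome_length: Optional[int] = None  # error if genes do not fit

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.exons_per_gene < 2:
            raise ConfigurationError("need >= 1 gene with >= 2 exons")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if not 0 <= self.read_error_rate < 1:
            raise ConfigurationError("read_error_rate must be in [0, 1)")
        if self.psi is None:
            self.psi = np.full((self.n_introns, len(self.conditions)), 0.1)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.shape != (self.n_introns, len(self.conditions)):
            raise ConfigurationError(
                f"psi must have shape {(self.n_introns, len(self.conditions))}")
        if np.any((self.psi < 0) | (self.psi > 1)):
            raise ConfigurationError("psi values must lie in [0, 1]")
        if self.barcode_set is None:
            rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0xBC)))
            codes = generate_barcodes(len(self.samples), rng)
            self.barcode_set = dict(zip(self.samples, codes))
        else:
            codes = list(self.barcode_set.values())
            for i, a in enumerate(codes):
                for b in codes[i + 1:]:
                    if levenshtein(a, b) < MIN_BARCODE_DISTANCE:
                        raise ConfigurationError("barcodes closer than minimum edit distance")

    @property
    def n_introns(self) -> int:
        return self.n_genes * (self.exons_per_gene - 1)

    @property
    def samples(self) -> List[str]:
        return [f"{c}_rep{r + 1}" for c in self.conditions
                for r in range(self.replicates_per_condition)]

    @property
    def sample_condition(self) -> Dict[str, str]:
        return {s: s.rsplit("_rep", 1)[0] for s in self.samples}

    def abundance_matrix(self) -> np.ndarray:
        ab = np.asarray(self.abundance, dtype=float)
        if ab.ndim == 0:
            ab = np.full((self.n_genes, len(self.samples)), float(ab))
        if ab.shape != (self.n_genes, len(self.samples)):
            raise ConfigurationError("abundance must be scalar or genes x samples")
        return ab


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    introns: Tuple[Tuple[int, int], ...]


@dataclass
class Reference:
    chromosome: str
    sequence: str
    genes: List[GeneAnnotation]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chromosome}\n")
            for i in range(0, len(self.sequence), 60):
                fh.write(self.sequence[i:i + 60] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        """GTF (1-based inclusive) with gene and exon features."""
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}";'
                fh.write("\t".join([
                    g.chromosome, "lorespl_sim", "gene", str(g.start + 1),
                    str(g.end), ".", g.strand, ".", attrs]) + "\n")
                for k, (s, e) in enumerate(g.exons, 1):
                    fh.write("\t".join([
                        g.chromosome, "lorespl_sim", "exon", str(s + 1), str(e),
                        ".", g.strand, ".",
                        attrs + f' exon_number "{k}";']) + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_reference(design: SimulationDesign) -> Reference:
    """Synthetic chromosome of non-overlapping alternating exon/intron genes."""
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0x9E)))
    cursor = design.intergenic_gap
    genes: List[GeneAnnotation] = []
    for g in range(design.n_genes):
        exons: List[Tuple[int, int]] = []
        introns: List[Tuple[int, int]] = []
        start = cursor
        for k in range(design.exons_per_gene):
            elen = int(rng.integers(design.exon_len[0], design.exon_len[1] + 1))
            exons.append((cursor, cursor + elen))
            cursor += elen
            if k < design.exons_per_gene - 1:
                ilen = int(rng.integers(design.intron_len[0], design.intron_len[1] + 1))
                introns.append((cursor, cursor + ilen))
                cursor += ilen
        genes.append(GeneAnnotation(
            gene_id=f"gene{g + 1:03d}", chromosome=design.chromosome,
            start=start, end=cursor, strand="+",
            exons=tuple(exons), introns=tuple(introns)))
        cursor += design.intergenic_gap
    total_len = cursor
    if design.chromosome_length is not None:
        if design.chromosome_length < total_len:
            raise ConfigurationError(
                f"genes need {total_len} bp but chromosome_length is {design.chromosome_length}")
        total_len = design.chromosome_length
    sequence = _random_seq(rng, total_len)
    return Reference(design.chromosome, sequence, genes)


@dataclass
class GroundTruth:
    """Per-read and per-(gene, sample) truth for a simulated experiment.

    ``reads`` columns: read_id, sample, condition, gene_id, pos, cigar,
    retained (comma-joined 0/1 per intron), insert (sense sequence),
    orientation.  ``counts`` is the genes x samples molecule-count table.
    """

    reads: pd.DataFrame
    counts: pd.DataFrame
    psi: np.ndarray
    design: SimulationDesign

    def write_tsv(self, path: str | Path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


def _cigar_for_molecule(gene: GeneAnnotation, retained: Sequence[bool]) -> List[Tuple[str, int]]:
    """Spliced CIGAR (M/N segments) for a molecule of this gene."""
    segs: List[Tuple[str, int]] = []

    def push(op: str, length: int) -> None:
        if length <= 0:
            return
        if segs and segs[-1][0] == op:
            segs[-1] = (op, segs[-1][1] + length)
        else:
            segs.append((op, length))

    for k, (es, ee) in enumerate(gene.exons):
        push("M", ee - es)
        if k < len(gene.introns):
            is_, ie = gene.introns[k]
            push("M" if retained[k] else "N", ie - is_)
    return segs


def _molecule_sequence(reference: Reference, gene: GeneAnnotation,
                       retained: Sequence[bool]) -> str:
    parts = []
    for k, (es, ee) in enumerate(gene.exons):
        parts.append(reference.sequence[es:ee])
        if k < len(gene.introns) and retained[k]:
            is_, ie = gene.introns[k]
            parts.append(reference.sequence[is_:ie])
    return "".join(parts)


def _simulate_molecules(design: SimulationDesign, reference: Reference) -> GroundTruth:
    """Draw molecule counts and per-molecule intron retention (seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0x401)))
    samples = design.samples
    cond_index = {c: i for i, c in enumerate(design.conditions)}
    ab = design.abundance_matrix()
    alpha = design.nb_dispersion
    counts = np.zeros((design.n_genes, len(samples)), dtype=int)
    for gi in range(design.n_genes):
        for si in range(len(samples)):
            mu = ab[gi, si]
            if mu <= 0:
                continue
            if alpha == 0:
                counts[gi, si] = rng.poisson(mu)
            else:
                r = 1.0 / alpha
                counts[gi, si] = rng.negative_binomial(r, r / (r + mu))
    n_introns_per_gene = design.exons_per_gene - 1
    rows = []
    read_no = 0
    for si, sample in enumerate(samples):
        ci = cond_index[design.sample_condition[sample]]
        for gi, gene in enumerate(reference.genes):
            psi_g = design.psi[gi * n_introns_per_gene:(gi + 1) * n_introns_per_gene, ci]
            for _ in range(counts[gi, si]):
                retained = rng.random(n_introns_per_gene) < psi_g
                cigar = _cigar_for_molecule(gene, retained)
                rows.append({
                    "read_id": f"read{read_no:07d}",
                    "sample": sample,
                    "condition": design.conditions[ci],
                    "gene_id": gene.gene_id,
                    "pos": gene.start,
                    "cigar": "".join(f"{l}{op}" for op, l in cigar),
                    "retained": ",".join("1" if r else "0" for r in retained),
                    "insert": _molecule_sequence(reference, gene, retained),
                    "orientation": "forward",
                })
                read_no += 1
    reads = pd.DataFrame(rows, columns=[
        "read_id", "sample", "condition", "gene_id", "pos", "cigar",
        "retained", "insert", "orientation"])
    counts_df = pd.DataFrame(counts, index=[g.gene_id for g in reference.genes],
                             columns=samples)
    return GroundTruth(reads=reads, counts=counts_df, psi=design.psi, design=design)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    if hit.size:
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def simulate_reads(design: SimulationDesign, reference: Reference
                   ) -> Tuple[List[Tuple[str, str, str]], GroundTruth]:
    """FASTQ records (id, sequence, quality) plus ground truth.

    Each read is [barcode][poly-T][revcomp(insert)][common primer] with
    uniform substitution errors; a ``fraction_reverse`` share is emitted
    reverse complemented to exercise orientation handling.
    """
    truth = _simulate_molecules(design, reference)
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0xF4)))
    records: List[Tuple[str, str, str]] = []
    orientations = []
    for row in truth.reads.itertuples():
        barcode = design.barcode_set[row.sample]
        tlen = int(rng.integers(design.polyt_len[0], design.polyt_len[1] + 1))
        read = barcode + "T" * tlen + reverse_complement(row.insert) + design.common_primer
        read = _mutate(read, design.read_error_rate, rng)
        if rng.random() < design.fraction_reverse:
            read = reverse_complement(read)
            orientations.append("reverse")
        else:
            orientations.append("forward")
        records.append((row.read_id, read, "I" * len(read)))
    truth.reads["orientation"] = orientations
    return records, truth


def write_fastq(records: Sequence[Tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def simulate_alignments(design: SimulationDesign, reference: Reference
                        ) -> Tuple[List[pysam.AlignedSegment], pysam.AlignmentHeader, GroundTruth]:
    """Spliced SAM alignments matching the same molecules as simulate_reads.

    Retained introns appear as M over the intron, excised introns as N;
    soft clips of random length are added at both ends and, at
    ``indel_rate``, one short internal insertion or deletion.
    """
    truth = _simulate_molecules(design, reference)
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0xA1)))
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.chromosome, "LN": len(reference.sequence)}],
    })
    out: List[pysam.AlignedSegment] = []
    for row in truth.reads.itertuples():
        segs = [(op, int(l)) for l, op in re.findall(r"(\d+)([MN])", row.cigar)]
        if design.indel_rate > 0 and rng.random() < design.indel_rate:
            segs = _inject_indel(segs, rng)
        clip5 = int(rng.integers(design.soft_clip[0], design.soft_clip[1] + 1))
        clip3 = int(rng.integers(design.soft_clip[0], design.soft_clip[1] + 1))
        cig: List[Tuple[int, int]] = []
        if clip5:
            cig.append((pysam.CSOFT_CLIP, clip5))
        opmap = {"M": pysam.CMATCH, "N": pysam.CREF_SKIP,
                 "D": pysam.CDEL, "I": pysam.CINS}
        cig.extend((opmap[op], l) for op, l in segs)
        if clip3:
            cig.append((pysam.CSOFT_CLIP, clip3))
        a = pysam.AlignedSegment(header)
        a.query_name = row.read_id
        a.reference_id = 0
        a.reference_start = row.pos
        a.mapping_quality = 60
        a.cigartuples = cig
        qlen = sum(l for op, l in cig if op in
                   (pysam.CMATCH, pysam.CINS, pysam.CSOFT_CLIP))
        a.query_sequence = _random_seq(rng, qlen)  # bases unused downstream
        a.flag = 0
        a.set_tag("RG", row.sample)
        out.append(a)
    return out, header, truth


def _inject_indel(segs: List[Tuple[str, int]], rng: np.random.Generator
                  ) -> List[Tuple[str, int]]:
    """Split one M segment with a 1-5 bp I or D, keeping segments valid."""
    m_idx = [i for i, (op, l) in enumerate(segs) if op == "M" and l >= 30]
    if not m_idx:
        return segs
    i = int(rng.choice(m_idx))
    op, l = segs[i]
    size = int(rng.integers(1, 6))
    at = int(rng.integers(10, l - 10))
    kind = "I" if rng.random() < 0.5 else "D"
    left = [("M", at), (kind, size), ("M", l - at if kind == "I" else l - at - size)]
    left = [(o, n) for o, n in left if n > 0]
    return segs[:i] + left + segs[i + 1:]


def write_sam(alignments: Sequence[pysam.AlignedSegment],
              header: pysam.AlignmentHeader, path: str | Path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            fh.write(a)


def write_barcode_manifest(design: SimulationDesign, path: str | Path) -> None:
    pd.DataFrame({
        "sample_id": list(design.barcode_set),
        "barcode": list(design.barcode_set.values()),
    }).to_csv(path, sep="\t", index=False)


def simulate_region_counts(psi_a: Sequence[float], psi_b: Sequence[float],
                           replicates: int = 3, mean_total: float = 100.0,
                           total_dispersion: float = 0.1,
                           retention_model: str = "binomial",
                           retention_dispersion: float = 0.2,
                           seed: int = 0) -> pd.DataFrame:
    """Region-level retained/total counts for two conditions.

    Emulates the per-region replicate counts the pileup stage produces,
    without simulating reads: totals are NB(mean_total, total_dispersion)
    per replicate; retained counts are Binomial(total, psi) under
    ``retention_model="binomial"`` (per-molecule Bernoulli retention, the
    read simulator's world) or NB(mean psi*total, retention_dispersion)
    clipped to the total under ``"nb"``.  Returns the long-format table
    the differential-retention stage consumes.
    """
    psi_a = np.asarray(psi_a, dtype=float)
    psi_b = np.asarray(psi_b, dtype=float)
    if psi_a.shape != psi_b.shape:
        raise ValueError("psi_a and psi_b must have equal length")
    if retention_model not in ("binomial", "nb"):
        raise ValueError(f"unknown retention model {retention_model!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(psi_a.size):
        for cond, pi in (("A", psi_a[i]), ("B", psi_b[i])):
            if total_dispersion > 0:
                r = 1.0 / total_dispersion
                totals = rng.negative_binomial(r, r / (r + mean_total), replicates)
            else:
                totals = rng.poisson(mean_total, replicates)
            totals = np.maximum(totals, 1)
            if retention_model == "binomial":
                retained = rng.binomial(totals, pi)
            else:
                mu = np.clip(pi, 1e-12, None) * totals
                r = 1.0 / max(retention_dispersion, 1e-12)
                retained = np.minimum(rng.negative_binomial(r, r / (r + mu)), totals)
            for j in range(replicates):
                rows.append({
                    "region_id": f"region{i + 1:05d}", "chromosome": "synthetic",
                    "start": i, "end": i + 1,
                    "sample": f"{cond}_rep{j + 1}", "condition": cond,
                    "retained_avg": int(retained[j]), "total_avg": int(totals[j]),
                })
    return pd.DataFrame(rows)


# --- qPCR -----------------------------------------------------------------

@dataclass(frozen=True)
class QpcrModelParams:
    """MAK-style amplification model: D_{c+1} = D_c + k ln(1 + D_c / k)."""

    k: float = 1000.0  # saturation constant (arbitrary fluorescence units)
    baseline: float = 50.0


def amplification_curve(quantity: float, params: QpcrModelParams, cycles: int) -> np.ndarray:
    """Noise-free fluorescence at cycles 1..cycles for a starting quantity."""
    d = float(quantity)
    out = np.empty(cycles)
    for c in range(cycles):
        if d > 0:
            d = d + params.k * np.log1p(d / params.k)
        out[c] = params.baseline + d
    return out


def simulate_qpcr(true_quantities: Dict[str, float],
                  model_params: QpcrModelParams = QpcrModelParams(),
                  cycles: int = 40, noise_sd: float = 0.0,
                  seed: int = 0) -> pd.DataFrame:
    """Cycle-indexed fluorescence curves with Gaussian noise.

    Keys of ``true_quantities`` label the curves (e.g. "sample|gene|rep");
    the returned frame has columns (curve_id, cycle, fluorescence).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for curve_id, q in true_quantities.items():
        if q < 0:
            raise ValueError("quantities must be >= 0")
        f = amplification_curve(q, model_params, cycles)
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=cycles)
        for c, v in enumerate(f, start=1):
            rows.append({"curve_id": curve_id, "cycle": c, "fluorescence": v})
    return pd.DataFrame(rows)
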