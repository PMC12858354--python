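"""Percent-spliced-in pileups and cumulative-average region segmentation.

Spliced long-read alignments are reduced to simplified CIGAR segments
(match-like / deletion / skip), and every genomic position accumulates
two counts per sample: ``included`` — reads that put a base at the
position (mismatches count) — and ``spanning`` — reads whose alignment
crosses the position whether or not a base is present.  PSI at a
position is included / spanning.

Filters follow the analysis this package reimplements:

* CIGAR segments shorter than 10 bp are merged into the preceding
  segment (a leading short segment merges forward); insertions are
  ignored.
* Reads are kept only when more than 80 % of their bases (soft clips
  included in the denominator) are aligned, dropping short spurious
  alignments.  A ``literal_eighty_percent_rule`` flag inverts this to
  the literally printed (self-contradictory) form.
* The first and last segment of every read contribute nothing, taming
  3'/5' alignment-end noise.
* Positions with spanning coverage < 5 in any sample or replicate-mean
  spanning < 20 are excluded.

Replicate pileups are pooled by positionwise summation, and the pooled
PSI track is segmented greedily: a region closes whenever the PSI at the
next position differs from the running cumulative mean by more than 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

MIN_SEGMENT = 10  # bp; shorter simplified-CIGAR regions merge into the previous one
MIN_ALIGNED_FRACTION = 0.8
SEGMENT_THRESHOLD = 0.1  # |PSI - cumulative mean| that opens a new region
MIN_COV_SAMPLE = 5
MIN_COV_MEAN = 20
MIN_REGION_PSI = 0.05  # regions below this in every sample are discarded

_REF_CONSUMING = {"M", "D", "N"}
_OP_NAME = {
    pysam.CMATCH: "M", pysam.CINS: "I", pysam.CDEL: "D", pysam.CREF_SKIP: "N",
    pysam.CSOFT_CLIP: "S", pysam.CHARD_CLIP: "H", pysam.CPAD: "P",
    pysam.CEQUAL: "M", pysam.CDIFF: "M",
}


def simplify_cigar(cigar: Sequence[Tuple[str, int]]) -> List[Tuple[str, int]]:
    """Simplify a CIGAR to coarse reference segments.

    Insertions (and clips) are dropped; =/X are folded into M; any
    remaining segment shorter than ``MIN_SEGMENT`` is merged into the
    preceding segment, taking its type (a run of leading short segments
    merges into the first long one); adjacent same-type segments
    coalesce.  Total reference span is preserved.
    """
    if not cigar:
        raise ValueError("empty CIGAR")
    segs = [("M" if op in "=X" else op, int(length)) for op, length in cigar
            if ("M" if op in "=X" else op) in _REF_CONSUMING and length > 0]
    if not segs:
        raise ValueError("CIGAR has no reference-consuming operations")
    out: List[Tuple[str, int]] = []
    pending_lead = 0  # leading short length awaiting the first long segment
    for op, length in segs:
        if not out:
            if length < MIN_SEGMENT:
                pending_lead += length
                continue
            out.append((op, length + pending_lead))
            pending_lead = 0
            continue
        if length < MIN_SEGMENT:
            prev_op, prev_len = out[-1]
            out[-1] = (prev_op, prev_len + length)
        elif out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))
    if not out:
        # every segment was short: collapse to one segment of the first type
        out = [(segs[0][0], pending_lead)]
    return out


def cigartuples_to_ops(cigartuples: Sequence[Tuple[int, int]]) -> List[Tuple[str, int]]:
    return [(_OP_NAME[op], length) for op, length in cigartuples]


def aligned_fraction(alignment: pysam.AlignedSegment) -> float:
    """Aligned read bases (match-like + insertions) over the full read length.

    Soft-clipped bases count in the denominator only.
    """
    aligned = 0
    total = 0
    for op, length in alignment.cigartuples:
        name = _OP_NAME.get(op, "?")
        if name in ("M", "I"):
            aligned += length
            total += length
        elif name == "S":
            total += length
    if total == 0:
        raise ValueError(f"{alignment.query_name}: zero-length read")
    return aligned / total


@dataclass
class Pileup:
    """Per-position included / spanning counts for one sample and chromosome."""

    chromosome: str
    sample_id: str
    included: np.ndarray
    spanning: np.ndarray

    @classmethod
    def zeros(cls, chromosome: str, length: int, sample_id: str = "") -> "Pileup":
        return cls(chromosome, sample_id,
                   np.zeros(length, dtype=np.int64), np.zeros(length, dtype=np.int64))

    def __add__(self, other: "Pileup") -> "Pileup":
        if other.chromosome != self.chromosome:
            raise ValueError("cannot pool pileups of different chromosomes")
        return Pileup(self.chromosome, "pooled",
                      self.included + other.included, self.spanning + other.spanning)

    def psi(self) -> np.ndarray:
        """PSI per position; NaN where nothing spans."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.spanning > 0, self.included / self.spanning, np.nan)

    def to_bedgraph(self, path) -> None:
        cov = np.flatnonzero(self.spanning > 0)
        with open(path, "w") as fh:
            for p in cov:
                fh.write(f"{self.chromosome}\t{p}\t{p + 1}\t"
                         f"{self.included[p]}\t{self.spanning[p]}\n")


def read_contributions(reference_start: int, simplified: Sequence[Tuple[str, int]]
                       ) -> List[Tuple[str, int, int]]:
    """Interior-segment intervals a read contributes: (kind, start, end).

    kind is "included" for match-like segments and "spanning" for skips
    and deletions; the first and last simplified segments are dropped.
    """
    coords = []
    pos = reference_start
    for op, length in simplified:
        coords.append((op, pos, pos + length))
        pos += length
    interior = coords[1:-1]
    return [("included" if op == "M" else "spanning", s, e) for op, s, e in interior]


def build_pileup(alignments: Iterable[pysam.AlignedSegment],
                 chromosome: str, length: int, sample_id: str = "",
                 min_aligned_fraction: float = MIN_ALIGNED_FRACTION,
                 literal_eighty_percent_rule: bool = False) -> Pileup:
    """Accumulate one sample's pileup from primary spliced alignments."""
    pile = Pileup.zeros(chromosome, length, sample_id)
    for a in alignments:
        if a.is_unmapped or a.is_secondary or a.is_supplementary:
            continue
        if a.reference_name != chromosome:
            continue
        frac = aligned_fraction(a)
        keep = frac > min_aligned_fraction
        if literal_eighty_percent_rule:
            keep = not keep
        if not keep:
            continue
        simplified = simplify_cigar(cigartuples_to_ops(a.cigartuples))
        for kind, s, e in read_contributions(a.reference_start, simplified):
            s, e = max(s, 0), min(e, length)
            if e <= s:
                continue
            pile.spanning[s:e] += 1
            if kind == "included":
                pile.included[s:e] += 1
    return pile


def coverage_mask(pileups: Sequence[Pileup],
                  min_cov_sample: int = MIN_COV_SAMPLE,
                  min_cov_mean: float = MIN_COV_MEAN) -> np.ndarray:
    """Boolean array, True where the position is excluded.

    A position is excluded when any sample's spanning coverage is below
    ``min_cov_sample`` or the mean across samples is below ``min_cov_mean``.
    """
    if not pileups:
        raise ValueError("need at least one pileup")
    spans = np.stack([p.spanning for p in pileups])
    return (spans < min_cov_sample).any(axis=0) | (spans.mean(axis=0) < min_cov_mean)


@dataclass
class Region:
    """A segmented genomic interval with its member (unmasked) positions."""

    chromosome: str
    start: int
    end: int  # half-open
    positions: np.ndarray  # unmasked positions belonging to the region
    mean_psi: float = float("nan")

    def __len__(self) -> int:
        return self.end - self.start


def segment_regions(pooled: Pileup, excluded: Optional[np.ndarray] = None,
                    threshold: float = SEGMENT_THRESHOLD) -> List[Region]:
    """Greedy segmentation of the pooled PSI track.

    Scans unmasked, covered positions left to right keeping the running
    cumulative mean PSI since the region started; when the next position's
    PSI differs from that mean by more than ``threshold`` the region is
    closed and a new one starts there (the mean resets to that PSI).
    Masked positions are skipped without splitting the region.
    """
    psi = pooled.psi()
    usable = pooled.spanning > 0
    if excluded is not None:
        usable &= ~excluded
    positions = np.flatnonzero(usable)
    regions: List[Region] = []
    members: List[int] = []
    total = 0.0

    def close() -> None:
        if members:
            arr = np.array(members)
            regions.append(Region(pooled.chromosome, int(arr[0]), int(arr[-1]) + 1,
                                  arr, total / len(members)))

    for p in positions:
        v = psi[p]
        if members and abs(v - total / len(members)) > threshold:
            close()
            members, total = [], 0.0
        members.append(int(p))
        total += v
    close()
    return regions


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def region_counts(region: Region, pileups: Sequence[Pileup]) -> pd.DataFrame:
    """Per-sample (retained_avg, total_avg): means over the region's
    positions, rounded to integers (half away from zero)."""
    if len(region.positions) == 0:
        raise ValueError("empty region")
    rows = []
    for p in pileups:
        inc = float(p.included[region.positions].mean())
        spa = float(p.spanning[region.positions].mean())
        rows.append({"sample": p.sample_id,
                     "retained_avg": _round_half_away(inc),
                     "total_avg": _round_half_away(spa)})
    return pd.DataFrame(rows)


def filter_regions(regions: Sequence[Region], pileups: Sequence[Pileup],
                   min_psi: float = MIN_REGION_PSI) -> List[Region]:
    """Drop regions not retained in any condition.

    A region is discarded iff its mean PSI is strictly below ``min_psi``
    in every sample.
    """
    kept = []
    for region in regions:
        for p in pileups:
            spa = p.spanning[region.positions]
            inc = p.included[region.positions]
            ok = spa.sum() > 0 and (inc[spa > 0] / spa[spa > 0]).mean() >= min_psi
            if ok:
                kept.append(region)
                break
    return kept


def regions_to_bed(regions: Sequence[Region], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\tregion{i:05d}\t"
                     f"{0 if np.isnan(r.mean_psi) else int(round(1000 * r.mean_psi))}\t+\n")
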