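"""Targeted quantifications: XBP1 intron splicing, gel densitometry, qPCR.

IRE1 removes a short (26 nt in human XBP1) intron by a nonconventional
cytosolic mechanism; three readouts of that event are implemented here:

* ``intron_splice_fraction`` — from spliced long-read alignments, the
  fraction of intron-spanning reads whose alignment lacks the intron.
* ``gel_splice_fraction`` — the densitometry formula
  (XBP1s + hybrid/2) / (XBP1u + XBP1s + hybrid) for the three RT-PCR
  bands (unspliced, spliced, and their heteroduplex hybrid).
* qPCR quantification — a mechanistic amplification-model fit that
  estimates the starting template quantity in arbitrary units, followed
  by technical-duplicate averaging, reference-gene (beta-actin)
  normalization, and division by the baseline sample's value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import optimize

from .pileup import cigartuples_to_ops, simplify_cigar
from .simulate import QpcrModelParams, amplification_curve

logger = logging.getLogger(__name__)

ANCHOR_LEN = 10  # nt each side a read must cover to "span" the intron
LACK_FRACTION = 0.90  # share of intron positions in skip/deletion to "lack" it


@dataclass(frozen=True)
class IntronTarget:
    """A targeted intron (e.g. the XBP1 intron) on the reference."""

    chromosome: str
    start: int  # 0-based half-open
    end: int
    anchor: int = ANCHOR_LEN

    def __post_init__(self) -> None:
        if self.end - self.start < 2:
            raise ValueError("intron interval too short")
        if self.anchor < 1:
            raise ValueError("anchor length must be >= 1")


def intron_splice_fraction(alignments: Iterable[pysam.AlignedSegment],
                           target: IntronTarget,
                           lack_fraction: float = LACK_FRACTION
                           ) -> Tuple[Optional[float], int, int]:
    """(fraction, spliced_count, spanning_count) for a targeted intron.

    A read spans the intron when its simplified alignment covers
    ``anchor`` nt on both flanks; it lacks the intron when at least
    ``lack_fraction`` of intron positions fall inside skip or deletion
    segments.  The fraction is None when nothing spans.
    """
    spanning = 0
    spliced = 0
    ilen = target.end - target.start
    for a in alignments:
        if a.is_unmapped or a.is_secondary or a.is_supplementary:
            continue
        if a.reference_name != target.chromosome:
            continue
        segs = simplify_cigar(cigartuples_to_ops(a.cigartuples))
        if a.reference_start > target.start - target.anchor:
            continue
        ref_end = a.reference_start + sum(l for _, l in segs)
        if ref_end < target.end + target.anchor:
            continue
        spanning += 1
        absent = 0  # intron positions with no base (N or D segments)
        pos = a.reference_start
        for op, length in segs:
            if op in ("N", "D"):
                absent += max(0, min(pos + length, target.end) - max(pos, target.start))
            pos += length
        if absent >= lack_fraction * ilen:
            spliced += 1
    fraction = spliced / spanning if spanning else None
    return fraction, spliced, spanning


def logit_summary(fractions: Sequence[float],
                  spanning_counts: Optional[Sequence[int]] = None) -> Dict[str, float]:
    """Mean fraction with 1-SD logit-space interval across replicates.

    Fractions of exactly 0 or 1 are clamped to [1/(N+1), N/(N+1)] using
    the replicate's spanning count N (or the default 1e3 when counts are
    not supplied) before the log(f / (1 - f)) transform.
    """
    f = np.asarray(fractions, dtype=float)
    if spanning_counts is None:
        n = np.full(f.shape, 1e3)
    else:
        n = np.asarray(spanning_counts, dtype=float)
    f = np.clip(f, 1.0 / (n + 1), n / (n + 1))
    logit = np.log(f / (1.0 - f))
    mean, sd = float(logit.mean()), float(logit.std(ddof=1)) if f.size > 1 else 0.0

    def expit(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-x))

    return {
        "mean_fraction": expit(mean),
        "logit_mean": mean,
        "logit_sd": sd,
        "lower": expit(mean - sd),
        "upper": expit(mean + sd),
    }


def gel_splice_fraction(u: float, s: float, h: float) -> float:
    """Splicing from background-corrected band intensities:
    (XBP1s + hybrid/2) / (XBP1u + XBP1s + hybrid)."""
    if min(u, s, h) < 0:
        raise ValueError("band intensities must be >= 0")
    denom = u + s + h
    if denom == 0:
        raise ValueError("all band intensities are zero")
    return (s + h / 2.0) / denom


class QpcrFitError(RuntimeError):
    pass


@dataclass
class QpcrFit:
    quantity: float  # starting template D0, arbitrary units
    k: float
    baseline: float
    rmse: float
    converged: bool


def qpcr_fit(fluorescence: Sequence[float], cycles: Optional[Sequence[int]] = None,
             min_amplitude_ratio: float = 10.0) -> QpcrFit:
    """Least-squares fit of the MAK-style amplification model.

    Model: D_{c+1} = D_c + k ln(1 + D_c / k), observed fluorescence =
    baseline + D_c.  Parameters (D0, k, baseline) are fit in log space
    for the positive ones, multi-starting D0 across decades.  Curves
    whose amplitude does not rise ``min_amplitude_ratio``-fold above the
    fit residual scale are rejected as non-amplifying.
    """
    f = np.asarray(fluorescence, dtype=float)
    if cycles is not None:
        order = np.argsort(np.asarray(cycles))
        f = f[order]
    if f.size < 20:
        raise ValueError("need >= 20 cycles")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite fluorescence")
    n = f.size
    amplitude = float(f.max() - f.min())
    # flat-curve guard: compare the full rise against the scatter of the
    # first cycles, which precede detectable amplification
    early_noise = float(np.std(f[:5]))
    if amplitude <= max(1e-12, min_amplitude_ratio * early_noise):
        raise QpcrFitError("flat curve: no amplification detected")

    k0 = max(amplitude, 1e-6)
    b0 = float(f.min())

    def residuals(theta: np.ndarray) -> np.ndarray:
        d0, k = np.exp(theta[0]), np.exp(theta[1])
        baseline = theta[2]
        model = baseline + (amplification_curve(d0, QpcrModelParams(k=k, baseline=0.0), n))
        return model - f

    best = None
    for log_d0 in np.log(k0) - np.log(10.0) * np.arange(2, 14, 2):
        try:
            res = optimize.least_squares(
                residuals, x0=[log_d0, math.log(k0), b0], method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise QpcrFitError("amplification model fit failed")
    d0, k = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    rmse = float(np.sqrt(2.0 * best.cost / n))
    converged = bool(best.success) and rmse < max(1e-6, 0.25 * amplitude)
    if not converged:
        raise QpcrFitError(f"amplification model did not converge (rmse={rmse:.3g})")
    return QpcrFit(quantity=d0, k=k, baseline=float(best.x[2]), rmse=rmse, converged=True)


def fit_qpcr_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Fit every curve in a (sample, gene, technical_rep, biological_rep,
    cycle, fluorescence) table; non-converging curves are dropped with a
    logged reason."""
    keys = ["sample", "gene", "biological_rep", "technical_rep"]
    rows = []
    for key, sub in curves.groupby(keys, sort=True):
        sub = sub.sort_values("cycle")
        try:
            fit = qpcr_fit(sub["fluorescence"].to_numpy(), sub["cycle"].to_numpy())
        except (QpcrFitError, ValueError) as exc:
            logger.warning("qPCR curve %s excluded: %s", key, exc)
            continue
        rows.append(dict(zip(keys, key)) | {"quantity": fit.quantity})
    return pd.DataFrame(rows, columns=keys + ["quantity"])


def qpcr_relative_expression(quantities: pd.DataFrame, target_gene: str,
                             reference_gene: str, baseline_sample: str
                             ) -> Dict[str, Dict[str, float]]:
    """Actin-normalized relative expression per sample.

    Technical duplicates are averaged, each biological replicate's target
    quantity is divided by the same-replicate reference-gene average,
    that ratio is divided by the baseline sample's normalized value, and
    the mean and sample standard error are taken across biological
    replicates.
    """
    tech_avg = (quantities.groupby(["sample", "gene", "biological_rep"])["quantity"]
                .mean().reset_index())
    wide = tech_avg.pivot_table(index=["sample", "biological_rep"], columns="gene",
                                values="quantity")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"no quantities for gene {gene!r}")
    missing_ref = wide[reference_gene].isna()
    if missing_ref.any():
        for idx in wide.index[missing_ref]:
            logger.warning("sample %s excluded: missing reference quantity", idx)
        wide = wide[~missing_ref]
    normalized = wide[target_gene] / wide[reference_gene]
    base = normalized.loc[baseline_sample]
    base_value = float(base.mean())
    if not math.isfinite(base_value) or base_value <= 0:
        raise ValueError("baseline sample has no usable normalized value")
    ratio = normalized / base_value
    out: Dict[str, Dict[str, float]] = {}
    for sample, vals in ratio.groupby(level="sample"):
        v = vals.dropna().to_numpy()
        se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
        out[sample] = {"mean_ratio": float(v.mean()), "se": se, "n": int(v.size)}
    return out
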