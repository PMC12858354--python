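"""Significance filtering and export helpers for result tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: -log10 value substituted for p == 0 in volcano exports
VOLCANO_CAP = 300.0


@dataclass(frozen=True)
class SignificanceFilter:
    """The study's reporting thresholds: FDR <= 0.05 and |log2FC| >= 0.5."""

    fdr_max: float = 0.05
    min_abs_log2fc: float = 0.5

    def __post_init__(self) -> None:
        if self.fdr_max < 0 or self.min_abs_log2fc < 0:
            raise ValueError("thresholds must be >= 0")


def apply_significance(table: pd.DataFrame,
                       filt: SignificanceFilter = SignificanceFilter()) -> pd.DataFrame:
    """Add a boolean ``significant`` column; both bounds are inclusive."""
    for col in ("fdr", "log2fc"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    out = table.copy()
    out["significant"] = ((out["fdr"] <= filt.fdr_max)
                          & (out["log2fc"].abs() >= filt.min_abs_log2fc)
                          & out["fdr"].notna())
    logger.info("%d of %d entries significant at fdr<=%g, |log2fc|>=%g",
                int(out["significant"].sum()), len(out), filt.fdr_max, filt.min_abs_log2fc)
    return out


def export_volcano_table(results: pd.DataFrame, effect_col: str = "delta_psi",
                         p_col: str = "fdr") -> pd.DataFrame:
    """Plotting-agnostic volcano table: (effect, -log10 p, capped flag)."""
    out = pd.DataFrame({
        "effect": results[effect_col],
        "p": results[p_col],
    })
    with np.errstate(divide="ignore"):
        y = -np.log10(out["p"].to_numpy(dtype=float))
    capped = np.isinf(y)
    y[capped] = VOLCANO_CAP
    out["neg_log10_p"] = y
    out["capped"] = capped
    return out


def gene_log2fc(counts: pd.DataFrame, samples_a: list, samples_b: list,
                pseudocount: float = 0.5) -> pd.DataFrame:
    """Library-size-normalized gene log2 fold change (A over B).

    A deliberately simple stand-in for a dedicated DE engine: counts are
    scaled to counts-per-mean-library, averaged within condition, and
    log2((mean_A + pseudocount) / (mean_B + pseudocount)) is reported.
    """
    lib = counts.sum(axis=0).astype(float)
    lib_mean = lib.replace(0, np.nan).mean()
    norm = counts / lib.replace(0, np.nan) * lib_mean
    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    return pd.DataFrame({
        "gene_id": counts.index,
        "mean_a": mean_a.to_numpy(),
        "mean_b": mean_b.to_numpy(),
        "log2fc": np.log2((mean_a + pseudocount) / (mean_b + pseudocount)).to_numpy(),
    }).set_index("gene_id")
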