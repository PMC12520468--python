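"""Per-contrast differential expression on log-expression.

Each contrast (e.g. W4 vs the W2 baseline) is tested independently with
an empirical-Bayes moderated t statistic: the pooled two-group variance
of each gene is shrunk toward a prior variance (by default the median
gene variance) with `prior_df` pseudo-degrees of freedom, which
stabilizes the denominator at n=3 replicates per group.  P-values come
from the t distribution on prior_df + residual df; multiplicity is
handled by Benjamini-Hochberg.  Genes are called differentially
expressed at |log2FC| > 1 and p < 0.05 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionSeries

__all__ = [
    "Contrast",
    "log2_fold_change",
    "moderated_t",
    "bh_adjust",
    "deg_table",
    "call_degs",
]


@dataclass(frozen=True)
class Contrast:
    """numerator timepoint vs denominator timepoint (e.g. W4 vs W2)."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("contrast timepoints must differ")

    @property
    def label(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def _check_contrast(series: ExpressionSeries, contrast: Contrast) -> None:
    for tp in (contrast.numerator, contrast.denominator):
        if tp not in series.timepoints:
            raise KeyError(f"timepoint {tp!r} not in series {series.timepoints}")


def log2_fold_change(series: ExpressionSeries, contrast: Contrast) -> pd.Series:
    """Mean log2 expression difference, numerator minus denominator."""
    _check_contrast(series, contrast)
    num = series.replicate_values(contrast.numerator).mean(axis=1)
    den = series.replicate_values(contrast.denominator).mean(axis=1)
    return pd.Series(num - den, index=series.data.index, name=contrast.label)


def moderated_t(
    series: ExpressionSeries,
    contrast: Contrast,
    prior_df: float = 4.0,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t statistic and two-sided p per gene.

    The pooled variance s_g^2 of each gene is shrunk to
    ``(d0*s0^2 + d*s_g^2) / (d0 + d)`` with d the residual degrees of
    freedom, d0 = ``prior_df`` and s0^2 = ``prior_var`` (median of the
    pooled gene variances when not given).  ``prior_df=0`` recovers the
    classical pooled t; ``prior_df=math.inf`` gives every gene the prior
    variance.
    """
    _check_contrast(series, contrast)
    x = series.replicate_values(contrast.numerator)
    y = series.replicate_values(contrast.denominator)
    n1, n2 = x.shape[1], y.shape[1]
    d = n1 + n2 - 2
    if d < 1:
        raise ValueError("zero residual df: need >= 2 replicates per group")
    pooled = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / d
    if prior_var is None:
        prior_var = float(np.median(pooled))
    if math.isinf(prior_df):
        s2 = np.full_like(pooled, prior_var)
        dof = math.inf
    else:
        s2 = (prior_df * prior_var + d * pooled) / (prior_df + d)
        dof = prior_df + d
    lfc = x.mean(axis=1) - y.mean(axis=1)
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if math.isinf(dof):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return pd.DataFrame(
        {"log2fc": lfc, "t_stat": t, "p": p}, index=series.data.index
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def deg_table(
    series: ExpressionSeries,
    contrasts: list[Contrast],
    prior_df: float = 4.0,
    prior_var: float | None = None,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Tidy per-gene, per-contrast table with q-values and DEG calls."""
    frames = []
    for contrast in contrasts:
        stats_df = moderated_t(series, contrast, prior_df, prior_var)
        stats_df = stats_df.copy()
        stats_df["q"] = bh_adjust(stats_df["p"].to_numpy())
        crit = stats_df["q"] if use_adjusted else stats_df["p"]
        stats_df["is_deg"] = (
            stats_df["log2fc"].abs() > lfc_threshold
        ) & (crit < p_threshold)
        stats_df.insert(0, "contrast", contrast.label)
        stats_df.insert(0, "gene", stats_df.index)
        frames.append(stats_df.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def call_degs(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> dict[str, set[str]]:
    """Gene sets passing |log2fc| > lfc_threshold and (p or q) < p_threshold,
    one set per contrast."""
    crit = table["q"] if use_adjusted else table["p"]
    mask = (table["log2fc"].abs() > lfc_threshold) & (crit < p_threshold)
    out: dict[str, set[str]] = {c: set() for c in table["contrast"].unique()}
    for _, row in table[mask].iterrows():
        out[row["contrast"]].add(row["gene"])
    return out
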