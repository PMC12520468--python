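"""Interaction-network and correlation analyses downstream of DNB
detection.

Covers the neighborhood steps (first neighbors of the DNB in a
protein--protein interaction graph, intersection with pre-tipping DEGs
and with metastasis gene sets), significance-filtered gene--gene
correlation networks at strict |r| thresholds (0.8 for DNB vs neighbor
DEGs, 0.7 for the dysregulation network), a simple per-sample pathway
activity score (mean member z-score), and the ranking of DNB genes by
their count of high-correlation metastasis-associated partners.

Correlation p-values are two-sided, from t = r*sqrt((n-2)/(1-r^2)) on
n-2 degrees of freedom, and are not multiplicity-adjusted by default
(``adjust="bh"`` enables Benjamini-Hochberg).  Threshold comparisons are
strict (>) on |r| and (<) on p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffexpr import bh_adjust
from .io import CorrelationEdge, ExpressionSeries, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayActivity",
    "neighbor_genes",
    "dnb_neighbor_degs",
    "metastasis_filter",
    "correlate_gene_sets",
    "pathway_activity",
    "correlate_dnb_pathways",
    "build_dysregulation_network",
]


@dataclass
class PathwayActivity:
    """Per-sample pathway scores (mean member z) and member coverage."""

    scores: pd.DataFrame  # pathways x samples
    coverage: pd.Series  # pathway -> member genes found


def neighbor_genes(graph: nx.Graph, seed_genes) -> set[str]:
    """Union of first neighbors of the seed genes, seeds excluded."""
    seeds = set(seed_genes)
    out: set[str] = set()
    for g in seeds:
        if g in graph:
            out.update(graph.neighbors(g))
    return out - seeds


def dnb_neighbor_degs(
    neighbors, deg_sets: dict[str, set[str]], contrasts_before_tipping
) -> set[str]:
    """Neighbors that are DEGs in any pre-tipping contrast."""
    pooled: set[str] = set()
    for c in contrasts_before_tipping:
        if c not in deg_sets:
            raise KeyError(f"contrast {c!r} not among DEG sets {sorted(deg_sets)}")
        pooled |= deg_sets[c]
    return set(neighbors) & pooled


def metastasis_filter(genes, metastasis_sets: GeneSetCollection) -> set[str]:
    """Genes also present in any metastasis-associated gene set."""
    return set(genes) & metastasis_sets.all_genes()


def _sample_matrix(
    series: ExpressionSeries, sample_scope: str
) -> pd.DataFrame:
    if sample_scope == "all_samples":
        return series.data
    if sample_scope == "timepoint_means":
        return series.timepoint_means()
    raise ValueError(
        f"sample_scope must be 'all_samples' or 'timepoint_means', got "
        f"{sample_scope!r}"
    )


def _pearson_matrix(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """r and two-sided p for every row of x against every row of y.

    Zero-variance rows give r = 0, p = 1 (logged).
    """
    n = x.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation p-values, got {n}")

    def _unit(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = a - a.mean(axis=1, keepdims=True)
        norm = np.sqrt((c**2).sum(axis=1))
        zero = norm == 0
        if zero.any():
            logger.warning(
                "%d zero-variance gene(s); correlations set to r=0, p=1",
                int(zero.sum()),
            )
        return c / np.where(zero, 1.0, norm)[:, None], zero

    ux, zx = _unit(x)
    uy, zy = _unit(y)
    r = np.clip(ux @ uy.T, -1.0, 1.0)
    r[zx, :] = 0.0
    r[:, zy] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[zx, :] = 1.0
    p[:, zy] = 1.0
    return r, p


def correlate_gene_sets(
    series: ExpressionSeries,
    set_a,
    set_b,
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
    sample_scope: str = "all_samples",
    adjust: str | None = None,
) -> tuple[list[CorrelationEdge], pd.Series]:
    """Pairwise correlations between two gene sets with threshold calls.

    Returns every (a, b) edge (identical ids skipped) plus the per-a-gene
    count of passing partners, sorted descending (ties broken by gene
    id).  ``passes`` requires |r| > r_threshold strictly and p (or the
    BH-adjusted p when ``adjust="bh"``) < p_threshold.
    """
    a = sorted(set(set_a))
    b = sorted(set(set_b))
    missing = [g for g in a + b if g not in series.data.index]
    if missing:
        raise KeyError(f"genes not in series: {missing[:5]}")
    mat = _sample_matrix(series, sample_scope)
    r, p = _pearson_matrix(
        mat.loc[a].to_numpy(dtype=float), mat.loc[b].to_numpy(dtype=float)
    )
    if adjust == "bh":
        keep = np.array(
            [[ga != gb for gb in b] for ga in a], dtype=bool
        )
        p_flat = p[keep]
        p = p.copy()
        p[keep] = bh_adjust(p_flat)
    edges: list[CorrelationEdge] = []
    counts = {g: 0 for g in a}
    for i, ga in enumerate(a):
        for j, gb in enumerate(b):
            if ga == gb:
                continue
            passes = (abs(r[i, j]) > r_threshold) and (p[i, j] < p_threshold)
            edges.append(
                CorrelationEdge(
                    gene_a=ga, gene_b=gb, r=float(r[i, j]), p=float(p[i, j]),
                    passes=passes,
                )
            )
            if passes:
                counts[ga] += 1
    ranked = pd.Series(counts, name="n_partners").sort_index()
    ranked = ranked.sort_values(ascending=False, kind="stable")
    return edges, ranked


def pathway_activity(
    series: ExpressionSeries, pathway_sets: GeneSetCollection
) -> PathwayActivity:
    """Per-sample pathway scores: mean z-scored expression of member
    genes present in the matrix.

    Pathways with fewer than two members present are dropped with a
    warning.  The score is a transparent coordinate-wise summary that is
    monotone in coordinated member expression; it is not a rank-based
    enrichment statistic.
    """
    z = series.data.sub(series.data.mean(axis=1), axis=0)
    sd = series.data.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "%d zero-variance gene(s) excluded from pathway scores",
            int(zero.sum()),
        )
    z = z.loc[~zero].div(sd[~zero], axis=0)
    rows, cov = {}, {}
    for name in pathway_sets.names():
        members = [g for g in pathway_sets.members(name) if g in z.index]
        if len(members) < 2:
            logger.warning(
                "pathway %r has %d usable member(s); dropped", name, len(members)
            )
            continue
        rows[name] = z.loc[members].mean(axis=0)
        cov[name] = len(members)
    scores = pd.DataFrame(rows).T
    if scores.empty:
        scores = pd.DataFrame(columns=series.data.columns)
    return PathwayActivity(
        scores=scores, coverage=pd.Series(cov, dtype=int, name="coverage")
    )


def correlate_dnb_pathways(
    series: ExpressionSeries,
    dnb_genes,
    activities: PathwayActivity,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Correlate each DNB gene with each pathway score across samples.

    Returns a tidy table (gene, pathway, r, p, passes) flagged at the
    strict |r| > 0.5, p < 0.05 defaults.
    """
    genes = sorted(set(dnb_genes))
    missing = [g for g in genes if g not in series.data.index]
    if missing:
        raise KeyError(f"genes not in series: {missing[:5]}")
    if activities.scores.empty:
        return pd.DataFrame(columns=["gene", "pathway", "r", "p", "passes"])
    cols = list(activities.scores.columns)
    r, p = _pearson_matrix(
        series.data.loc[genes, cols].to_numpy(dtype=float),
        activities.scores.to_numpy(dtype=float),
    )
    rows = []
    for i, g in enumerate(genes):
        for j, pw in enumerate(activities.scores.index):
            rows.append(
                {
                    "gene": g,
                    "pathway": pw,
                    "r": float(r[i, j]),
                    "p": float(p[i, j]),
                    "passes": (abs(r[i, j]) > r_threshold)
                    and (p[i, j] < p_threshold),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "pathway", "r", "p", "passes"])


def build_dysregulation_network(
    series: ExpressionSeries,
    dnb_genes,
    metastasis_genes,
    r_threshold: float = 0.7,
    p_threshold: float = 0.05,
    sample_scope: str = "all_samples",
) -> list[CorrelationEdge]:
    """Passing DNB-gene x metastasis-gene correlation edges at the
    |r| > 0.7, p < 0.05 defaults, ready for Cytoscape export."""
    edges, _ = correlate_gene_sets(
        series,
        dnb_genes,
        metastasis_genes,
        r_threshold=r_threshold,
        p_threshold=p_threshold,
        sample_scope=sample_scope,
    )
    return [e for e in edges if e.passes]
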