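"""Temporal pattern clustering of per-gene expression profiles.

Profiles are replicate means per timepoint, z-scored across timepoints so
only the shape matters, then soft-clustered with fuzzy c-means (Bezdek):
memberships and centroids alternate until the weighted within-cluster
squared-distance objective stops improving.  The default k=4 reflects the
four qualitative time-course shapes commonly seen in short perturbation
series (monotone up/down, transient peak/dip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionSeries

__all__ = ["ClusterAssignment", "standardize_profiles", "fuzzy_cmeans"]


@dataclass
class ClusterAssignment:
    """Soft clustering result.

    membership rows sum to 1; hard_label is the per-gene argmax cluster
    (ties -> lowest index); objective_trace is non-increasing.
    """

    membership: pd.DataFrame  # genes x k
    hard_label: pd.Series  # gene -> cluster index
    centroids: pd.DataFrame  # k x timepoints
    objective_trace: list[float]

    def cluster_genes(self, j: int) -> list[str]:
        return list(self.hard_label.index[self.hard_label == j])


def standardize_profiles(
    series: ExpressionSeries,
) -> tuple[pd.DataFrame, list[str]]:
    """Replicate-mean profiles z-scored across timepoints (ddof=1).

    Returns (profiles, excluded) where ``excluded`` lists genes with zero
    temporal variance, which carry no shape information and are left out.
    """
    means = series.timepoint_means()
    sd = means.std(axis=1, ddof=1)
    excluded = list(means.index[sd == 0])
    kept = means.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return z, excluded


def _init_centroids(
    profiles: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    distinct = np.unique(profiles, axis=0)
    if k > distinct.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {distinct.shape[0]} distinct profiles"
        )
    pick = rng.choice(distinct.shape[0], size=k, replace=False)
    return distinct[np.sort(pick)].copy()


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ij from squared distances; coincident points get membership 1
    on their (first) zero-distance cluster."""
    n, k = d2.shape
    u = np.empty((n, k))
    zero_rows = (d2 == 0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    for i in np.nonzero(zero_rows)[0]:
        u[i] = 0.0
        u[i, int(np.argmin(d2[i]))] = 1.0
    return u


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int = 4,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    init_centroids: np.ndarray | None = None,
) -> ClusterAssignment:
    """Fuzzy c-means on standardized temporal profiles.

    Alternates membership updates
    ``u_ij = 1 / sum_l (d_ij/d_il)^(2/(m-1))`` and centroid updates
    ``c_j = sum_i u_ij^m x_i / sum_i u_ij^m`` (Euclidean distance) until
    the objective ``J = sum_ij u_ij^m d_ij^2`` changes by less than
    ``tol`` or ``max_iter`` is reached.  Initial centroids are k distinct
    profiles drawn from ``seed`` unless ``init_centroids`` is given (the
    deterministic-testing mode).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = profiles.to_numpy(dtype=float)
    if init_centroids is not None:
        centroids = np.asarray(init_centroids, dtype=float).copy()
        if centroids.shape != (k, x.shape[1]):
            raise ValueError("init_centroids must be k x n_timepoints")
    else:
        rng = np.random.default_rng(seed)
        centroids = _init_centroids(x, k, rng)

    trace: list[float] = []
    u = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(d2, m)
        um = u**m
        trace.append(float((um * d2).sum()))
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < tol:
            centroids = new_centroids
            break
        centroids = new_centroids

    # final memberships consistent with the returned centroids
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = _memberships(d2, m)

    membership = pd.DataFrame(u, index=profiles.index, columns=range(k))
    hard = pd.Series(np.argmax(u, axis=1), index=profiles.index, name="cluster")
    cents = pd.DataFrame(centroids, index=range(k), columns=profiles.columns)
    return ClusterAssignment(
        membership=membership,
        hard_label=hard,
        centroids=cents,
        objective_trace=trace,
    )
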