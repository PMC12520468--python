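"""Synthetic replicated time-series expression with a planted critical
transition.

The generator is a one-factor model: at every (timepoint, replicate) a
single latent factor z is drawn with a timepoint-dependent standard
deviation s(t) that jumps from ``factor_sd_base`` to ``factor_sd_peak``
at the transition timepoint ``t_star``.  Genes in the planted module load
on the factor with per-gene loadings, so at the transition their
replicate-wise variance and mutual correlation rise together; non-module
genes couple weakly to the factor before the transition and decouple at
it, so their correlation to the module falls.  This reproduces, with
analytically known second moments, the three early-warning signatures a
dynamic network biomarker must show (rising within-module deviation and
correlation, falling outside correlation) without committing to an
explicit dynamical model near the bifurcation.

A planted set of "neighbor" genes, plus an optional mean shift applied to
module and neighbor genes from the transition onward, gives downstream
differential-expression and network stages their own ground truth.  A
matching planted interaction graph is produced by :func:`simulate_ppi`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionSeries

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_critical_transition",
    "simulate_ppi",
    "simulate_temporal_patterns",
    "gene_id",
]

# fixed offsets deriving independent RNG sub-streams from the root seed
_SEED_MEANS = 1
_SEED_LOADINGS = 2
_SEED_FACTOR = 3
_SEED_NOISE = 4
_SEED_GENESETS = 5
_SEED_PPI = 6


def gene_id(i: int) -> str:
    """Deterministic gene-id scheme shared by generator and PPI builder."""
    return f"G{i:05d}"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-transition generator.

    All expression quantities are in log-expression units.  Defaults are
    the reference study conditions: 200 genes with a 20-gene module over
    five timepoints with triplicates, factor SD 0.2 at baseline rising to
    2.0 at the transition (timepoint index 2), residual SD 0.5, and
    pre-transition background coupling 0.3.
    """

    n_genes: int = 200
    module_size: int = 20
    n_timepoints: int = 5
    n_replicates: int = 3
    t_star: int = 2
    factor_sd_base: float = 0.2
    factor_sd_peak: float = 2.0
    loading_range: tuple[float, float] = (0.75, 1.25)
    noise_sd: float = 0.5
    background_coupling: float = 0.3
    baseline_mean_range: tuple[float, float] = (4.0, 10.0)
    mean_shift: float = 0.0
    n_neighbors: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.module_size < self.n_genes:
            raise ValueError(
                f"module_size ({self.module_size}) must be < n_genes ({self.n_genes})"
            )
        if self.n_replicates < 3:
            raise ValueError(f"n_replicates ({self.n_replicates}) must be >= 3")
        if not 0 <= self.t_star < self.n_timepoints:
            raise ValueError(
                f"t_star ({self.t_star}) must lie in [0, {self.n_timepoints})"
            )
        if not self.factor_sd_peak >= self.factor_sd_base >= 0:
            raise ValueError(
                "factor_sd_peak must be >= factor_sd_base >= 0; got "
                f"factor_sd_peak={self.factor_sd_peak}, "
                f"factor_sd_base={self.factor_sd_base}"
            )
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd ({self.noise_sd}) must be > 0")
        if self.n_neighbors < 0 or (
            self.n_neighbors > self.n_genes - self.module_size
        ):
            raise ValueError(
                f"n_neighbors ({self.n_neighbors}) must fit among the "
                f"{self.n_genes - self.module_size} non-module genes"
            )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulation run."""

    module_genes: frozenset[str]
    neighbor_genes: frozenset[str]
    t_star: int
    config: SimulationConfig = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "module_genes": sorted(self.module_genes),
            "neighbor_genes": sorted(self.neighbor_genes),
            "t_star": self.t_star,
            "config": dataclasses.asdict(self.config),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def from_json(path) -> "SimulationTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        for key in ("loading_range", "baseline_mean_range"):
            cfg[key] = tuple(cfg[key])
        return SimulationTruth(
            module_genes=frozenset(payload["module_genes"]),
            neighbor_genes=frozenset(payload["neighbor_genes"]),
            t_star=payload["t_star"],
            config=SimulationConfig(**cfg),
        )


def _timepoint_labels(n: int) -> list[str]:
    # W2, W3, ... mirrors a weekly sampling design
    return [f"W{i + 2}" for i in range(n)]


def simulate_critical_transition(
    config: SimulationConfig,
) -> tuple[ExpressionSeries, SimulationTruth]:
    """Draw one replicated time series with a planted transition.

    For each timepoint t and replicate r a single factor draw
    ``z ~ N(0, s(t)^2)`` is shared by all genes of that sample, with
    ``s(t) = factor_sd_peak`` at ``t_star`` and ``factor_sd_base``
    elsewhere.  Module genes load on the factor with loadings drawn from
    ``loading_range``; other genes couple with ``background_coupling``
    before the transition and 0 from it onward.  If ``mean_shift`` is
    non-zero it is added to module and neighbor genes from ``t_star``
    onward, planting differential expression.  Deterministic given
    ``config.seed``.
    """
    cfg = config
    G, T, R = cfg.n_genes, cfg.n_timepoints, cfg.n_replicates
    genes = [gene_id(i) for i in range(G)]

    rng_sets = np.random.default_rng(cfg.seed + _SEED_GENESETS)
    picked = rng_sets.choice(G, size=cfg.module_size + cfg.n_neighbors, replace=False)
    module_idx = np.sort(picked[: cfg.module_size])
    neighbor_idx = np.sort(picked[cfg.module_size :])

    rng_means = np.random.default_rng(cfg.seed + _SEED_MEANS)
    mu = rng_means.uniform(*cfg.baseline_mean_range, size=G)
    rng_load = np.random.default_rng(cfg.seed + _SEED_LOADINGS)
    lam = rng_load.uniform(*cfg.loading_range, size=cfg.module_size)

    rng_factor = np.random.default_rng(cfg.seed + _SEED_FACTOR)
    rng_noise = np.random.default_rng(cfg.seed + _SEED_NOISE)

    loadings = np.zeros((G, T))
    for t in range(T):
        w = cfg.background_coupling if t < cfg.t_star else 0.0
        loadings[:, t] = w
        loadings[module_idx, t] = lam

    shift_mask = np.zeros(G)
    shift_mask[module_idx] = cfg.mean_shift
    shift_mask[neighbor_idx] = cfg.mean_shift

    values = np.empty((G, T * R))
    sample_map: dict[str, tuple[str, int]] = {}
    labels = _timepoint_labels(T)
    col = 0
    for t in range(T):
        s_t = cfg.factor_sd_peak if t == cfg.t_star else cfg.factor_sd_base
        for r in range(R):
            z = rng_factor.normal(0.0, s_t) if s_t > 0 else 0.0
            eps = rng_noise.normal(0.0, cfg.noise_sd, size=G)
            values[:, col] = mu + loadings[:, t] * z + eps
            if t >= cfg.t_star:
                values[:, col] += shift_mask
            sample = f"{labels[t]}_r{r + 1}"
            sample_map[sample] = (labels[t], r + 1)
            col += 1

    series = ExpressionSeries(
        data=pd.DataFrame(values, index=genes, columns=list(sample_map)),
        sample_map=sample_map,
        timepoints=labels,
    )
    truth = SimulationTruth(
        module_genes=frozenset(genes[i] for i in module_idx),
        neighbor_genes=frozenset(genes[i] for i in neighbor_idx),
        t_star=cfg.t_star,
        config=cfg,
    )
    return series, truth


def simulate_ppi(
    truth: SimulationTruth,
    n_extra_nodes: int,
    p_background_edge: float,
    seed: int,
) -> nx.Graph:
    """Planted interaction graph matching a simulation run.

    Every (module gene, neighbor gene) pair is an edge; background edges
    are added independently with probability ``p_background_edge`` among
    all other node pairs.  Extra nodes are the first ``n_extra_nodes``
    simulated genes outside module and neighbors, so the graph's id space
    matches the expression matrix.  Undirected, no self-loops,
    deterministic given ``seed``.
    """
    if not 0.0 <= p_background_edge <= 1.0:
        raise ValueError(
            f"p_background_edge ({p_background_edge}) must be in [0, 1]"
        )
    module = sorted(truth.module_genes)
    neighbors = sorted(truth.neighbor_genes)
    others = [
        g
        for i in range(truth.config.n_genes)
        if (g := gene_id(i)) not in truth.module_genes
        and g not in truth.neighbor_genes
    ][:n_extra_nodes]

    graph = nx.Graph()
    graph.add_nodes_from(module + neighbors + others)
    for m in module:
        for n in neighbors:
            graph.add_edge(m, n)

    planted = {frozenset((m, n)) for m in module for n in neighbors}
    nodes = sorted(graph.nodes)
    rng = np.random.default_rng(seed + _SEED_PPI)
    if p_background_edge > 0:
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                if frozenset((a, b)) in planted:
                    continue
                if rng.random() < p_background_edge:
                    graph.add_edge(a, b)
    return graph


def simulate_temporal_patterns(
    n_genes_per_pattern: int = 25,
    n_timepoints: int = 5,
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    amplitude: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionSeries, dict[str, int]]:
    """Replicated series in which genes follow four planted temporal
    shapes (rising, falling, transient peak, transient dip), for
    exercising pattern clustering with known labels.

    Returns the series and a gene -> pattern-index map.
    """
    t = np.linspace(0.0, 1.0, n_timepoints)
    peak = np.exp(-(((t - 0.5) / 0.22) ** 2))
    shapes = np.stack([t, 1.0 - t, peak, 1.0 - peak])
    rng = np.random.default_rng(seed)
    labels = _timepoint_labels(n_timepoints)

    genes, rows, pattern_of = [], [], {}
    for p in range(4):
        for g in range(n_genes_per_pattern):
            gid = f"P{p}_{g:03d}"
            base = rng.uniform(4.0, 8.0)
            profile = base + amplitude * shapes[p]
            reps = profile[:, None] + rng.normal(
                0.0, noise_sd, size=(n_timepoints, n_replicates)
            )
            genes.append(gid)
            rows.append(reps.ravel())
            pattern_of[gid] = p
    sample_map = {
        f"{labels[t_]}_r{r + 1}": (labels[t_], r + 1)
        for t_ in range(n_timepoints)
        for r in range(n_replicates)
    }
    data = pd.DataFrame(np.array(rows), index=genes, columns=list(sample_map))
    return (
        ExpressionSeries(data=data, sample_map=sample_map, timepoints=labels),
        pattern_of,
    )
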