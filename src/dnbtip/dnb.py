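"""Dynamic-network-biomarker statistics and tipping-point detection.

A dynamic network biomarker (DNB) is a group of genes whose collective
fluctuation signals an imminent state transition.  At each timepoint the
group is summarized over that timepoint's replicates by three statistics:

* ``SD_in`` — the average standard deviation of the group's genes;
* ``PCC_in`` — the average absolute Pearson correlation over all gene
  pairs within the group;
* ``PCC_out`` — the average absolute Pearson correlation between group
  genes and all other genes.

Approaching a critical transition, SD_in and PCC_in rise sharply while
PCC_out falls, and the composite criticality index

    CI = size * PCC_in * SD_in / PCC_out

peaks.  The size weight is meaningful only together with the
high-variance pre-selection in candidate generation: on an unrestricted
gene pool it would reward padding a genuine module with noise genes.  The timepoint at which CI peaks is reported as the tipping
point.  Candidate groups are generated by agglomerative clustering of
genes on the 1-|r| correlation distance at each timepoint; significance
of an observed CI is assessed by permuting gene labels.

With n=3 replicates, per-timepoint correlations are extremely noisy (the
null expectation of |r| at n=3 is 2/pi ~ 0.64); the statistics are
well-defined but individual values should be read as ensemble evidence,
which is why detection aggregates over candidate modules and the
permutation null is provided.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .io import ExpressionSeries

logger = logging.getLogger(__name__)

#: default agglomerative cut heights on the 1 - |r| distance
DEFAULT_CUT_HEIGHTS: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.5, 0.7)

__all__ = [
    "DEFAULT_CUT_HEIGHTS",
    "ModuleStats",
    "DNBResult",
    "module_stats",
    "criticality_index",
    "candidate_modules",
    "detect_tipping",
    "permutation_null",
    "NullDistribution",
]


@dataclass(frozen=True)
class ModuleStats:
    """Per-timepoint summary of a candidate DNB group."""

    timepoint: str
    sd_in: float
    pcc_in: float
    pcc_out: float
    size: int


@dataclass
class DNBResult:
    """Detected DNB module with its criticality profile.

    criteria_flags are (SD_in maximal at the tipping point, PCC_in
    maximal, PCC_out minimal) relative to all other timepoints.
    """

    module_genes: frozenset[str]
    stats_by_timepoint: list[ModuleStats]
    ci_by_timepoint: list[float]
    tipping_timepoint: str
    criteria_flags: tuple[bool, bool, bool]
    perm_p: float | None = None
    candidates: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "module_genes": sorted(self.module_genes),
            "tipping_timepoint": self.tipping_timepoint,
            "ci_by_timepoint": {
                s.timepoint: ci
                for s, ci in zip(self.stats_by_timepoint, self.ci_by_timepoint)
            },
            "stats_by_timepoint": [
                {
                    "timepoint": s.timepoint,
                    "sd_in": s.sd_in,
                    "pcc_in": s.pcc_in,
                    "pcc_out": s.pcc_out,
                    "size": s.size,
                }
                for s in self.stats_by_timepoint
            ],
            "criteria_flags": {
                "sd_in_increased": self.criteria_flags[0],
                "pcc_in_increased": self.criteria_flags[1],
                "pcc_out_decreased": self.criteria_flags[2],
            },
            "perm_p": self.perm_p,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def profile_frame(self) -> pd.DataFrame:
        rows = [
            {
                "timepoint": s.timepoint,
                "sd_in": s.sd_in,
                "pcc_in": s.pcc_in,
                "pcc_out": s.pcc_out,
                "ci": ci,
            }
            for s, ci in zip(self.stats_by_timepoint, self.ci_by_timepoint)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# per-timepoint correlation/SD cache


class _TimepointProfile:
    """|r| matrix and per-gene replicate SD at one timepoint.

    Pairs where either gene has zero replicate variance contribute
    |r| = 0 (logged once); the diagonal is excluded from all averages.
    """

    def __init__(self, series: ExpressionSeries, timepoint: str):
        x = series.replicate_values(timepoint)
        if x.shape[1] < 3:
            raise ValueError(
                f"timepoint {timepoint!r} has {x.shape[1]} replicates; "
                "correlation statistics need >= 3"
            )
        self.genes = list(series.data.index)
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.sd = x.std(axis=1, ddof=1)
        centered = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        zero_var = norms == 0
        if zero_var.any():
            logger.warning(
                "%d gene(s) with zero replicate variance at %s; their "
                "correlations are set to 0",
                int(zero_var.sum()),
                timepoint,
            )
        safe = np.where(zero_var, 1.0, norms)
        unit = centered / safe[:, None]
        r = unit @ unit.T
        r[zero_var, :] = 0.0
        r[:, zero_var] = 0.0
        np.fill_diagonal(r, 1.0)
        self.abs_r = np.abs(np.clip(r, -1.0, 1.0))

    def stats(self, module_idx: np.ndarray, timepoint: str) -> ModuleStats:
        k = module_idx.size
        sub = self.abs_r[np.ix_(module_idx, module_idx)]
        pcc_in = (sub.sum() - np.trace(sub)) / (k * (k - 1))
        mask = np.ones(len(self.genes), dtype=bool)
        mask[module_idx] = False
        n_out = int(mask.sum())
        if n_out:
            pcc_out = float(self.abs_r[np.ix_(module_idx, mask)].mean())
        else:
            pcc_out = 0.0
        return ModuleStats(
            timepoint=timepoint,
            sd_in=float(self.sd[module_idx].mean()),
            pcc_in=float(pcc_in),
            pcc_out=pcc_out,
            size=k,
        )


def _module_index(profile: _TimepointProfile, module_genes) -> np.ndarray:
    idx = []
    for g in module_genes:
        if g not in profile.index:
            raise KeyError(f"module gene {g!r} not in series")
        idx.append(profile.index[g])
    return np.array(sorted(idx), dtype=int)


def module_stats(
    series: ExpressionSeries, module_genes, timepoint: str
) -> ModuleStats:
    """SD_in, PCC_in, PCC_out of a gene group at one timepoint.

    SD_in averages the per-gene replicate standard deviation (ddof=1);
    PCC_in averages |r| over all within-group pairs; PCC_out averages
    |r| over all group x outside pairs, on the same replicate sample
    space.
    """
    module_genes = list(module_genes)
    if len(set(module_genes)) < 2:
        raise ValueError("module needs >= 2 distinct genes")
    profile = _TimepointProfile(series, timepoint)
    return profile.stats(_module_index(profile, module_genes), timepoint)


def criticality_index(
    stats: ModuleStats,
    use_size_weight: bool = True,
    epsilon: float = 1e-6,
) -> float:
    """CI = w * PCC_in * SD_in / (PCC_out + epsilon), w = size or 1.

    The epsilon guard keeps CI finite when the group is uncorrelated
    with the rest of the transcriptome.  ``use_size_weight=False``
    drops the size factor.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    w = stats.size if use_size_weight else 1.0
    return w * stats.pcc_in * stats.sd_in / (stats.pcc_out + epsilon)


def candidate_modules(
    series: ExpressionSeries,
    timepoint: str,
    min_size: int = 5,
    max_size: int | None = None,
    linkage: str = "average",
    cut_heights: tuple[float, ...] = DEFAULT_CUT_HEIGHTS,
    select_fraction: float | None = 0.1,
) -> list[frozenset[str]]:
    """Candidate gene groups from agglomerative clustering at one
    timepoint.

    Genes are clustered on the distance 1 - |r| (r over replicates) with
    the given linkage; at each cut height, clusters whose size falls in
    [min_size, max_size] become candidates.  The default cut grid reaches
    down to 0.05 because with few replicates even unrelated gene pairs
    have large |r| (null expectation 2/pi at n=3), so a genuinely
    co-fluctuating module separates from the noise only at small
    1 - |r| distances.  ``max_size`` defaults to a quarter of the
    transcriptome: a DNB is a dominant *group*, not the bulk of the
    matrix, and without a cap the size-weighted CI rewards arbitrarily
    large noise clusters.  Genes are processed in lexicographic order so
    the result does not depend on input order.  Returns deduplicated
    candidates, sorted by size then gene ids.

    ``select_fraction`` keeps only the top fraction of genes by
    replicate SD at this timepoint before clustering (pass None to
    cluster everything).  The pre-selection is essential at small
    replicate numbers: a rising-variance module is sharply separated
    from the background by its SD, while 1 - |r| alone cannot separate
    it because null correlations at n=3 are heavy-tailed.
    """
    order = sorted(series.data.index)
    reordered = series.subset_genes(order)
    full_profile = _TimepointProfile(reordered, timepoint)
    if select_fraction is not None:
        if not 0 < select_fraction <= 1:
            raise ValueError("select_fraction must be in (0, 1]")
        n_keep = max(min_size, int(np.ceil(select_fraction * len(order))))
        by_sd = sorted(
            range(len(order)), key=lambda i: (-full_profile.sd[i], order[i])
        )[:n_keep]
        order = [order[i] for i in sorted(by_sd)]
        if len(order) < 2:
            return []
        reordered = series.subset_genes(order)
        profile = _TimepointProfile(reordered, timepoint)
    else:
        profile = full_profile
    dist = 1.0 - profile.abs_r
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = scipy_linkage(condensed, method=linkage)
    hi = max_size if max_size is not None else max(min_size, series.n_genes // 4)
    # a module needs outside genes for PCC_out to be defined
    hi = min(hi, series.n_genes - 1)
    out: set[frozenset[str]] = set()
    for h in cut_heights:
        labels = fcluster(tree, t=h, criterion="distance")
        for lab in np.unique(labels):
            members = [order[i] for i in np.nonzero(labels == lab)[0]]
            if min_size <= len(members) <= hi:
                out.add(frozenset(members))
    if not out:
        logger.info(
            "no candidate in size window [%d, %s] at %s", min_size, hi, timepoint
        )
    return sorted(out, key=lambda s: (len(s), tuple(sorted(s))))


def _flags(
    stats: list[ModuleStats], tipping_idx: int
) -> tuple[bool, bool, bool]:
    others = [s for i, s in enumerate(stats) if i != tipping_idx]
    at = stats[tipping_idx]
    return (
        at.sd_in > max(s.sd_in for s in others),
        at.pcc_in > max(s.pcc_in for s in others),
        at.pcc_out < min(s.pcc_out for s in others),
    )


def _result_for_module(
    module: frozenset[str],
    profiles: dict[str, _TimepointProfile],
    timepoints: list[str],
    use_size_weight: bool,
    epsilon: float,
) -> DNBResult:
    idx = _module_index(profiles[timepoints[0]], module)
    stats = [profiles[tp].stats(idx, tp) for tp in timepoints]
    ci = [criticality_index(s, use_size_weight, epsilon) for s in stats]
    tip = int(np.argmax(ci))  # argmax ties -> earliest timepoint
    return DNBResult(
        module_genes=module,
        stats_by_timepoint=stats,
        ci_by_timepoint=ci,
        tipping_timepoint=timepoints[tip],
        criteria_flags=_flags(stats, tip),
    )


def detect_tipping(
    series: ExpressionSeries,
    min_size: int = 5,
    max_size: int | None = None,
    cut_heights: tuple[float, ...] = DEFAULT_CUT_HEIGHTS,
    use_size_weight: bool = True,
    epsilon: float = 1e-6,
    select_fraction: float | None = 0.1,
    module_genes=None,
) -> DNBResult:
    """Search candidate modules at every timepoint and report the DNB.

    For each timepoint, candidates generated there are scored by their CI
    at that timepoint and the best is kept (ties -> lexicographically
    smallest gene set); the global DNB is the best per-timepoint winner
    (ties -> earliest timepoint).  Its full CI profile across all
    timepoints determines the tipping point (profile argmax, ties ->
    earliest).  Passing ``module_genes`` bypasses the search and profiles
    that group directly.  The per-timepoint winner table is attached as
    ``candidates``.
    """
    if len(series.timepoints) < 2:
        raise ValueError("need >= 2 timepoints to locate a tipping point")
    profiles = {tp: _TimepointProfile(series, tp) for tp in series.timepoints}
    tps = list(series.timepoints)

    if module_genes is not None:
        if len(set(module_genes)) < 2:
            raise ValueError("module needs >= 2 distinct genes")
        return _result_for_module(
            frozenset(module_genes), profiles, tps, use_size_weight, epsilon
        )

    best_module: frozenset[str] | None = None
    best_ci = -np.inf
    rows = []
    for tp in tps:
        cands = candidate_modules(
            series, tp, min_size=min_size, max_size=max_size,
            cut_heights=cut_heights, select_fraction=select_fraction,
        )
        tp_best: frozenset[str] | None = None
        tp_best_ci = -np.inf
        for module in cands:
            idx = _module_index(profiles[tp], module)
            ci = criticality_index(
                profiles[tp].stats(idx, tp), use_size_weight, epsilon
            )
            if tp_best is None or ci > tp_best_ci or (
                ci == tp_best_ci and tuple(sorted(module)) < tuple(sorted(tp_best))
            ):
                tp_best, tp_best_ci = module, ci
        if tp_best is None:
            continue
        rows.append(
            {
                "timepoint": tp,
                "size": len(tp_best),
                "ci": tp_best_ci,
                "genes": ",".join(sorted(tp_best)),
            }
        )
        if tp_best_ci > best_ci:  # strict: ties keep the earlier timepoint
            best_module, best_ci = tp_best, tp_best_ci
    if best_module is None:
        raise ValueError(
            "no candidate module found at any timepoint; relax min_size "
            "or cut_heights"
        )
    result = _result_for_module(
        best_module, profiles, tps, use_size_weight, epsilon
    )
    result.candidates = pd.DataFrame(
        rows, columns=["timepoint", "size", "ci", "genes"]
    )
    return result


@dataclass
class NullDistribution:
    """Permutation null sample of CI values at one timepoint."""

    values: np.ndarray
    timepoint: str
    module_size: int

    def pvalue(self, observed_ci: float) -> float:
        """Empirical p with the +1 correction:
        (1 + #{null >= observed}) / (B + 1)."""
        b = self.values.size
        return (1.0 + float(np.sum(self.values >= observed_ci))) / (b + 1.0)


def permutation_null(
    series: ExpressionSeries,
    module_size: int,
    timepoint: str,
    n_perm: int = 1000,
    seed: int | None = None,
    use_size_weight: bool = True,
    epsilon: float = 1e-6,
) -> NullDistribution:
    """Null CI distribution from random gene groups of the given size.

    Draws ``n_perm`` groups uniformly without replacement from all genes
    and computes each group's CI at the timepoint.  Deterministic given
    ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    if module_size > series.n_genes:
        raise ValueError("module_size exceeds the number of genes")
    profile = _TimepointProfile(series, timepoint)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_perm)
    for b in range(n_perm):
        idx = np.sort(rng.choice(series.n_genes, size=module_size, replace=False))
        vals[b] = criticality_index(
            profile.stats(idx, timepoint), use_size_weight, epsilon
        )
    return NullDistribution(values=vals, timepoint=timepoint, module_size=module_size)
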