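"""Configuration-driven end-to-end run: differential expression,
temporal clustering, DNB tipping-point detection, and the network
intersection/ranking stages, written to a reproducible results
directory.

Stages run in a fixed order and every stage logs the counts of genes
entering and leaving its filters.  Identical configuration + seed yields
byte-identical result files (the run log carries no timestamps either).
On a stage failure, partial outputs are kept and a ``FAILED`` marker
file names the stage and cause.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import fuzzy_cmeans, standardize_profiles
from .diffexpr import Contrast, call_degs, deg_table
from .dnb import detect_tipping, permutation_null
from .io import (
    ExpressionSeries,
    read_edge_list,
    read_expression_tsv,
    read_gmt,
    write_edge_list,
    write_expression_tsv,
    write_gmt,
    write_network_tsv,
    GeneSetCollection,
)
from .network import (
    build_dysregulation_network,
    correlate_dnb_pathways,
    correlate_gene_sets,
    dnb_neighbor_degs,
    metastasis_filter,
    neighbor_genes,
    pathway_activity,
)
from .simulate import SimulationConfig, simulate_critical_transition, simulate_ppi

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline", "make_demo"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad paths or thresholds)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Correlation thresholds default to the strict |r| > 0.8 (DNB vs
    neighbor DEGs), > 0.5 (pathways) and > 0.7 (dysregulation network)
    conventions with raw p < 0.05; DEG calls default to |log2FC| > 1,
    p < 0.05.
    """

    expression: str = "expression.tsv"
    metadata: str = "samples.tsv"
    ppi_edges: str = "ppi.tsv"
    metastasis_gmt: str = "metastasis.gmt"
    pathway_gmt: str = "pathways.gmt"
    output_dir: str = "results"
    baseline_timepoint: str | None = None  # default: first timepoint
    # differential expression
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    use_adjusted: bool = False
    prior_df: float = 4.0
    # clustering
    k: int = 4
    fuzzifier: float = 2.0
    cluster_tol: float = 1e-6
    # DNB
    min_size: int = 5
    max_size: int | None = None
    cut_heights: tuple[float, ...] = (0.3, 0.5, 0.7)
    use_size_weight: bool = True
    epsilon: float = 1e-6
    permutations: int = 0
    # correlation thresholds
    neighbor_r_threshold: float = 0.8
    pathway_r_threshold: float = 0.5
    dysregulation_r_threshold: float = 0.7
    correlation_p_threshold: float = 0.05
    sample_scope: str = "all_samples"
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        if check_paths:
            for name in (
                "expression", "metadata", "ppi_edges", "metastasis_gmt",
                "pathway_gmt",
            ):
                p = Path(getattr(self, name))
                if not p.exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
        for name in (
            "p_threshold", "correlation_p_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "neighbor_r_threshold", "pathway_r_threshold",
            "dysregulation_r_threshold",
        ):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.sample_scope not in ("all_samples", "timepoint_means"):
            raise ConfigError(f"invalid sample_scope {self.sample_scope!r}")
        if self.min_size < 2:
            raise ConfigError("min_size must be >= 2")
        if self.k < 1 or self.fuzzifier <= 1:
            raise ConfigError("need k >= 1 and fuzzifier > 1")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")
        if self.permutations < 0:
            raise ConfigError("permutations must be >= 0")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["cut_heights"] = list(self.cut_heights)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cut_heights" in payload:
            payload["cut_heights"] = tuple(payload["cut_heights"])
        return PipelineConfig(**payload)


def _contrasts(series: ExpressionSeries, baseline: str) -> list[Contrast]:
    if baseline not in series.timepoints:
        raise ConfigError(f"baseline timepoint {baseline!r} not in series")
    return [
        Contrast(numerator=tp, denominator=baseline)
        for tp in series.timepoints
        if tp != baseline
    ]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the results directory."""
    config.validate(check_paths=True)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dnbtip")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    try:
        logger.info("dnbtip %s, seed %d", __version__, config.seed)
        config.to_yaml(out / "config.yaml")

        stage = "load"
        series = read_expression_tsv(config.expression, config.metadata)
        graph = read_edge_list(config.ppi_edges)
        metastasis = read_gmt(config.metastasis_gmt)
        pathways = read_gmt(config.pathway_gmt)
        logger.info(
            "loaded %d genes x %d samples, %d PPI edges",
            series.n_genes, series.data.shape[1], graph.number_of_edges(),
        )

        stage = "degs"
        baseline = config.baseline_timepoint or series.timepoints[0]
        contrasts = _contrasts(series, baseline)
        table = deg_table(
            series, contrasts,
            prior_df=config.prior_df,
            lfc_threshold=config.lfc_threshold,
            p_threshold=config.p_threshold,
            use_adjusted=config.use_adjusted,
        )
        table.to_csv(out / "degs.tsv", sep="\t", index=False, float_format="%.9g")
        deg_sets = call_degs(
            table, config.lfc_threshold, config.p_threshold, config.use_adjusted
        )
        for c in contrasts:
            logger.info("contrast %s: %d DEGs", c.label, len(deg_sets[c.label]))

        stage = "cluster"
        deg_union = sorted(set().union(*deg_sets.values())) if deg_sets else []
        cluster_genes = deg_union if len(deg_union) >= config.k else series.gene_ids
        profiles, excluded = standardize_profiles(series.subset_genes(cluster_genes))
        logger.info(
            "clustering %d profiles (%d zero-variance excluded)",
            profiles.shape[0], len(excluded),
        )
        assignment = fuzzy_cmeans(
            profiles, k=config.k, m=config.fuzzifier,
            tol=config.cluster_tol, seed=config.seed,
        )
        assignment.membership.to_csv(
            out / "cluster_membership.tsv", sep="\t", float_format="%.9g",
            index_label="gene",
        )
        assignment.centroids.to_csv(
            out / "cluster_centroids.tsv", sep="\t", float_format="%.9g",
            index_label="cluster",
        )
        with open(out / "cluster_genes.txt", "w", encoding="utf-8") as fh:
            for j in range(config.k):
                for g in assignment.cluster_genes(j):
                    fh.write(f"{j}\t{g}\n")

        stage = "dnb"
        result = detect_tipping(
            series,
            min_size=config.min_size,
            max_size=config.max_size,
            cut_heights=config.cut_heights,
            use_size_weight=config.use_size_weight,
            epsilon=config.epsilon,
        )
        if config.permutations > 0:
            null = permutation_null(
                series, len(result.module_genes), result.tipping_timepoint,
                n_perm=config.permutations, seed=config.seed,
                use_size_weight=config.use_size_weight, epsilon=config.epsilon,
            )
            tip_idx = series.timepoints.index(result.tipping_timepoint)
            result.perm_p = null.pvalue(result.ci_by_timepoint[tip_idx])
        logger.info(
            "DNB: %d genes, tipping at %s, flags %s",
            len(result.module_genes), result.tipping_timepoint,
            result.criteria_flags,
        )
        if result.candidates is not None:
            result.candidates.to_csv(
                out / "candidates.tsv", sep="\t", index=False, float_format="%.9g"
            )
        result.profile_frame().to_csv(
            out / "dnb_profile.tsv", sep="\t", index=False, float_format="%.9g"
        )
        with open(out / "dnb_genes.txt", "w", encoding="utf-8") as fh:
            for g in sorted(result.module_genes):
                fh.write(g + "\n")
        result.to_json(out / "dnb_result.json")

        stage = "network"
        dnb_genes = sorted(result.module_genes)
        neighbors = neighbor_genes(graph, dnb_genes)
        tip_idx = series.timepoints.index(result.tipping_timepoint)
        pre_tip = [
            c.label for c in contrasts
            if series.timepoints.index(c.numerator) <= tip_idx
        ]
        nb_degs = dnb_neighbor_degs(neighbors, deg_sets, pre_tip)
        meta_nb = metastasis_filter(nb_degs, metastasis)
        logger.info(
            "neighbors %d -> pre-tipping DEG neighbors %d -> metastasis-"
            "specific %d", len(neighbors), len(nb_degs), len(meta_nb),
        )
        with open(out / "metastasis_neighbor_degs.txt", "w", encoding="utf-8") as fh:
            for g in sorted(meta_nb):
                fh.write(g + "\n")

        expressed_meta = [g for g in sorted(meta_nb) if g in series.data.index]
        if expressed_meta:
            edges, ranking = correlate_gene_sets(
                series, dnb_genes, expressed_meta,
                r_threshold=config.neighbor_r_threshold,
                p_threshold=config.correlation_p_threshold,
                sample_scope=config.sample_scope,
            )
            write_network_tsv(
                [e for e in edges if e.passes], out / "dnb_neighbor_network.tsv"
            )
            ranking.rename_axis("gene").to_csv(out / "dnb_ranking.tsv", sep="\t")
            top = ranking.index[0] if len(ranking) else None
            logger.info("top DNB gene by metastasis-neighbor count: %s", top)
        else:
            ranking = None
            logger.info("no metastasis-specific neighbor DEGs in the matrix")

        activities = pathway_activity(series, pathways)
        assoc = correlate_dnb_pathways(
            series, dnb_genes, activities,
            r_threshold=config.pathway_r_threshold,
            p_threshold=config.correlation_p_threshold,
        )
        assoc.to_csv(
            out / "pathway_associations.tsv", sep="\t", index=False,
            float_format="%.9g",
        )

        meta_expressed = sorted(
            g for g in metastasis.all_genes()
            if g in series.data.index and g not in result.module_genes
        )
        dys = build_dysregulation_network(
            series, dnb_genes, meta_expressed,
            r_threshold=config.dysregulation_r_threshold,
            p_threshold=config.correlation_p_threshold,
            sample_scope=config.sample_scope,
        )
        write_network_tsv(dys, out / "dysregulation_network.tsv")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "baseline_timepoint": baseline,
            "contrasts": [c.label for c in contrasts],
            "n_genes": series.n_genes,
            "deg_counts": {c: len(s) for c, s in sorted(deg_sets.items())},
            "n_clustered": int(profiles.shape[0]),
            "dnb_size": len(result.module_genes),
            "tipping_timepoint": result.tipping_timepoint,
            "criteria_flags": list(result.criteria_flags),
            "perm_p": result.perm_p,
            "n_neighbors": len(neighbors),
            "n_neighbor_degs": len(nb_degs),
            "n_metastasis_neighbor_degs": len(meta_nb),
            "top_ranked_gene": (
                str(ranking.index[0]) if ranking is not None and len(ranking) else None
            ),
            "n_dysregulation_edges": len(dys),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def make_demo(
    output_dir,
    sim_config: SimulationConfig | None = None,
    n_extra_ppi_nodes: int = 50,
    p_background_edge: float = 0.02,
    n_metastasis_decoys: int = 20,
    seed: int | None = None,
) -> PipelineConfig:
    """Write a complete synthetic input set and a matching config.

    Simulates the reference planted-transition series (mean shift 2.0 so
    differential expression also has ground truth), the planted PPI
    graph, a metastasis gene set (planted neighbors plus background
    decoys) and three demonstration pathways, then returns a
    PipelineConfig pointing at the files.  The simulation truth is
    written alongside as ``truth.json``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sim_config is None:
        sim_config = SimulationConfig(
            mean_shift=2.0, seed=seed if seed is not None else 0
        )
    elif seed is not None:
        sim_config = dataclasses.replace(sim_config, seed=seed)
    series, truth = simulate_critical_transition(sim_config)
    write_expression_tsv(series, out / "expression.tsv", out / "samples.tsv")
    truth.to_json(out / "truth.json")
    graph = simulate_ppi(
        truth, n_extra_nodes=n_extra_ppi_nodes,
        p_background_edge=p_background_edge, seed=sim_config.seed,
    )
    write_edge_list(graph, out / "ppi.tsv")

    background = [
        g for g in series.gene_ids
        if g not in truth.module_genes and g not in truth.neighbor_genes
    ]
    decoys = background[:n_metastasis_decoys]
    metastasis = GeneSetCollection(
        sets={
            "METASTASIS_ASSOCIATED": (
                "planted neighbors plus background decoys",
                sorted(truth.neighbor_genes) + decoys,
            )
        }
    )
    write_gmt(metastasis, out / "metastasis.gmt")
    pathways = GeneSetCollection(
        sets={
            "MODULE_PATHWAY": ("planted module genes", sorted(truth.module_genes)),
            "NEIGHBOR_PATHWAY": ("planted neighbor genes", sorted(truth.neighbor_genes)),
            "BACKGROUND_PATHWAY": ("unperturbed genes", background[-30:]),
        }
    )
    write_gmt(pathways, out / "pathways.gmt")

    config = PipelineConfig(
        expression=str(out / "expression.tsv"),
        metadata=str(out / "samples.tsv"),
        ppi_edges=str(out / "ppi.tsv"),
        metastasis_gmt=str(out / "metastasis.gmt"),
        pathway_gmt=str(out / "pathways.gmt"),
        output_dir=str(out / "results"),
        seed=sim_config.seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
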