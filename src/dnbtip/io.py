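"""Readers and writers for the pipeline's file formats.

Expression matrices travel as a pair of TSV files (values + sample
metadata), gene sets as GMT, protein--protein interaction networks as
STRING-style edge lists, and correlation networks as Cytoscape-importable
TSV.  Gene identifiers are opaque, case-sensitive strings; no symbol
mapping is attempted.  Expression values are assumed to be on a log scale
already; ``read_expression_tsv(log2_transform=True)`` applies log2(x+1)
for raw-scale inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionSeries",
    "GeneSetCollection",
    "CorrelationEdge",
    "ExpressionFormatError",
    "DuplicateGeneError",
    "SampleMetadataError",
    "NonNumericValueError",
    "GeneSetFormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "write_network_tsv",
    "read_network_tsv",
]


class ExpressionFormatError(ValueError):
    """Base class for malformed expression input."""


class DuplicateGeneError(ExpressionFormatError):
    """A gene identifier occurs more than once."""


class SampleMetadataError(ExpressionFormatError):
    """Matrix samples and the sample metadata table disagree."""


class NonNumericValueError(ExpressionFormatError):
    """A matrix cell cannot be parsed as a finite number."""


class GeneSetFormatError(ValueError):
    """Malformed GMT content (duplicate names, empty member lists)."""


@dataclass
class ExpressionSeries:
    """Replicated, timepoint-ordered log-expression matrix.

    Parameters
    ----------
    data
        genes x samples DataFrame; index are unique gene ids, columns are
        sample ids.
    sample_map
        sample id -> ``(timepoint, replicate_index)``.
    timepoints
        Timepoint labels in temporal order.  Every timepoint must carry at
        least two replicate samples (correlation-based statistics demand
        three and check for it themselves).
    """

    data: pd.DataFrame
    sample_map: dict[str, tuple[str, int]]
    timepoints: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timepoints:
            seen: list[str] = []
            for tp, _ in self.sample_map.values():
                if tp not in seen:
                    seen.append(tp)
            self.timepoints = seen
        self.validate()

    def validate(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise DuplicateGeneError(f"duplicate gene ids: {dupes}")
        missing = [s for s in self.data.columns if s not in self.sample_map]
        if missing:
            raise SampleMetadataError(
                f"samples missing from metadata: {missing}"
            )
        extra = [s for s in self.sample_map if s not in self.data.columns]
        if extra:
            raise SampleMetadataError(
                f"metadata samples missing from matrix: {extra}"
            )
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise NonNumericValueError(
                "non-finite value at gene "
                f"{self.data.index[bad[0]]!r}, sample "
                f"{self.data.columns[bad[1]]!r}"
            )
        for tp in self.timepoints:
            n = len(self.samples_at(tp))
            if n < 2:
                raise SampleMetadataError(
                    f"timepoint {tp!r} has {n} replicate(s); need >= 2"
                )

    # ---- convenience accessors -------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def samples_at(self, timepoint: str) -> list[str]:
        """Sample ids of one timepoint, ordered by replicate index."""
        pairs = [
            (rep, s)
            for s, (tp, rep) in self.sample_map.items()
            if tp == timepoint and s in self.data.columns
        ]
        return [s for _, s in sorted(pairs)]

    def n_replicates(self, timepoint: str) -> int:
        return len(self.samples_at(timepoint))

    def replicate_values(self, timepoint: str) -> np.ndarray:
        """genes x replicates array for one timepoint."""
        cols = self.samples_at(timepoint)
        if not cols:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return self.data[cols].to_numpy(dtype=float)

    def timepoint_means(self) -> pd.DataFrame:
        """genes x timepoints matrix of replicate means."""
        out = {
            tp: self.data[self.samples_at(tp)].mean(axis=1)
            for tp in self.timepoints
        }
        return pd.DataFrame(out, columns=self.timepoints)

    def subset_genes(self, genes: list[str]) -> "ExpressionSeries":
        return ExpressionSeries(
            data=self.data.loc[list(genes)].copy(),
            sample_map=dict(self.sample_map),
            timepoints=list(self.timepoints),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise GeneSetFormatError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out.update(members)
        return out


@dataclass(frozen=True)
class CorrelationEdge:
    """A gene--gene correlation with its two-sided significance."""

    gene_a: str
    gene_b: str
    r: float
    p: float
    passes: bool

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge on {self.gene_a!r}")


# ---------------------------------------------------------------------
# expression TSV


def read_expression_tsv(
    path, metadata_path, log2_transform: bool = False
) -> ExpressionSeries:
    """Read an expression matrix and its sample metadata.

    The matrix TSV has a header row of sample ids and gene ids in the
    first column.  The metadata TSV has columns ``sample``, ``timepoint``,
    ``replicate``; timepoint order is the order of first appearance in
    that file.  Empty or "." cells are rejected rather than treated as NA.
    """
    mat = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if mat.index.has_duplicates:
        dupes = mat.index[mat.index.duplicated()].unique().tolist()
        raise DuplicateGeneError(f"duplicate gene ids in {path}: {dupes}")
    values = np.empty(mat.shape, dtype=float)
    for j, sample in enumerate(mat.columns):
        for i, cell in enumerate(mat.iloc[:, j]):
            try:
                v = float(cell)
            except ValueError:
                v = math.nan
            if not math.isfinite(v):
                raise NonNumericValueError(
                    f"non-numeric value {cell!r} at gene "
                    f"{mat.index[i]!r}, sample {sample!r}"
                )
            values[i, j] = v
    if log2_transform:
        values = np.log2(values + 1.0)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample", "timepoint", "replicate"}
    if not required.issubset(meta.columns):
        raise SampleMetadataError(
            f"metadata needs columns {sorted(required)}, got {list(meta.columns)}"
        )
    sample_map = {
        row["sample"]: (row["timepoint"], int(row["replicate"]))
        for _, row in meta.iterrows()
    }
    timepoints: list[str] = []
    for tp in meta["timepoint"]:
        if tp not in timepoints:
            timepoints.append(tp)
    data = pd.DataFrame(values, index=mat.index, columns=mat.columns)
    return ExpressionSeries(data=data, sample_map=sample_map, timepoints=timepoints)


def write_expression_tsv(series: ExpressionSeries, path, metadata_path) -> None:
    """Write the matrix + metadata pair; 17 significant digits so that a
    read round-trip is bit-exact."""
    if series.n_genes == 0:
        raise ExpressionFormatError("refusing to write an empty gene list")
    series.data.to_csv(path, sep="\t", float_format="%.17g", index_label="gene")
    rows = []
    for tp in series.timepoints:
        for s in series.samples_at(tp):
            rows.append(
                {"sample": s, "timepoint": tp, "replicate": series.sample_map[s][1]}
            )
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GeneSetFormatError(
                    f"{path}:{lineno}: expected name, description and >=1 gene"
                )
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise GeneSetFormatError(f"duplicate gene-set name {name!r}")
            if not members:
                raise GeneSetFormatError(f"gene set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------
# PPI edge list


def read_edge_list(
    path,
    score_column: str | None = None,
    min_score: int | None = None,
) -> nx.Graph:
    """Read a STRING-style undirected edge list.

    The first two columns are gene ids; ``score_column`` optionally names
    an integer 0-1000 combined-score column.  Duplicate and reversed pairs
    collapse to one edge keeping the maximum score; self-loop rows are
    skipped with a warning; edges below ``min_score`` are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    graph = nx.Graph()
    if df.empty:
        return graph
    a_col, b_col = df.columns[:2]
    for _, row in df.iterrows():
        a, b = str(row[a_col]), str(row[b_col])
        if a == b:
            logger.warning("skipping self-loop row %s-%s", a, b)
            continue
        score = int(row[score_column]) if score_column else None
        if graph.has_edge(a, b):
            prev = graph.edges[a, b].get("score")
            if score is not None and (prev is None or score > prev):
                graph.edges[a, b]["score"] = score
        elif score is not None:
            graph.add_edge(a, b, score=score)
        else:
            graph.add_edge(a, b)
    if min_score is not None:
        drop = [
            (a, b)
            for a, b, s in graph.edges(data="score")
            if s is not None and s < min_score
        ]
        graph.remove_edges_from(drop)
        graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = []
    for a, b, s in sorted(graph.edges(data="score", default="")):
        rows.append({"gene_a": a, "gene_b": b, "score": s})
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------
# Cytoscape network export


_NETWORK_COLUMNS = ["source", "target", "interaction", "r", "p", "passes"]


def write_network_tsv(edges: list[CorrelationEdge], path) -> None:
    """Write correlation edges as a Cytoscape-importable TSV.

    One row per edge with columns source, target, interaction, r, p,
    passes; r and p carry nine decimals.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_NETWORK_COLUMNS) + "\n")
        for e in edges:
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\tcorrelation\t"
                f"{e.r:.9f}\t{e.p:.9f}\t{str(e.passes).lower()}\n"
            )


def read_network_tsv(path) -> list[CorrelationEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    return [
        CorrelationEdge(
            gene_a=row["source"],
            gene_b=row["target"],
            r=float(row["r"]),
            p=float(row["p"]),
            passes=bool(row["passes"]),
        )
        for _, row in df.iterrows()
    ]
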