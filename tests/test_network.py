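import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from dnbtip.io import GeneSetCollection
from dnbtip.network import (
    build_dysregulation_network,
    correlate_dnb_pathways,
    correlate_gene_sets,
    dnb_neighbor_degs,
    metastasis_filter,
    neighbor_genes,
    pathway_activity,
)

from conftest import make_series


class TestNeighborGenes:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        assert neighbor_genes(g, {"B"}) == {"A", "C"}

    def test_isolated_seed(self):
        g = nx.Graph()
        g.add_node("A")
        assert neighbor_genes(g, {"A"}) == set()

    def test_matches_adjacency_scan(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(30)})
        seeds = {"g1", "g5", "g9"}
        expected = set()
        for a, b in g.edges:
            if a in seeds:
                expected.add(b)
            if b in seeds:
                expected.add(a)
        assert neighbor_genes(g, seeds) == expected - seeds


class TestSetOperations:
    def test_disjoint_sets_empty(self):
        assert dnb_neighbor_degs({"A"}, {"c1": {"B"}}, ["c1"]) == set()

    def test_neighbors_subset_of_degs(self):
        degs = {"c1": {"A", "B", "C"}, "c2": {"A", "B"}}
        assert dnb_neighbor_degs({"A", "B"}, degs, ["c1", "c2"]) == {"A", "B"}

    def test_random_sets_match_set_algebra(self, rng):
        universe = [f"g{i}" for i in range(50)]
        for _ in range(20):
            nbrs = set(rng.choice(universe, 15, replace=False))
            degs = {
                "c1": set(rng.choice(universe, 20, replace=False)),
                "c2": set(rng.choice(universe, 10, replace=False)),
            }
            got = dnb_neighbor_degs(nbrs, degs, ["c1", "c2"])
            assert got == nbrs & (degs["c1"] | degs["c2"])

    def test_unknown_contrast(self):
        with pytest.raises(KeyError):
            dnb_neighbor_degs({"A"}, {"c1": {"A"}}, ["c9"])

    def test_metastasis_filter(self, rng):
        coll = GeneSetCollection(sets={"M1": ("", ["A", "B"]), "M2": ("", ["C"])})
        assert metastasis_filter({"B", "C", "D"}, coll) == {"B", "C"}


def exact_r_series(r_target):
    """6-sample series where (gA, gB) have sample correlation exactly
    r_target, built from an orthonormal basis of the centered space."""
    n = 6
    zx = np.zeros(n)
    zx[0], zx[1] = 1, -1
    zx = (zx - zx.mean()) / np.std(zx - zx.mean(), ddof=1)
    w = np.zeros(n)
    w[2], w[3] = 1, -1
    w = (w - w.mean()) / np.std(w - w.mean(), ddof=1)
    y = r_target * zx + np.sqrt(1 - r_target**2) * w
    vals = np.vstack([zx, y])
    return make_series(vals, ["W2", "W3"], 3, gene_ids=["gA", "gB"])


class TestCorrelateGeneSets:
    def test_duplicated_gene_has_unit_correlation(self):
        vals = np.array([[0.0, 1, 2, 3, 4, 5], [0.0, 1, 2, 3, 4, 5]])
        series = make_series(vals, ["W2", "W3"], 3, gene_ids=["gA", "gA2"])
        edges, counts = correlate_gene_sets(series, ["gA"], ["gA2"])
        assert edges[0].r == pytest.approx(1.0)
        assert edges[0].passes
        assert counts["gA"] == 1

    def test_boundary_is_strict(self):
        series = exact_r_series(0.8)
        edges, _ = correlate_gene_sets(series, ["gA"], ["gB"], r_threshold=0.8)
        assert edges[0].r == pytest.approx(0.8, abs=1e-12)
        assert not edges[0].passes

    def test_same_id_pairs_skipped(self, rng):
        series = make_series(rng.normal(size=(3, 6)), ["W2", "W3"], 3)
        edges, _ = correlate_gene_sets(series, ["g0", "g1"], ["g1", "g2"])
        assert all((e.gene_a, e.gene_b) != ("g1", "g1") for e in edges)

    def test_matches_pearsonr_oracle(self, rng):
        """r and p for a random 6x6 instance equal scipy.stats.pearsonr
        pair by pair."""
        series = make_series(rng.normal(size=(12, 9)), ["W2", "W3", "W4"], 3)
        a = [f"g{i}" for i in range(6)]
        b = [f"g{i}" for i in range(6, 12)]
        edges, _ = correlate_gene_sets(series, a, b)
        for e in edges:
            ref = stats.pearsonr(
                series.data.loc[e.gene_a], series.data.loc[e.gene_b]
            )
            assert e.r == pytest.approx(ref.statistic, abs=1e-12)
            assert e.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_gene(self, caplog):
        vals = np.vstack([np.ones(6), np.arange(6.0)])
        series = make_series(vals, ["W2", "W3"], 3)
        with caplog.at_level("WARNING"):
            edges, _ = correlate_gene_sets(series, ["g0"], ["g1"])
        assert edges[0].r == 0.0 and edges[0].p == 1.0

    def test_counts_sorted_descending_ties_lexicographic(self, rng):
        series = make_series(rng.normal(size=(6, 9)), ["W2", "W3", "W4"], 3)
        _, counts = correlate_gene_sets(
            series, ["g0", "g1", "g2"], ["g3", "g4", "g5"], r_threshold=0.99
        )
        vals = counts.to_numpy()
        assert (np.diff(vals) <= 0).all()
        for v in set(vals):
            tied = counts.index[counts == v]
            assert list(tied) == sorted(tied)

    def test_timepoint_means_scope(self, rng):
        series = make_series(rng.normal(size=(4, 9)), ["W2", "W3", "W4"], 3)
        edges, _ = correlate_gene_sets(
            series, ["g0"], ["g1"], sample_scope="timepoint_means"
        )
        means = series.timepoint_means()
        ref = stats.pearsonr(means.loc["g0"], means.loc["g1"])
        assert edges[0].r == pytest.approx(ref.statistic, abs=1e-12)


class TestPathwayActivity:
    def test_single_gene_pathway_dropped(self, rng, caplog):
        series = make_series(rng.normal(size=(4, 6)), ["W2", "W3"], 3)
        coll = GeneSetCollection(sets={"P1": ("", ["g0"]), "P2": ("", ["g1", "g2"])})
        with caplog.at_level("WARNING"):
            act = pathway_activity(series, coll)
        assert list(act.scores.index) == ["P2"]
        assert any("dropped" in m for m in caplog.messages)

    def test_identical_members_score_equals_gene_z(self, rng):
        row = rng.normal(size=6)
        vals = np.vstack([row, row, rng.normal(size=6)])
        series = make_series(vals, ["W2", "W3"], 3)
        act = pathway_activity(
            series, GeneSetCollection(sets={"P": ("", ["g0", "g1"])})
        )
        z = (row - row.mean()) / np.std(row, ddof=1)
        np.testing.assert_allclose(act.scores.loc["P"], z, atol=1e-12)

    def test_matches_two_step_computation(self, rng):
        series = make_series(rng.normal(size=(6, 6)), ["W2", "W3"], 3)
        members = ["g0", "g2", "g5"]
        act = pathway_activity(series, GeneSetCollection(sets={"P": ("", members)}))
        zs = []
        for g in members:
            x = series.data.loc[g].to_numpy()
            zs.append((x - x.mean()) / np.std(x, ddof=1))
        np.testing.assert_allclose(act.scores.loc["P"], np.mean(zs, axis=0), atol=1e-12)


class TestDNBPathwayAssociations:
    def test_boundary_strict_at_half(self, rng):
        series = exact_r_series(0.5)
        # pathway of two copies of gB scores exactly gB's z profile
        import pandas as pd

        data = pd.concat([series.data, series.data.loc[["gB"]].rename(index={"gB": "gB2"})])
        series2 = make_series(
            data.to_numpy(), ["W2", "W3"], 3, gene_ids=list(data.index)
        )
        act = pathway_activity(
            series2, GeneSetCollection(sets={"P": ("", ["gB", "gB2"])})
        )
        table = correlate_dnb_pathways(series2, ["gA"], act)
        assert table["r"].iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert not table["passes"].iloc[0]

    def test_formula_matches_pearsonr(self, rng):
        series = make_series(rng.normal(size=(6, 9)), ["W2", "W3", "W4"], 3)
        act = pathway_activity(
            series, GeneSetCollection(sets={"P": ("", ["g4", "g5"])})
        )
        table = correlate_dnb_pathways(series, ["g0", "g1"], act)
        for _, row in table.iterrows():
            ref = stats.pearsonr(series.data.loc[row["gene"]], act.scores.loc["P"])
            assert row["r"] == pytest.approx(ref.statistic, abs=1e-12)
            assert row["p"] == pytest.approx(ref.pvalue, abs=1e-12)


class TestDysregulationNetwork:
    def test_returns_only_passing_edges(self, rng):
        series = make_series(rng.normal(size=(10, 9)), ["W2", "W3", "W4"], 3)
        edges = build_dysregulation_network(
            series, ["g0", "g1"], ["g5", "g6", "g7"], r_threshold=0.7
        )
        assert all(e.passes for e in edges)
        assert all(abs(e.r) > 0.7 and e.p < 0.05 for e in edges)

    def test_strong_pair_captured(self):
        series = exact_r_series(0.95)
        edges = build_dysregulation_network(series, ["gA"], ["gB"])
        assert len(edges) == 1 and edges[0].r == pytest.approx(0.95, abs=1e-12)
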