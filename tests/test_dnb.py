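import itertools

import numpy as np
import pytest

from dnbtip.dnb import (
    ModuleStats,
    candidate_modules,
    criticality_index,
    detect_tipping,
    module_stats,
    permutation_null,
)
from dnbtip.simulate import SimulationConfig, simulate_critical_transition

from conftest import make_series


def brute_force_stats(series, module, timepoint):
    """Literal double loops over every gene pair."""
    cols = series.samples_at(timepoint)
    module = sorted(module)
    others = [g for g in series.gene_ids if g not in set(module)]

    def sd(g):
        return float(np.std(series.data.loc[g, cols], ddof=1))

    def abs_r(a, b):
        x = series.data.loc[a, cols].to_numpy(dtype=float)
        y = series.data.loc[b, cols].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return abs(float(np.corrcoef(x, y)[0, 1]))

    sd_in = np.mean([sd(g) for g in module])
    pcc_in = np.mean([abs_r(a, b) for a, b in itertools.combinations(module, 2)])
    pcc_out = np.mean([abs_r(a, b) for a in module for b in others])
    return sd_in, pcc_in, pcc_out


class TestModuleStats:
    def test_perfectly_correlated_pair(self):
        vals = np.array([[1.0, 2, 3], [2, 4, 6], [0, 0, 1]])
        series = make_series(vals, ["W2"], 3)
        st = module_stats(series, ["g0", "g1"], "W2")
        assert st.pcc_in == pytest.approx(1.0)
        assert st.sd_in == pytest.approx(1.5)

    def test_zero_variance_pairs_contribute_zero(self, caplog):
        vals = np.array([[1.0, 1, 1], [2, 2, 2], [0, 1, 2]])
        series = make_series(vals, ["W2"], 3)
        with caplog.at_level("WARNING"):
            st = module_stats(series, ["g0", "g1"], "W2")
        assert st.pcc_in == 0.0
        assert any("zero replicate variance" in m for m in caplog.messages)

    def test_matches_exhaustive_pair_loops(self, rng):
        """Vectorized statistics equal the brute-force double loop on 100
        random instances of up to 12 genes."""
        for _ in range(100):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, n))
            series = make_series(rng.normal(size=(n, 3)), ["W2"], 3)
            module = list(rng.choice(series.gene_ids, size=k, replace=False))
            st = module_stats(series, module, "W2")
            sd_in, pcc_in, pcc_out = brute_force_stats(series, module, "W2")
            assert st.sd_in == pytest.approx(sd_in, abs=1e-12)
            assert st.pcc_in == pytest.approx(pcc_in, abs=1e-12)
            assert st.pcc_out == pytest.approx(pcc_out, abs=1e-12)

    def test_too_few_replicates(self):
        series = make_series(np.ones((4, 2)), ["W2"], 2)
        with pytest.raises(ValueError, match="replicate"):
            module_stats(series, ["g0", "g1"], "W2")

    def test_module_too_small(self):
        series = make_series(np.random.default_rng(0).normal(size=(4, 3)), ["W2"], 3)
        with pytest.raises(ValueError, match="2 distinct"):
            module_stats(series, ["g0"], "W2")


class TestCriticalityIndex:
    def test_hand_arithmetic(self):
        st = ModuleStats("W4", sd_in=2.0, pcc_in=0.5, pcc_out=0.25, size=2)
        assert criticality_index(st, use_size_weight=True, epsilon=1e-12) == (
            pytest.approx(8.0)
        )

    def test_zero_pcc_in_annihilates(self):
        st = ModuleStats("W4", sd_in=9.0, pcc_in=0.0, pcc_out=0.1, size=5)
        assert criticality_index(st) == 0.0

    def test_monotonicity_over_random_grid(self, rng):
        """CI rises with SD_in and PCC_in and falls with PCC_out."""
        for _ in range(200):
            sd, pin, pout = rng.uniform(0.1, 3), rng.uniform(0.1, 1), rng.uniform(0.1, 1)
            base = criticality_index(ModuleStats("t", sd, pin, pout, 5))
            up = rng.uniform(0.01, 0.5)
            assert criticality_index(ModuleStats("t", sd + up, pin, pout, 5)) > base
            assert (
                criticality_index(ModuleStats("t", sd, min(1, pin + up), pout, 5))
                > base
            )
            assert criticality_index(ModuleStats("t", sd, pin, pout + up, 5)) < base

    def test_epsilon_must_be_positive(self):
        st = ModuleStats("t", 1, 1, 1, 2)
        with pytest.raises(ValueError):
            criticality_index(st, epsilon=0.0)


def block_series(rng, n_noise=10, n_rep=20):
    """Two perfectly correlated 6-gene blocks plus independent noise.

    Block genes are scaled copies of a shared high-variance pattern, so
    each block sits at zero correlation distance internally.  Twenty
    replicates keep chance noise correlations well below the block
    signal (at three replicates even independent genes correlate
    strongly in sample).
    """
    base1 = rng.normal(0, 4, size=n_rep)
    base2 = rng.normal(0, 4, size=n_rep)
    rows = [base1 * rng.uniform(0.5, 2) + rng.uniform(-1, 1) for _ in range(6)]
    rows += [base2 * rng.uniform(0.5, 2) + rng.uniform(-1, 1) for _ in range(6)]
    rows += list(rng.normal(0, 0.05, size=(n_noise, n_rep)))
    ids = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)] + [
        f"n{i}" for i in range(n_noise)
    ]
    return make_series(np.array(rows), ["W2"], n_rep, gene_ids=ids)


class TestCandidateModules:
    def test_planted_blocks_recovered(self, rng):
        """Both perfectly correlated blocks surface as candidates; a cut
        below the chance-correlation scale isolates them exactly."""
        series = block_series(rng)
        cands = candidate_modules(
            series, "W2", min_size=5, max_size=10, cut_heights=(0.2, 0.5),
            select_fraction=None,
        )
        sets = {frozenset(c) for c in cands}
        assert frozenset(f"a{i}" for i in range(6)) in sets
        assert frozenset(f"b{i}" for i in range(6)) in sets

    def test_min_size_above_n_genes_gives_empty(self, rng):
        series = make_series(rng.normal(size=(6, 3)), ["W2"], 3)
        assert candidate_modules(series, "W2", min_size=10) == []

    def test_invariant_to_gene_order(self, rng):
        series = block_series(rng)
        shuffled = series.subset_genes(
            list(np.array(series.gene_ids)[rng.permutation(series.n_genes)])
        )
        a = candidate_modules(series, "W2", select_fraction=None)
        b = candidate_modules(shuffled, "W2", select_fraction=None)
        assert {frozenset(c) for c in a} == {frozenset(c) for c in b}

    def test_sd_preselection_limits_pool(self, rng):
        series = block_series(rng, n_noise=36)
        cands = candidate_modules(series, "W2", min_size=5, select_fraction=0.25)
        pool = set().union(*cands) if cands else set()
        # the low-variance noise genes cannot enter any candidate
        assert not any(g.startswith("n") for g in pool)


class TestDetectTipping:
    def test_recovers_planted_transition_reference_seed(self):
        series, truth = simulate_critical_transition(SimulationConfig(seed=1))
        res = detect_tipping(series)
        assert series.timepoints.index(res.tipping_timepoint) == truth.t_star
        jac = len(res.module_genes & truth.module_genes) / len(
            res.module_genes | truth.module_genes
        )
        assert jac >= 0.6

    def test_direct_module_profile_matches_hand_computation(self):
        series, truth = simulate_critical_transition(
            SimulationConfig(n_genes=40, module_size=8, n_neighbors=0, seed=2)
        )
        module = sorted(truth.module_genes)
        res = detect_tipping(series, module_genes=module)
        for st, ci in zip(res.stats_by_timepoint, res.ci_by_timepoint):
            ref = module_stats(series, module, st.timepoint)
            assert st == ref
            assert ci == pytest.approx(criticality_index(ref))
        assert res.tipping_timepoint == series.timepoints[
            int(np.argmax(res.ci_by_timepoint))
        ]

    def test_criteria_flags_derive_from_stats(self):
        series, truth = simulate_critical_transition(SimulationConfig(seed=3))
        res = detect_tipping(series)
        tip = [s.timepoint for s in res.stats_by_timepoint].index(
            res.tipping_timepoint
        )
        others = [s for i, s in enumerate(res.stats_by_timepoint) if i != tip]
        at = res.stats_by_timepoint[tip]
        assert res.criteria_flags == (
            at.sd_in > max(s.sd_in for s in others),
            at.pcc_in > max(s.pcc_in for s in others),
            at.pcc_out < min(s.pcc_out for s in others),
        )

    def test_determinism(self):
        series, _ = simulate_critical_transition(SimulationConfig(seed=4))
        a = detect_tipping(series)
        b = detect_tipping(series)
        assert a.module_genes == b.module_genes
        assert a.ci_by_timepoint == b.ci_by_timepoint
        assert a.tipping_timepoint == b.tipping_timepoint

    def test_needs_two_timepoints(self):
        series, _ = simulate_critical_transition(
            SimulationConfig(n_genes=30, module_size=5, n_timepoints=1,
                             t_star=0, n_neighbors=0, seed=0)
        )
        with pytest.raises(ValueError, match="2 timepoints"):
            detect_tipping(series)


class TestPermutationNull:
    def test_extreme_p_values(self):
        series, _ = simulate_critical_transition(
            SimulationConfig(n_genes=30, module_size=5, n_neighbors=0, seed=5)
        )
        null = permutation_null(series, 5, "W4", n_perm=99, seed=0)
        assert null.pvalue(np.inf) == pytest.approx(1 / 100)
        assert null.pvalue(-np.inf) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        series, _ = simulate_critical_transition(
            SimulationConfig(n_genes=30, module_size=5, n_neighbors=0, seed=5)
        )
        a = permutation_null(series, 5, "W4", n_perm=50, seed=3)
        b = permutation_null(series, 5, "W4", n_perm=50, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize("kw", [{"n_perm": 0}, {"module_size": 1}])
    def test_invalid_arguments(self, kw):
        series, _ = simulate_critical_transition(
            SimulationConfig(n_genes=30, module_size=5, n_neighbors=0, seed=5)
        )
        args = {"module_size": 5, "n_perm": 10, **kw}
        with pytest.raises(ValueError):
            permutation_null(series, args["module_size"], "W4",
                             n_perm=args["n_perm"], seed=0)
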