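import numpy as np
import pandas as pd
import pytest

from seqgsa import analytic_moments
from seqgsa.datatypes import (
    CountMatrix,
    DegenerateRandomizationError,
    GeneSetCollection,
    RunConfig,
    make_gene_table,
)
from seqgsa.length_weighting import uniform_selection_probs
from seqgsa.restandardization import (
    bh_adjust,
    permutation_masks,
    randomization_moments,
    run_collection,
    run_collection_both,
    run_set,
)
from seqgsa.synthetic import Sim1Design, generate_sim1


class TestBHAdjust:
    def test_hand_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_empty(self):
        assert bh_adjust([]).size == 0


class TestRandomizationMoments:
    def test_constant_z_degenerate(self):
        with pytest.raises(DegenerateRandomizationError):
            randomization_moments(np.full(100, 2.0), uniform_selection_probs(100),
                                  10, 50, rng=1)

    def test_reproducible(self, rng):
        z = np.random.default_rng(0).normal(size=500)
        q = uniform_selection_probs(500)
        assert randomization_moments(z, q, 25, 100, rng=7) == randomization_moments(
            z, q, 25, 100, rng=7
        )

    def test_mean_matches_analytic_oracle(self):
        """mu_dag over N(0,1) z agrees with the closed-form E(S)."""
        n, n_S, K = 20_000, 50, 4000
        z = np.random.default_rng(3).normal(size=n)
        spec = analytic_moments.MixtureSpec(1.0, 0.0, np.zeros(n_S))
        expected = analytic_moments.maxmean_moments(spec, np.arange(n_S)).expected_S
        mu, sd = randomization_moments(z, uniform_selection_probs(n), n_S, K, rng=11)
        se = sd / np.sqrt(K)
        assert abs(mu - expected) < 3 * se + 0.01  # + finite-sample z allowance


class TestPermutationMasks:
    def test_shapes_and_group_sizes(self, rng):
        groups = np.array(["c"] * 4 + ["t"] * 4)
        masks = permutation_masks(groups, 25, rng)
        assert masks.shape == (26, 8)
        assert np.all(masks.sum(axis=1) == 4)
        assert np.array_equal(masks[0], groups == "c")


def _run_both(data, set_indices, B=60, K=60, seed=5):
    cfg = RunConfig(B=B, K=K, seed=seed, dispersion=0.0)
    sub = GeneSetCollection([data.sets[i] for i in set_indices])
    return run_collection_both(data.counts, data.table, sub, cfg)


class TestRunSetAndCollection:
    def test_pvalues_on_permutation_grid(self, small_sim1):
        res_w, res_u = _run_both(small_sim1, range(5), B=60)
        for r in res_w + res_u:
            assert 0.0 <= r.p_value <= 1.0
            assert r.p_value * 60 == pytest.approx(round(r.p_value * 60), abs=1e-9)

    def test_collection_of_one_matches_run_set(self, small_sim1):
        data = small_sim1
        cfg = RunConfig(B=40, K=50, seed=9, dispersion=0.0)
        single = run_set(data.counts, data.table, data.sets[2], cfg)
        coll = run_collection(
            data.counts, data.table, GeneSetCollection([data.sets[2]]), cfg
        )[0]
        assert single.p_value == coll.p_value
        assert single.S_star == coll.S_star
        assert single.q_value == single.p_value  # single-set BH

    def test_results_order_independent(self, small_sim1):
        data = small_sim1
        cfg = RunConfig(B=40, K=50, seed=9, dispersion=0.0)
        fwd = run_collection(data.counts, data.table, data.sets, cfg)
        rev_sets = GeneSetCollection(list(data.sets)[::-1])
        rev = {r.name: r for r in run_collection(data.counts, data.table, rev_sets, cfg)}
        for r in fwd:
            assert r.p_value == rev[r.name].p_value
            assert r.S_star == rev[r.name].S_star

    def test_empty_collection(self, small_sim1):
        data = small_sim1
        cfg = RunConfig(B=10, K=10, seed=1)
        assert run_collection(data.counts, data.table, GeneSetCollection([]), cfg) == []

    def test_equal_length_universe_weighted_equals_unweighted(self):
        """With all lengths equal the weights collapse to uniform exactly."""
        data = generate_sim1(
            Sim1Design(n_genes=100, n_sets=5, set_size=20, beta=0.2,
                       n_de=2, seed=3)
        )
        table = make_gene_table(data.table.index, np.full(100, 1500))
        cfg = RunConfig(B=40, K=50, seed=13, dispersion=0.0)
        res_w, res_u = run_collection_both(data.counts, table, data.sets, cfg)
        for w, u in zip(res_w, res_u):
            assert w.mu_dag == u.mu_dag
            assert w.sigma_dag == u.sigma_dag
            assert w.p_value == u.p_value

    def test_constant_counts_raise_degenerate(self):
        counts = pd.DataFrame(
            np.full((30, 6), 7), index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(6)],
        )
        cm = CountMatrix(counts, np.array(["c"] * 3 + ["t"] * 3))
        table = make_gene_table(counts.index, np.arange(30) + 1000)
        from seqgsa.datatypes import GeneSet

        gs = GeneSet("all7", tuple(counts.index[:10]))
        with pytest.raises(DegenerateRandomizationError):
            run_set(cm, table, gs, RunConfig(B=10, K=20, seed=1, dispersion=0.0))

    def test_missing_members_dropped_with_count(self, small_sim1):
        from seqgsa.datatypes import GeneSet

        data = small_sim1
        members = data.sets[0].members[:10] + ("not_a_gene",)
        res = run_set(data.counts, data.table, GeneSet("partial", members),
                      RunConfig(B=10, K=20, seed=1, dispersion=0.0))
        assert res.n_used == 10

    # With 2 vs 2 samples every non-tie label permutation balances the true
    # groups and kills the signal, so an extreme DE set beats all of them.
    _boundary_design = Sim1Design(
        n_genes=100, n_sets=5, set_size=20, beta=0.5, n_de=2, n_de_first=20,
        n_control=2, n_treat=2, seed=21,
    )

    def test_strong_de_set_reaches_p_zero(self):
        data = generate_sim1(self._boundary_design)
        res = run_set(data.counts, data.table, data.sets[0],
                      RunConfig(B=50, K=60, seed=2, dispersion=0.0))
        assert res.p_value == 0.0

    def test_add_one_smoothing_bounds_p_away_from_zero(self):
        data = generate_sim1(self._boundary_design)
        res = run_set(data.counts, data.table, data.sets[0],
                      RunConfig(B=50, K=60, seed=2, dispersion=0.0,
                                add_one_smoothing=True))
        assert res.p_value == pytest.approx(1 / 51)

    def test_redraw_sets_variant_runs(self, small_sim1):
        data = small_sim1
        cfg = RunConfig(B=10, K=30, K_perm=20, seed=4, dispersion=0.0,
                        redraw_sets=True)
        res = run_set(data.counts, data.table, data.sets[1], cfg)
        assert 0 <= res.p_value <= 1

    def test_null_type_i_error_controlled_small(self):
        """Random null sets give approximately uniform p-values."""
        from seqgsa.experiments import rejection_rates, sim1_replicates

        out = sim1_replicates(
            n_replicates=60, beta=0.0, n_de=0, set_indices=(0, 5),
            B=60, K=60, seed=17,
            design=Sim1Design(n_genes=200, n_sets=10, set_size=20),
        )
        se = np.sqrt(0.05 * 0.95 / 60)
        for method in ("weighted", "unweighted"):
            assert rejection_rates(out[method]).max() <= 0.05 + 3 * se
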