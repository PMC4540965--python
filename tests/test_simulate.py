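"""Synthetic data generators: determinism, analytic consistency, truth."""

import math

import numpy as np
import pytest
from scipy import stats

from coevotrace.model import (
    STATES,
    PairModelParams,
    build_qcoevo,
    relative_rate,
    stationary_distribution,
)
from coevotrace.parsimony import site_rate_proxy, total_tree_length
from coevotrace.simulate import (
    SyntheticConfig,
    edge_order,
    sample_tree,
    simulate_alignment,
    simulate_dataset,
    simulate_pair_ctmc,
    synthetic_structure,
)


class TestSampleTree:
    def test_two_leaves_is_a_cherry(self):
        tree = sample_tree(2, seed=0)
        assert len(tree.leaf_nodes()) == 2
        assert len(tree.seed_node.child_nodes()) == 2

    def test_seed_reproducibility(self):
        a = sample_tree(12, tree_length=10.0, seed=7).as_string(schema="newick")
        b = sample_tree(12, tree_length=10.0, seed=7).as_string(schema="newick")
        assert a == b

    def test_total_length_rescaled_exactly(self):
        tree = sample_tree(20, tree_length=12.5, seed=3)
        assert total_tree_length(tree) == pytest.approx(12.5)

    def test_unscaled_mean_length_matches_birth_rate(self):
        # 2n-2 edges, each Exp(1/birth_rate): mean total = (2n-2)/birth_rate
        totals = [
            total_tree_length(sample_tree(8, birth_rate=2.0, seed=s))
            for s in range(300)
        ]
        expected = 14 / 2.0
        se = np.std(totals, ddof=1) / math.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            sample_tree(1, seed=0)


class TestPairCtmc:
    def test_no_jump_ever_changes_both_sites(self):
        q = build_qcoevo(PairModelParams(S=3.0))
        for seed in range(50):
            _, _, events = simulate_pair_ctmc(q, seed=seed, duration=2.0)
            for _, a, b in events:
                assert sum(x != y for x, y in zip(STATES[a], STATES[b])) == 1

    def test_seed_reproducibility_duration_mode(self):
        q = build_qcoevo(PairModelParams(S=2.0))
        assert simulate_pair_ctmc(q, seed=5, duration=1.0) == simulate_pair_ctmc(
            q, seed=5, duration=1.0
        )

    def test_tree_mode_endpoints_consistent(self):
        q = build_qcoevo(PairModelParams(S=1.0))
        tree = sample_tree(10, tree_length=5.0, seed=2)
        leaf_states, branch_events, endpoints = simulate_pair_ctmc(q, seed=9, tree=tree)
        order = edge_order(tree)
        for i, nd in enumerate(order):
            start, end = endpoints[i]
            events = branch_events[i]
            if events:
                assert events[0][1] == start
                assert events[-1][2] == end
            else:
                assert start == end
            if nd.is_leaf():
                assert leaf_states[nd.taxon.label] == end
            if nd.parent_node is not tree.seed_node:
                j = order.index(nd.parent_node)
                assert endpoints[j][1] == start

    def test_root_state_follows_stationary_distribution(self):
        params = PairModelParams(S=4.0)
        q = build_qcoevo(params)
        pi = stationary_distribution(params)
        roots = [
            simulate_pair_ctmc(q, seed=s, duration=0.0)[0] for s in range(2000)
        ]
        freq = np.bincount(roots, minlength=4) / len(roots)
        assert np.allclose(freq, pi, atol=4 * np.sqrt(pi * (1 - pi) / 2000) + 1e-3)


class TestSimulateAlignment:
    def test_no_coevolving_pairs_truth_is_empty(self):
        cfg = SyntheticConfig(seed=1, n_leaves=8, n_independent_sites=10, tree_length=4.0)
        aln, truth, _ = simulate_alignment(cfg)
        assert truth.coevolving_pairs == []
        assert aln.n_columns == 10

    def test_seed_reproducibility(self):
        cfg = SyntheticConfig(
            seed=11, n_leaves=10, n_independent_sites=12, coevolving_S=(3.0,)
        )
        a1, t1, _ = simulate_alignment(cfg)
        a2, t2, _ = simulate_alignment(cfg)
        assert np.array_equal(a1.matrix, a2.matrix)
        assert t1.coevolving_pairs == t2.coevolving_pairs

    def test_changing_seed_changes_output(self):
        cfg1 = SyntheticConfig(seed=1, n_leaves=10, n_independent_sites=12)
        cfg2 = SyntheticConfig(seed=2, n_leaves=10, n_independent_sites=12)
        a1, _, _ = simulate_alignment(cfg1)
        a2, _, _ = simulate_alignment(cfg2)
        assert not np.array_equal(a1.matrix, a2.matrix)

    def test_column_permutation_is_a_bijection(self):
        cfg = SyntheticConfig(
            seed=4, n_leaves=8, n_independent_sites=9, coevolving_S=(2.0, 5.0)
        )
        aln, truth, _ = simulate_alignment(cfg)
        assert sorted(truth.column_permutation) == list(range(1, aln.n_columns + 1))
        assert sorted(truth.column_permutation.values()) == list(
            range(1, aln.n_columns + 1)
        )

    def test_strong_selection_suppresses_events(self):
        # mean true event count of a coevolving column should track the
        # analytic rate reduction: 0.5 * T * relative_rate(S)
        S, T = 5.0, 12.0
        counts = []
        for seed in range(40):
            cfg = SyntheticConfig(
                seed=seed,
                n_leaves=16,
                n_independent_sites=0,
                tree_length=T,
                coevolving_S=(S,),
            )
            _, truth, _ = simulate_alignment(cfg)
            counts.extend(truth.n_events.values())
        expected = 0.5 * T * relative_rate(S)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 0.05
        # and far below the neutral expectation 0.5 * T
        assert np.mean(counts) < 0.25 * T

    def test_independent_pairs_show_no_excess_double_changes(self):
        # with S = 0 the number of same-branch coincidences must match the
        # analytic expectation sum_e q(ra, le) * q(rb, le), q = (1 - e^-rl)/2
        cfg = SyntheticConfig(
            seed=6, n_leaves=24, n_independent_sites=400, tree_length=6.0,
            gamma_shape=0.5,
        )
        aln, truth, tree = simulate_alignment(cfg)
        lengths = np.array([nd.edge.length for nd in edge_order(tree)])
        cols = list(range(1, aln.n_columns + 1))
        observed, expected, variance = 0.0, 0.0, 0.0
        for a, b in zip(cols[0::2], cols[1::2]):  # 200 disjoint pairs
            observed += len(truth.changed_edges[a] & truth.changed_edges[b])
            qa = (1 - np.exp(-truth.site_rates[a] * lengths)) / 2
            qb = (1 - np.exp(-truth.site_rates[b] * lengths)) / 2
            p = qa * qb
            expected += p.sum()
            variance += (p * (1 - p)).sum()
        assert abs(observed - expected) < 3 * math.sqrt(variance)

    def test_rate_proxy_recovers_simulated_rates(self):
        cfg = SyntheticConfig(
            seed=9, n_leaves=32, n_independent_sites=60, tree_length=8.0
        )
        aln, truth, tree = simulate_alignment(cfg)
        proxies, truths = [], []
        for c in range(1, aln.n_columns + 1):
            column = dict(zip(aln.ids, aln.column(c).tolist()))
            proxies.append(site_rate_proxy(tree, column))
            truths.append(truth.site_rates[c])
        rho = stats.spearmanr(proxies, truths).statistic
        assert rho > 0.5


class TestSyntheticStructure:
    def test_perfect_coupling_matches_rate_order(self):
        rng = np.random.default_rng(0)
        rates = rng.gamma(0.5, 2.0, 80)
        context, _ = synthetic_structure(rates, rho=1.0, seed=1)
        radii = np.array(
            [
                np.linalg.norm(context.coords[context.col_to_res[c]][0])
                for c in range(1, 81)
            ]
        )
        assert stats.spearmanr(rates, radii).statistic == pytest.approx(1.0)

    def test_zero_coupling_uncorrelated(self):
        rng = np.random.default_rng(1)
        rhos = []
        for seed in range(40):
            rates = rng.gamma(0.5, 2.0, 200)
            context, _ = synthetic_structure(rates, rho=0.0, seed=seed)
            radii = [
                np.linalg.norm(context.coords[context.col_to_res[c]][0])
                for c in range(1, 201)
            ]
            rhos.append(abs(stats.spearmanr(rates, radii).statistic))
        assert np.mean(rhos) < 0.15

    def test_seed_reproducibility(self):
        rates = np.linspace(0.1, 2.0, 30)
        c1, k1 = synthetic_structure(rates, rho=0.5, seed=3)
        c2, k2 = synthetic_structure(rates, rho=0.5, seed=3)
        for col in range(1, 31):
            assert np.array_equal(
                c1.coords[c1.col_to_res[col]], c2.coords[c2.col_to_res[col]]
            )
        assert k1 == k2

    def test_accessibility_monotone_in_radius_with_buried_core(self):
        rates = np.linspace(0.1, 2.0, 100)
        context, _ = synthetic_structure(rates, rho=1.0, seed=2, buried_fraction=0.1)
        keys = [context.col_to_res[c] for c in range(1, 101)]
        radii = np.array([np.linalg.norm(context.coords[k][0]) for k in keys])
        acc = np.array([context.rel_acc[k] for k in keys])
        order = np.argsort(radii)
        assert (np.diff(acc[order]) >= -1e-9).all()
        assert (acc == 0).sum() == 10  # innermost 10% completely buried

    def test_contact_density_is_protein_like(self):
        rng = np.random.default_rng(5)
        rates = rng.gamma(0.5, 2.0, 150)
        _, contacts = synthetic_structure(rates, rho=0.5, seed=4)
        density = np.mean(list(contacts.values()))
        assert 0.02 < density < 0.25


class TestDatasetBundle:
    def test_bundle_carries_consistent_truth(self):
        cfg = SyntheticConfig(
            seed=21, n_leaves=12, n_independent_sites=20, coevolving_S=(4.0,)
        )
        bundle = simulate_dataset(cfg)
        n = bundle.alignment.n_columns
        assert n == 22
        assert len(bundle.truth.contacts) == n * (n - 1) // 2
        assert set(bundle.context.col_to_res) == set(range(1, n + 1))
        (i, j, S) = bundle.truth.coevolving_pairs[0]
        assert 1 <= i < j <= n and S == 4.0

    def test_bundle_reproducible(self):
        cfg = SyntheticConfig(seed=33, n_leaves=8, n_independent_sites=10)
        b1 = simulate_dataset(cfg)
        b2 = simulate_dataset(cfg)
        assert np.array_equal(b1.alignment.matrix, b2.alignment.matrix)
        assert b1.truth.contacts == b2.truth.contacts
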