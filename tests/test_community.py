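"""Modularity quality, Louvain consensus, gamma tuning, ARI, participation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nanet.community import (
    adjusted_rand_index,
    louvain_consensus,
    modularity_quality,
    module_participation,
    morphological_partition,
    tune_gamma,
)
from nanet.synthetic import parent_cell_coupling, simulate_traces
from nanet.connectivity import build_functional_adjacency


def two_triangles():
    W = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for a in block:
            for b in block:
                if a != b:
                    W[a, b] = 1.0
    return W


def planted_blocks(n_blocks=3, size=10, p_in=0.8, p_out=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = n_blocks * size
    truth = np.repeat(np.arange(1, n_blocks + 1), size)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if truth[i] == truth[j] else p_out
            if rng.uniform() < p:
                W[i, j] = W[j, i] = rng.uniform(0.5, 1.0)
    return W, truth


class TestModularityQuality:
    def test_two_triangles_hand_value(self):
        W = two_triangles()
        g = np.array([1, 1, 1, 2, 2, 2])
        assert modularity_quality(W, g, gamma=1.0) == pytest.approx(0.5)

    def test_single_community_zero(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(size=(8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        assert modularity_quality(W, np.ones(8), gamma=1.0) == pytest.approx(0.0)

    def test_singleton_partition_closed_form(self):
        W = two_triangles()
        g = np.arange(6)
        k = W.sum(axis=1)
        two_m = W.sum()
        expected = -np.sum(k**2) / two_m**2
        assert modularity_quality(W, g, gamma=1.0) == pytest.approx(expected)
        assert modularity_quality(W, g, gamma=1.0) <= 0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty graph"):
            modularity_quality(np.zeros((4, 4)), np.ones(4))


class TestLouvainConsensus:
    def test_two_triangles_recovered_in_every_run(self):
        res = louvain_consensus(two_triangles(), gamma=1.0, n_runs=50, seed=0)
        assert res.n_communities == 2
        assert adjusted_rand_index(res.partition,
                                   [1, 1, 1, 2, 2, 2]) == pytest.approx(1.0)
        for run in res.runs:
            assert adjusted_rand_index(run, res.partition) == pytest.approx(1.0)

    def test_complete_graph_single_community(self):
        W = np.ones((8, 8)) - np.eye(8)
        res = louvain_consensus(W, gamma=1.0, n_runs=20, seed=1)
        assert res.n_communities == 1

    def test_planted_three_blocks_recovered(self):
        W, truth = planted_blocks(seed=2)
        res = louvain_consensus(W, gamma=1.0, n_runs=50, seed=3)
        assert adjusted_rand_index(res.partition, truth) >= 0.9

    def test_consensus_beats_singletons(self):
        W, _ = planted_blocks(seed=4)
        res = louvain_consensus(W, gamma=1.0, n_runs=20, seed=5)
        q_singletons = modularity_quality(W, np.arange(len(W)), gamma=1.0)
        assert res.quality >= q_singletons

    def test_consensus_stable_across_master_seeds(self):
        W, truth = planted_blocks(p_in=0.9, p_out=0.02, seed=6)
        partitions = [
            louvain_consensus(W, gamma=1.0, n_runs=50, seed=s).partition
            for s in range(10)
        ]
        for p in partitions[1:]:
            assert adjusted_rand_index(partitions[0], p) == pytest.approx(1.0)

    def test_labels_contiguous_from_one(self):
        W, _ = planted_blocks(seed=7)
        res = louvain_consensus(W, gamma=1.0, n_runs=10, seed=8)
        labels = np.unique(res.partition)
        assert labels[0] == 1
        assert np.array_equal(labels, np.arange(1, len(labels) + 1))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty graph"):
            louvain_consensus(np.zeros((5, 5)), seed=0)


class TestTuneGamma:
    def test_same_network_matches_at_reference_gamma(self):
        W, _ = planted_blocks(seed=9)
        res = tune_gamma(W, W, gammas=(0.5, 1.0, 1.5), seed=1, gamma_ref=1.0,
                         n_runs=20)
        match = res.table.query("gamma == 1.0")["abs_diff"].iloc[0]
        assert match == 0
        assert res.table.loc[res.table["abs_diff"].idxmin(), "gamma"] <= 1.0

    def test_grid_search_agrees_with_exhaustive_scan(self):
        W_ref, _ = planted_blocks(n_blocks=3, seed=10)
        W_tgt, _ = planted_blocks(n_blocks=4, size=8, seed=11)
        gammas = (0.6, 0.9, 1.2, 1.5)
        res = tune_gamma(W_ref, W_tgt, gammas=gammas, seed=2, n_runs=20)
        # the chosen gamma truly minimizes |n_target - n_ref| on the scan
        best = res.table["abs_diff"].min()
        chosen = res.table.query("gamma == @res.gamma_star")["abs_diff"].iloc[0]
        assert chosen == best
        ties = res.table.query("abs_diff == @best")["gamma"]
        assert res.gamma_star == ties.min()  # tie-break to smallest gamma

    def test_empty_grid_rejected(self):
        W, _ = planted_blocks(seed=12)
        with pytest.raises(ValueError, match="nonempty"):
            tune_gamma(W, W, gammas=())


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        g = np.array([1, 1, 2, 2, 3, 3])
        assert adjusted_rand_index(g, g) == pytest.approx(1.0)
        assert adjusted_rand_index(g, g + 10) == pytest.approx(1.0)

    def test_one_community_vs_singletons_zero(self):
        g1 = np.ones(10)
        g2 = np.arange(10)
        assert adjusted_rand_index(g1, g2) == pytest.approx(0.0)

    def test_chance_level_near_zero(self):
        rng = np.random.default_rng(13)
        g = np.repeat(np.arange(4), 25)
        vals = [
            adjusted_rand_index(g, rng.permutation(g)) for _ in range(500)
        ]
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 0.01

    def test_symmetry_and_label_permutation_invariance(self):
        rng = np.random.default_rng(14)
        g1 = rng.integers(1, 4, size=30)
        g2 = rng.integers(1, 5, size=30)
        assert adjusted_rand_index(g1, g2) == pytest.approx(
            adjusted_rand_index(g2, g1)
        )
        relabel = {1: 7, 2: 5, 3: 9}
        g1b = np.array([relabel[v] for v in g1])
        assert adjusted_rand_index(g1, g2) == pytest.approx(
            adjusted_rand_index(g1b, g2)
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_sklearn(self, trial):
        rng = np.random.default_rng(100 + trial)
        g1 = rng.integers(0, 5, size=40)
        g2 = rng.integers(0, 3, size=40)
        assert adjusted_rand_index(g1, g2) == pytest.approx(
            adjusted_rand_score(g1, g2), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestParticipationAndMorphology:
    def test_mixed_modules_full_participation(self):
        partition = np.array([1, 1, 2, 2])
        types = np.array(["neuron", "astrocyte_segment"] * 2)
        out = module_participation(partition, types)
        assert out == {"astrocyte_segment": 1.0, "neuron": 1.0}

    def test_hand_fraction(self):
        partition = np.array([1, 1, 2, 2, 3, 3])
        types = np.array(["neuron"] * 5 + ["astrocyte_segment"])
        out = module_participation(partition, types)
        assert out["astrocyte_segment"] == pytest.approx(1 / 3)
        assert out["neuron"] == pytest.approx(1.0)

    def test_single_type_network(self):
        partition = np.array([1, 2, 2])
        types = np.array(["neuron"] * 3)
        assert module_participation(partition, types) == {"neuron": 1.0}

    def test_morphological_partition_groups_by_parent(self, small_population):
        labels, seg_ids = morphological_partition(small_population)
        parents = {
            r.roi_id: r.parent_cell_id
            for r in small_population.rois
            if r.parent_cell_id
        }
        for a in range(len(seg_ids)):
            for b in range(len(seg_ids)):
                same_cell = parents[seg_ids[a]] == parents[seg_ids[b]]
                assert (labels[a] == labels[b]) == same_cell
        assert adjusted_rand_index(labels, labels) == 1.0

    def test_neurons_only_rejected(self):
        from nanet.synthetic import generate_population

        pop = generate_population(5, 0, seed=0)
        with pytest.raises(ValueError, match="no astrocyte"):
            morphological_partition(pop)


class TestFunctionalRecoversMorphology:
    def test_within_cell_synchrony_recovers_cells(self):
        """Segments coupled within their parent cell cluster by cell."""
        from conftest import grid_population

        pop = grid_population(0, 3, 5)
        coupling = parent_cell_coupling(pop, strength=1.0)
        # a long recording so every within-cell pair clears the edge test
        ts = simulate_traces(pop, coupling, duration=600.0, seed=21,
                             base_rates={"neuron": 0.08,
                                         "astrocyte_segment": 0.05})
        fa = build_functional_adjacency(ts, n_surrogates=50, seed=22)
        truth, _ = morphological_partition(pop)
        res = louvain_consensus(fa.weights, gamma=1.0, n_runs=50, seed=23)
        assert adjusted_rand_index(res.partition, truth) >= 0.9
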