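"""Observed/expected similarity matrices, distance transforms, filtering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from repeatome_kit import (
    HitGraph,
    SimulationConfig,
    euclidean_profile_distance,
    filter_complete_clusters,
    inverse_similarity_distance,
    observed_expected_matrix,
    simulate_repeatome,
)
from repeatome_kit.distance import ClusterSimilarityMatrix


def make_graph(reads_per_species, edges):
    hg = HitGraph()
    for sp, n in reads_per_species.items():
        for i in range(n):
            hg.add_read(f"{sp}_{i}", species=sp)
    for a, b in edges:
        hg.add_hit(a, b, 90.0)
    return hg


class TestObservedExpected:
    def test_complete_graph_ratios_are_one(self):
        hg = make_graph({"AAA": 3, "BBB": 2}, [])
        nodes = list(hg.graph.nodes)
        for a, b in itertools.combinations(nodes, 2):
            hg.add_hit(a, b, 90.0)
        sim = observed_expected_matrix(hg)
        assert np.allclose(sim.matrix, 1.0)

    def test_bipartite_hand_count(self):
        # 2 species x 2 reads; all 4 inter pairs, no intra: E=4,
        # expected_inter = 4*4/6 = 8/3 -> ratio 1.5; intra observed 0
        hg = make_graph(
            {"AAA": 2, "BBB": 2},
            [(f"AAA_{i}", f"BBB_{j}") for i in range(2) for j in range(2)],
        )
        sim = observed_expected_matrix(hg)
        i, j = sim.species.index("AAA"), sim.species.index("BBB")
        assert sim.matrix[i, j] == pytest.approx(1.5)
        assert sim.matrix[i, i] == 0.0
        assert sim.matrix[j, j] == 0.0

    def test_species_without_reads_absent(self):
        hg = make_graph({"AAA": 2, "BBB": 2}, [("AAA_0", "BBB_0")])
        sim = observed_expected_matrix(hg)
        assert sim.species == ["AAA", "BBB"]  # only species with reads appear

    def test_single_species_cluster_rejected(self):
        hg = make_graph({"AAA": 3}, [("AAA_0", "AAA_1")])
        with pytest.raises(ValueError, match="single species"):
            observed_expected_matrix(hg)

    def test_uniform_random_graph_ratio_calibration(self):
        # Erdos-Renyi edges over all node pairs: mean ratio ~ 1
        rng = np.random.default_rng(0)
        hg = make_graph({"AAA": 50, "BBB": 50, "CCC": 50}, [])
        nodes = list(hg.graph.nodes)
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < 0.2:
                hg.add_hit(a, b, 90.0)
        sim = observed_expected_matrix(hg)
        assert np.nanmean(sim.offdiag()) == pytest.approx(1.0, rel=0.1)


class TestTransforms:
    def sim(self, matrix, species=None):
        species = species or [f"s{i}" for i in range(len(matrix))]
        return ClusterSimilarityMatrix(
            cluster_id="CL1",
            species=species,
            matrix=np.asarray(matrix, float),
            read_counts=dict.fromkeys(species, 10),
        )

    def test_identical_profiles_have_zero_distance(self):
        d = euclidean_profile_distance(self.sim([[1.0, 1.0], [1.0, 1.0]]))
        assert np.allclose(d.matrix, 0.0)

    def test_orthogonal_profiles_hand_value(self):
        d = euclidean_profile_distance(self.sim([[1.0, 0.0], [0.0, 1.0]]))
        assert d.matrix[0, 1] == pytest.approx(np.sqrt(2))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        sim = self.sim(m, species=list("abcd"))
        perm = [2, 0, 3, 1]
        m_p = m[np.ix_(perm, perm)]
        sim_p = self.sim(m_p, species=[list("abcd")[i] for i in perm])
        for f in (euclidean_profile_distance, inverse_similarity_distance):
            d, dp = f(sim), f(sim_p)
            assert np.allclose(d.matrix[np.ix_(perm, perm)], dp.matrix)

    def test_inverse_elementwise(self):
        m = np.array([[1.0, 2, 4], [2, 1.0, 0.5], [4, 0.5, 1.0]])
        d = inverse_similarity_distance(self.sim(m))
        assert d.matrix[0, 1] == 0.5
        assert d.matrix[0, 2] == 0.25
        assert d.matrix[1, 2] == 2.0
        assert np.allclose(np.diag(d.matrix), 0.0)

    def test_zero_similarity_rejected_by_inverse(self):
        with pytest.raises(ValueError, match="filter first"):
            inverse_similarity_distance(self.sim([[1.0, 0.0], [0.0, 1.0]]))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_euclidean_satisfies_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((5, 5)) * 3
        m = (m + m.T) / 2
        d = euclidean_profile_distance(self.sim(m)).matrix
        for i, j, k in itertools.permutations(range(5), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestFiltering:
    def sim_with(self, value):
        m = np.ones((3, 3))
        m[0, 1] = m[1, 0] = value
        return ClusterSimilarityMatrix(
            cluster_id=f"CL_{value}",
            species=list("abc"),
            matrix=m,
            read_counts=dict.fromkeys("abc", 5),
        )

    def test_zero_ratio_cluster_discarded(self):
        mats = [self.sim_with(1.0), self.sim_with(0.0), self.sim_with(2.0)]
        retained, report = filter_complete_clusters(mats)
        assert report.n_retained == 2
        assert "zero" in report.discarded["CL_0.0"]

    def test_all_complete_retained(self):
        mats = [self.sim_with(1.0), self.sim_with(2.0)]
        retained, report = filter_complete_clusters(mats)
        assert len(retained) == 2
        assert report.discarded == {}

    def test_missing_species_discarded(self):
        full = self.sim_with(1.0)
        partial = ClusterSimilarityMatrix(
            cluster_id="CL_partial",
            species=["a", "b"],
            matrix=np.ones((2, 2)),
            read_counts={"a": 5, "b": 5},
        )
        retained, report = filter_complete_clusters([full, partial])
        assert [m.cluster_id for m in retained] == ["CL_1.0"]
        assert "absent" in report.discarded["CL_partial"]

    def test_sparse_synthetic_run_populates_discard_reasons(self):
        cfg = SimulationConfig(
            tree_seed=1, data_seed=2, reads_per_species_per_cluster=5,
            conservatism=0.1, decay=2.0,
        )
        ds = simulate_repeatome(cfg)
        sims = []
        for cl in sorted(ds.hitgraphs):
            try:
                sims.append(observed_expected_matrix(ds.hitgraphs[cl], cl))
            except ValueError:
                continue
        retained, report = filter_complete_clusters(sims)
        assert report.n_retained <= report.n_input
        assert report.discarded  # sparse graphs must lose some clusters
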