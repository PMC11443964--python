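"""Correlation, PCA, direction and normalisation analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurodegen import ConductanceVector
from neurodegen.analysis import (
    DirectionVector,
    alignment,
    correlation_graph,
    homogeneous_scaling_direction,
    normalize_by_rin,
    pairwise_correlations,
    pca,
    tls_regression,
)
from neurodegen.populations import Population


@pytest.fixture()
def toy_pop(stg):
    """Five points in 8D with a known covariance eigenstructure."""
    rng = np.random.default_rng(1)
    base = rng.uniform(1.0, 10.0, size=(5, stg.N))
    return Population(stg, base)


class TestPairwiseCorrelations:
    def test_diagonal_is_one_and_matrix_symmetric(self, toy_pop):
        R = pairwise_correlations(toy_pop).to_numpy()
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T, equal_nan=True)

    def test_constant_channel_flagged_undefined(self, stg):
        rng = np.random.default_rng(0)
        M = rng.uniform(1, 2, size=(6, stg.N))
        M[:, 2] = 5.0
        R = pairwise_correlations(Population(stg, M))
        assert R.iloc[2].drop(R.columns[2]).isna().all()
        assert np.isnan(R.iloc[2, 2])

    def test_too_few_members_rejected(self, stg):
        with pytest.raises(ValueError, match="3 members"):
            pairwise_correlations(Population(stg, np.ones((2, stg.N))))


class TestCorrelationGraph:
    def test_default_threshold_is_inverse_dimension(self, toy_pop, stg):
        G = correlation_graph(toy_pop)
        assert G.graph["threshold"] == pytest.approx(1.0 / stg.N)
        for _, _, d in G.edges(data=True):
            assert abs(d["r"]) >= 1.0 / stg.N
            assert d["sign"] in (-1, 1)

    def test_threshold_above_one_gives_empty_edge_set(self, toy_pop):
        assert correlation_graph(toy_pop, threshold=1.1).number_of_edges() == 0

    def test_identical_members_yield_no_defined_edges(self, stg):
        M = np.tile(np.linspace(1, 8, stg.N), (5, 1))
        G = correlation_graph(Population(stg, M))
        assert G.number_of_edges() == 0

    def test_stg_random_population_mostly_positive_edges(self, stg_random_pop):
        G = correlation_graph(stg_random_pop)
        signs = [d["sign"] for _, _, d in G.edges(data=True)]
        assert len(signs) > 0
        assert sum(s > 0 for s in signs) > len(signs) / 2


class TestPCA:
    def test_matches_brute_force_eigendecomposition(self, stg):
        rng = np.random.default_rng(3)
        M = rng.uniform(0.5, 4.0, size=(12, stg.N))
        pop = Population(stg, M)
        P = pca(pop, center=True, standardize=False)
        C = np.cov(M, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        assert np.allclose(P.variance_fraction, evals / evals.sum(), atol=1e-10)
        for k in range(3):
            assert alignment(P.loadings[k], evecs[:, order[k]]) == pytest.approx(
                1.0, abs=1e-8
            )

    def test_collinear_points_have_single_component(self, stg):
        t = np.linspace(1, 3, 12)[:, None]
        M = t * np.linspace(0.5, 8.0, stg.N)[None, :]
        P = pca(Population(stg, M), standardize=False)
        assert P.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_fractions_sum_to_one_loadings_orthonormal(self, stg_random_pop):
        P = pca(stg_random_pop)
        assert P.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(P.variance_fraction) <= 1e-12)
        G = P.loadings @ P.loadings.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-10)

    def test_needs_more_members_than_channels(self, stg):
        with pytest.raises(ValueError, match="n > N"):
            pca(Population(stg, np.ones((4, stg.N))))

    def test_sign_convention_largest_entry_positive(self, stg_random_pop):
        P = pca(stg_random_pop)
        for row in P.loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestDirectionsAndAlignment:
    def test_scaling_direction_of_points_on_a_ray(self, stg):
        M = np.outer([1.0, 3.0], np.ones(stg.N))
        d = homogeneous_scaling_direction(Population(stg, M))
        assert np.allclose(d.vector, np.ones(stg.N) / np.sqrt(stg.N))

    def test_scaling_direction_equals_uncentered_svd_direction(self, stg):
        """TLS through the origin = dominant right-singular vector of the
        raw data matrix; for a near-ray population both coincide with the
        origin-to-mean direction."""
        rng = np.random.default_rng(5)
        t = rng.uniform(1, 4, size=20)[:, None]
        ray = np.linspace(0.5, 8.0, stg.N)[None, :]
        M = t * ray * (1 + 0.01 * rng.normal(size=(20, stg.N)))
        pop = Population(stg, M)
        d_mean = homogeneous_scaling_direction(pop)
        P = pca(pop, center=False, standardize=False)
        assert alignment(d_mean, P.loadings[0]) > 0.9999

    def test_alignment_identity_orthogonal_and_sign_invariance(self):
        u = DirectionVector(np.array([1.0, 0.0]))
        v = DirectionVector(np.array([0.0, 1.0]))
        assert alignment(u, u) == pytest.approx(1.0)
        assert alignment(u, v) == pytest.approx(0.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_alignment_symmetric_and_flip_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 6))
        assert alignment(a, b) == pytest.approx(alignment(b, a))
        assert alignment(-a, b) == pytest.approx(alignment(a, b))
        assert 0.0 <= alignment(a, b) <= 1.0 + 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            alignment(np.ones(3), np.ones(4))


class TestNormalizeByRin:
    def test_passive_population_normalised_by_gleak_exactly(self, stg):
        rows = []
        for gl in (0.01, 0.02, 0.04):
            v = np.zeros(stg.N)
            v[-1] = gl
            rows.append(v)
        pop = Population(stg, np.array(rows))
        npop = normalize_by_rin(pop, V_ref=-70.0)
        assert np.allclose(npop.matrix[:, -1], 1.0, rtol=1e-9)
        assert np.max(np.std(npop.matrix, axis=0)) < 1e-9

    def test_scaling_subset_collapses_to_a_point(self, stg, stg_scaling_subset):
        # collapse is exact up to the calcium-reversal dependence of g_in
        npop = normalize_by_rin(stg_scaling_subset, V_ref=-70.0)
        spread = np.max(np.abs(npop.matrix - npop.matrix[0]))
        assert spread < 1e-4 * np.max(np.abs(npop.matrix))


class TestTLSRegression:
    def test_through_origin_on_exact_ray(self, stg):
        M = np.zeros((3, stg.N))
        M[:, 0] = [1.0, 2.0, 3.0]
        M[:, 1] = [2.0, 4.0, 6.0]
        M[:, -1] = 0.01
        d = tls_regression(Population(stg, M), ["Na", "Kd"], through_origin=True)
        assert alignment(d, np.array([1.0, 2.0]) / np.sqrt(5)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_grid_search_over_angles(self, stg):
        rng = np.random.default_rng(8)
        M = np.zeros((6, stg.N))
        M[:, 0] = rng.uniform(1, 5, 6)
        M[:, 1] = 0.7 * M[:, 0] + rng.normal(0, 0.3, 6)
        M[:, -1] = 0.01
        pop = Population(stg, M)
        d = tls_regression(pop, ["Na", "Kd"])
        X = pop.pair(["Na", "Kd"])
        Xc = X - X.mean(axis=0)
        best, best_cost = None, np.inf
        for th in np.linspace(0, np.pi, 20001):
            v = np.array([np.cos(th), np.sin(th)])
            cost = np.sum((Xc - np.outer(Xc @ v, v)) ** 2)
            if cost < best_cost:
                best, best_cost = v, cost
        assert alignment(d, best) > 1 - 1e-6

    def test_degenerate_data_rejected(self, stg):
        M = np.ones((4, stg.N))
        with pytest.raises(ValueError, match="degenerate"):
            tls_regression(Population(stg, M), ["Na", "Kd"])
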