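"""Latent direction, residual projection, deviation geometry, edge profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hetconn as hc
from hetconn._utils import DataError
from hetconn.connectome import CohortMatrix
from hetconn.stacp import LatentDirection, ProjectionResult


def _cohort(edges, groups, standardized=False):
    n = edges.shape[0]
    return CohortMatrix(edges, [f"s{i}" for i in range(n)],
                        np.asarray(groups), None, hc.EdgeIndexMap(10),
                        standardized=standardized)


class TestFitDirection:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_closed_form_oracle(self, seed):
        """First PLS weight of a centered binary response is X^T y."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        p = int(rng.integers(3, 200))
        X = rng.standard_normal((n, p))
        mask = np.zeros(n, bool)
        mask[: n // 2] = True
        cohort = _cohort(X, np.where(mask, "NDD", "HC"), standardized=True)
        d = hc.fit_direction(cohort, mask)
        Xc = X - X.mean(axis=0)
        y = np.where(mask, 1.0, -1.0)
        w_oracle = Xc.T @ (y - y.mean())
        w_oracle /= np.linalg.norm(w_oracle)
        assert abs(abs(d.weights @ w_oracle) - 1.0) <= 1e-10
        assert np.linalg.norm(d.weights) == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_patient_positive(self, rng):
        X = rng.standard_normal((40, 8))
        mask = np.zeros(40, bool)
        mask[:20] = True
        X[mask] += 1.0
        cohort = _cohort(X, np.where(mask, "NDD", "HC"))
        d = hc.fit_direction(cohort, mask)
        t = (X - X.mean(axis=0)) @ d.weights
        assert t[mask].mean() > 0

    def test_single_class_rejected(self, rng):
        cohort = _cohort(rng.standard_normal((10, 5)), ["HC"] * 10)
        with pytest.raises(DataError):
            hc.fit_direction(cohort, np.zeros(10, bool))

    def test_planted_direction_recovery(self):
        """Direction recovery in a regime where the closed-form SNR of the
        X^T y estimator predicts cosine ~0.95."""
        cosines = []
        for seed in range(10):
            cohort, _, tr = hc.gen_cohort_fc(
                {"HC": 500, "A": 500}, n_edges=10, effect_size=0.8,
                deviation_magnitudes={"A": 0.0}, subject_magnitude_sd=0.0,
                noise_sd=1.0, seed=seed)
            d = hc.EdgePLS(cohort, hc_label="HC").fit().direction
            cosines.append(hc.cosine_similarity(d.weights,
                                                tr.planted_direction))
        assert min(cosines) >= 0.9


class TestProjection:
    def test_collinear_subject(self):
        w = np.zeros(6)
        w[0] = 1.0
        d = LatentDirection(w, 1.0)
        cohort = _cohort(3 * np.tile(w, (2, 1)), ["A", "A"])
        res = hc.project_residualize(cohort, d)
        assert res.scores[0] == pytest.approx(3.0)
        assert np.abs(res.residuals).max() <= 1e-12

    def test_orthogonal_subject(self, rng):
        w = np.zeros(6)
        w[0] = 1.0
        x = np.zeros(6)
        x[3] = 2.0
        res = hc.project_residualize(_cohort(x[None, :], ["A"]),
                                     LatentDirection(w, 1.0))
        assert res.scores[0] == 0.0
        np.testing.assert_array_equal(res.residuals[0], x)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_pythagoras_and_orthogonality(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((12, 30))
        w = rng.standard_normal(30)
        w /= np.linalg.norm(w)
        res = hc.project_residualize(_cohort(X, ["A"] * 12),
                                     LatentDirection(w, 1.0))
        for i in range(12):
            assert abs(res.residuals[i] @ w) <= 1e-10
            lhs = X[i] @ X[i]
            rhs = res.scores[i] ** 2 + res.residuals[i] @ res.residuals[i]
            assert abs(lhs - rhs) <= 1e-8 * max(1.0, lhs)


class TestDscd:
    def test_identical_residuals(self):
        res = ProjectionResult(["a", "b"], np.zeros(2),
                               np.tile([1.0, 2.0, 3.0], (2, 1)))
        profs = hc.compute_dscd(res, np.array(["X", "X"]))
        assert len(profs) == 1
        np.testing.assert_array_equal(profs[0].vector, [1.0, 2.0, 3.0])

    def test_singleton_group(self, rng):
        R = rng.standard_normal((3, 5))
        res = ProjectionResult(list("abc"), np.zeros(3), R)
        profs = hc.compute_dscd(res, np.array(["X", "X", "Y"]))
        by = {p.disorder: p for p in profs}
        np.testing.assert_array_equal(by["Y"].vector, R[2])
        assert by["Y"].n_subjects == 1

    def test_planted_geometry_recovery(self, closed_cohort):
        """Planted -0.9 deviation cosine recovered by residual projection."""
        cohort, _, _ = closed_cohort
        profs = hc.EdgePLS(cohort).fit().deviation_profiles()
        by = {p.disorder: p.vector for p in profs}
        c = hc.cosine_similarity(by["ASD"], by["ADHD"])
        assert abs(c - (-0.9)) <= 0.05

    def test_dscds_sum_to_zero_weighted(self, closed_cohort):
        # structural identity of mean residuals of a centered cohort
        cohort, _, _ = closed_cohort
        profs = hc.EdgePLS(cohort).fit().deviation_profiles()
        total = sum(p.n_subjects * p.vector for p in profs)
        assert np.abs(total).max() < 1e-8 * sum(p.n_subjects
                                                for p in profs)


class TestCosine:
    @pytest.mark.parametrize("a,b,expected", [
        ([1.0, 2.0], [1.0, 2.0], 1.0),
        ([1.0, 2.0], [-1.0, -2.0], -1.0),
        ([1.0, 0.0], [0.0, 1.0], 0.0),
    ])
    def test_known(self, a, b, expected):
        assert hc.cosine_similarity(np.array(a), np.array(b)) == \
            pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(DataError):
            hc.cosine_similarity(np.zeros(3), np.ones(3))


class TestTopEdges:
    def test_full_fraction(self):
        prof = hc.top_edges(np.array([1.0, -2.0, 3.0]), fraction=1.0)
        assert len(prof.edge_indices) == 3

    def test_half_fraction_enumeration(self):
        prof = hc.top_edges(np.array([5.0, -7.0, 1.0, 3.0]), fraction=0.5)
        assert sorted(prof.edge_indices.tolist()) == [0, 1]
        assert set(prof.signed_weights.tolist()) == {5.0, -7.0}

    def test_tie_break_by_index(self):
        prof = hc.top_edges(np.ones(10), fraction=0.3)
        assert prof.edge_indices.tolist() == [0, 1, 2]

    def test_count_is_ceiling(self):
        prof = hc.top_edges(np.arange(45, dtype=float), fraction=0.01)
        assert len(prof.edge_indices) == 1


class TestNetworkPairCounts:
    def test_hand_built_example(self):
        emap = hc.EdgeIndexMap(4)
        nets = ["vis", "vis", "dmn", "dmn"]
        v = np.array([10.0, 1.0, 5.0, 0.1, 0.2, 8.0])
        prof = hc.top_edges(v, fraction=0.5)   # edges (0,1),(0,3),(2,3)
        table = hc.network_pair_counts(prof, nets, emap)
        assert table.loc["vis", "vis"] == 1
        assert table.loc["dmn", "dmn"] == 1
        assert table.loc["vis", "dmn"] == 1
        assert table.loc["dmn", "vis"] == 1

    def test_counts_sum_to_profile_size(self, rng):
        emap = hc.EdgeIndexMap(8)
        nets = ["a", "a", "b", "b", "c", "c", "c", "a"]
        prof = hc.top_edges(rng.standard_normal(emap.n_edges), 0.25)
        table = hc.network_pair_counts(prof, nets, emap)
        diag = np.trace(table.to_numpy())
        off = (table.to_numpy().sum() - diag) / 2
        assert diag + off == len(prof.edge_indices)

    def test_unmapped_region_rejected(self):
        emap = hc.EdgeIndexMap(3)
        prof = hc.top_edges(np.ones(3), 1.0)
        with pytest.raises(DataError):
            hc.network_pair_counts(prof, {0: "a", 1: "b"}, emap)


class TestEdgePc1:
    def test_rank_one_matrix(self, rng):
        s = rng.standard_normal(10)
        v = rng.standard_normal(4)
        scores = hc.edge_pc1_scores(np.outer(s, v))
        sc = s - s.mean()
        r = np.corrcoef(scores, sc)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10

    def test_hand_computed_3x2(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
        scores = hc.edge_pc1_scores(X)
        # centered X has covariance [[1,.5],[.5,1]]; PC1 loading (1,1)/sqrt2
        expected = (X - X.mean(0)) @ (np.ones(2) / np.sqrt(2))
        np.testing.assert_allclose(np.abs(scores), np.abs(expected),
                                   atol=1e-10)

    def test_duplicated_columns_scale_scores(self, rng):
        X = rng.standard_normal((15, 3))
        s1 = hc.edge_pc1_scores(X)
        s2 = hc.edge_pc1_scores(np.hstack([X, X]))
        r = np.corrcoef(s1, s2)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10


class TestSpearman:
    def test_monotone_transform_perfect(self, rng):
        s = rng.standard_normal(30)
        rho, p, lo, hi = hc.spearman_assoc(s, np.exp(s), seed=1)
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_reversed_ranks(self):
        rho, *_ = hc.spearman_assoc(np.arange(1, 6.0),
                                    np.arange(5, 0.0, -1), seed=1)
        assert rho == pytest.approx(-1.0)

    def test_null_rarely_large(self):
        big = 0
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = rng.standard_normal(200)
            b = rng.standard_normal(200)
            from scipy import stats
            if abs(stats.spearmanr(a, b).statistic) >= 0.2:
                big += 1
        assert big <= 10

    def test_ci_contains_estimate(self, rng):
        s = rng.standard_normal(60)
        c = s + rng.standard_normal(60)
        rho, p, lo, hi = hc.spearman_assoc(s, c, seed=2)
        assert lo <= rho <= hi

    def test_all_tied_clinical_rejected(self, rng):
        with pytest.raises(DataError):
            hc.spearman_assoc(rng.standard_normal(10), np.ones(10))

    def test_clinical_coupling_recovered_from_estimates(self, closed_cohort):
        """Estimated deviation scores carry the generated clinical coupling."""
        cohort, clinical, _ = closed_cohort
        fitres = hc.EdgePLS(cohort).fit()
        patients = cohort.subset(cohort.groups != "HC").standardize()
        proj = fitres.project_residualize(patients)
        profs = hc.compute_dscd(proj, patients.groups)
        rhos = []
        for p in profs:
            d_hat = p.vector / np.linalg.norm(p.vector)
            mask = patients.groups == p.disorder
            scores = proj.residuals[mask] @ d_hat
            ids = [s for s, m in zip(patients.subject_ids, mask) if m]
            clin = clinical.set_index("subject_id").loc[ids,
                                                        "clinical_score"]
            rho, *_ = hc.spearman_assoc(scores, clin.to_numpy(), seed=0)
            rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.15)
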