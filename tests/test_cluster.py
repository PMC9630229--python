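"""Subtyping stage: standardisation, k-means, voting, stability, naming."""

import itertools

import numpy as np
import pandas as pd
import pytest

from diabsub.cluster import (
    SubtypeModel,
    assign_by_reference,
    concordance,
    jaccard_stability,
    kmeans_fit,
    name_subgroups,
    reference_centroids,
    residualize_on_covariate,
    select_k_majority_vote,
    standardize,
)
from tests.conftest import CLASSIFIERS, LOG_COLUMNS


class TestStandardize:
    def test_three_point_column_population_sd(self):
        Z, _ = standardize(np.array([[2.0], [4.0], [6.0]]), ddof=0)
        np.testing.assert_allclose(Z[:, 0], [-1.224744871, 0.0, 1.224744871], atol=1e-9)

    def test_fitted_columns_have_zero_mean_unit_sd(self, standardized_cohort):
        Z, _ = standardized_cohort
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_idempotent_with_own_params(self, standardized_cohort, table1_cohort):
        Z, params = standardized_cohort
        Z2, _ = standardize(table1_cohort, columns=CLASSIFIERS,
                            log_columns=LOG_COLUMNS, params=params)
        np.testing.assert_allclose(Z, Z2, atol=1e-12)

    def test_round_trip_inverse(self, standardized_cohort, table1_cohort):
        Z, params = standardized_cohort
        back = params.inverse_transform(Z)
        for col in CLASSIFIERS:
            np.testing.assert_allclose(
                back[col].to_numpy(), table1_cohort[col].to_numpy(), rtol=1e-10
            )

    def test_constant_column_named_in_error(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="'b'"):
            standardize(data)

    def test_nonpositive_under_log_flag_rejected(self):
        data = pd.DataFrame({"homa2b": [1.0, -2.0, 3.0]})
        with pytest.raises(ValueError, match="homa2b"):
            standardize(data, log_columns=("homa2b",))


def _brute_force_best_bipartition(X):
    """Exhaustive minimum-WSS 2-partition for tiny n (independent oracle)."""
    n = len(X)
    best, best_wss = None, np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + bits)
        if labels.min() == labels.max():
            continue
        wss = sum(
            ((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
            for c in (0, 1)
        )
        if wss < best_wss:
            best, best_wss = labels, wss
    return best, best_wss


class TestKmeans:
    def test_k1_analytic(self, rng):
        X = rng.standard_normal((40, 3))
        model = kmeans_fit(X, k=1, restarts=5, seed=0)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0), atol=1e-8)
        assert model.wss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum(), rel=1e-8)

    def test_k_equals_n_zero_wss(self, rng):
        X = rng.standard_normal((8, 2))
        model = kmeans_fit(X, k=8, restarts=5, seed=0)
        assert model.wss == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_bipartition_oracle(self, rng):
        X = np.vstack([rng.standard_normal((6, 2)), rng.standard_normal((6, 2)) + 10])
        oracle_labels, oracle_wss = _brute_force_best_bipartition(X)
        model = kmeans_fit(X, k=2, restarts=25, seed=1)
        assert model.wss == pytest.approx(oracle_wss, rel=1e-8)
        agreement, _ = concordance(model.labels, oracle_labels)
        assert agreement == 1.0

    def test_wss_non_increasing_in_restarts(self, rng):
        X = rng.standard_normal((120, 4))
        wss = [kmeans_fit(X, k=5, restarts=r, seed=3).wss for r in (1, 5, 25)]
        assert wss[0] >= wss[1] >= wss[2]

    def test_canonical_numbering_descending_size(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)),
                       rng.standard_normal((10, 2)) + 12])
        model = kmeans_fit(X, k=2, restarts=10, seed=0)
        sizes = model.cluster_sizes()
        assert sizes[0] >= sizes[1]
        assert sizes[0] == 30

    def test_nearest_centroid_fixed_point(self, standardized_cohort):
        Z, _ = standardized_cohort
        model = kmeans_fit(Z, k=3, restarts=10, seed=5)
        np.testing.assert_array_equal(model.predict(Z), model.labels)

    def test_invalid_k_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            kmeans_fit(X, k=6)
        with pytest.raises(ValueError):
            kmeans_fit(X, k=2, restarts=0)


class TestSelectK:
    @pytest.mark.parametrize("true_k", [2, 3, 4])
    def test_recovers_planted_k_for_separated_blobs(self, true_k):
        # separation 8 SDs: planted k must win in >= 95% of seeds
        hits = 0
        centers = 10.0 * np.eye(true_k)  # pairwise separation 10*sqrt(2) SDs
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.standard_normal((50, true_k)) + c for c in centers])
            vote = select_k_majority_vote(X, k_range=range(2, 7), seed=seed)
            hits += vote.winner == true_k
        assert hits >= 9

    def test_calinski_harabasz_hand_formula(self):
        # 6 points, 2 clusters: CH = (BGSS/(k-1)) / (WGSS/(n-k))
        from sklearn.metrics import calinski_harabasz_score

        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        grand = X.mean()
        bgss = sum(3 * (X[labels == c].mean() - grand) ** 2 for c in (0, 1))
        wgss = sum(((X[labels == c] - X[labels == c].mean()) ** 2).sum() for c in (0, 1))
        expected = (bgss / 1) / (wgss / 4)
        assert calinski_harabasz_score(X, labels) == pytest.approx(expected, rel=1e-10)

    def test_vote_tie_breaks_to_smallest_k(self):
        from diabsub._indices import preferred_k

        curve = {2: 1.0, 3: 1.0, 4: 0.5}
        assert preferred_k(curve, "max", [2, 3, 4]) == 2
        assert preferred_k({2: np.nan, 3: np.nan}, "max", [2, 3]) is None


class TestJaccardStability:
    def test_duplicated_separated_points_perfectly_stable(self):
        base = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]])
        X = np.repeat(base, 6, axis=0)
        model = kmeans_fit(X, k=3, restarts=5, seed=0)
        report = jaccard_stability(X, model, B=30, seed=1)
        np.testing.assert_allclose(report.per_cluster_mean, 1.0, atol=1e-12)

    def test_reported_mean_equals_mean_of_bootstraps(self, standardized_cohort):
        Z, _ = standardized_cohort
        model = kmeans_fit(Z, k=3, restarts=10, seed=2)
        report = jaccard_stability(Z, model, B=25, seed=3)
        np.testing.assert_allclose(
            report.per_cluster_mean, report.per_bootstrap.mean(axis=0), atol=1e-12
        )
        assert report.per_bootstrap.shape == (25, 3)


class TestReferenceAssignment:
    def test_row_at_centroid_and_exhaustive_oracle(self, rng):
        centroids = pd.DataFrame(
            {"bmi": [30.0, 25.0, 32.0], "onset_age": [52.0, 56.0, 40.0]}
        )
        rows = pd.DataFrame(
            {"bmi": rng.uniform(20, 35, 5), "onset_age": rng.uniform(35, 60, 5)}
        )
        got = assign_by_reference(centroids, rows)
        C = centroids.to_numpy()
        X = rows.to_numpy()
        expected = np.array(
            [np.argmin([((x - c) ** 2).sum() for c in C]) for x in X]
        )
        np.testing.assert_array_equal(got, expected)
        exact = assign_by_reference(centroids, centroids)
        np.testing.assert_array_equal(exact, [0, 1, 2])

    def test_kmeans_fixed_point_identity(self, standardized_cohort, table1_cohort):
        # assigning the discovery rows to the model's own centroids over the
        # five classifiers reproduces the k-means assignments exactly
        Z, params = standardized_cohort
        model = kmeans_fit(Z, k=3, restarts=10, seed=4, scaling=params,
                           classifier_names=CLASSIFIERS)
        cents = reference_centroids(
            pd.DataFrame(Z, columns=CLASSIFIERS), model.labels, CLASSIFIERS
        )
        labels = assign_by_reference(cents.set_axis(list(CLASSIFIERS), axis=1),
                                     pd.DataFrame(Z, columns=CLASSIFIERS))
        np.testing.assert_array_equal(labels, model.labels)

    def test_affine_rescaling_absorbed_by_scaling(self, table1_cohort):
        # distances in standardised space are invariant to unit changes
        # absorbed into the ScalingParams fitted on the same data
        vars4 = ("bmi", "onset_age", "hba1c", "tg_hdl_ratio")
        data = table1_cohort.loc[:50, list(vars4)]
        _, params = standardize(data)
        cents = reference_centroids(data, np.arange(len(data)) % 3, vars4)
        base = assign_by_reference(cents, data, scaling=params)

        scaled = data.copy()
        scaled["bmi"] *= 10.0   # e.g. kg/m^2 -> arbitrary unit
        _, params2 = standardize(scaled)
        cents2 = cents.copy()
        cents2["bmi"] *= 10.0
        rescaled = assign_by_reference(cents2, scaled, scaling=params2)
        np.testing.assert_array_equal(base, rescaled)

    def test_missing_variable_reported(self):
        centroids = pd.DataFrame({"bmi": [30.0], "hba1c": [7.0]})
        with pytest.raises(ValueError, match="hba1c"):
            assign_by_reference(centroids, pd.DataFrame({"bmi": [28.0]}))


class TestResidualize:
    def test_orthogonal_covariate_mean_centers(self):
        cov = np.array([-1.0, 1.0, -1.0, 1.0])
        col = np.array([1.0, 1.0, 3.0, 3.0])  # orthogonal to cov
        res = residualize_on_covariate(col.reshape(-1, 1), cov)
        np.testing.assert_allclose(res.to_numpy()[:, 0], col - col.mean(), atol=1e-12)

    def test_column_proportional_to_covariate_vanishes(self):
        cov = np.array([0.0, 1.0, 2.0, 3.0])
        res = residualize_on_covariate((2 * cov).reshape(-1, 1), cov)
        np.testing.assert_allclose(res.to_numpy(), 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        cov = rng.standard_normal(5)
        Y = rng.standard_normal((5, 3))
        res = residualize_on_covariate(Y, cov)
        D = np.column_stack([np.ones(5), cov])
        beta = np.linalg.solve(D.T @ D, D.T @ Y)
        np.testing.assert_allclose(res.to_numpy(), Y - D @ beta, atol=1e-10)
        # residuals orthogonal to the covariate
        assert np.abs(res.to_numpy().T @ cov).max() < 1e-8

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            residualize_on_covariate(np.ones((4, 2)), np.ones(4))


class TestConcordance:
    def test_identical_labelings(self):
        a = ["x", "y", "x", "z"]
        assert concordance(a, a) == (1.0, 1.0)

    def test_permuted_relabeling_alignment(self, rng):
        a = rng.integers(0, 3, 200)
        mapping = {0: "B", 1: "C", 2: "A"}
        b = [mapping[v] for v in a]
        agreement, kappa = concordance(a, b)
        assert agreement == 1.0
        assert kappa == 1.0

    def test_two_by_two_hand_example(self):
        # confusion [[20, 5], [10, 15]] -> po 0.7, pe 0.5, kappa 0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        agreement, kappa = concordance(a, b)
        assert agreement == pytest.approx(0.7)
        assert kappa == pytest.approx(0.4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            concordance([0, 1], [0, 1, 2])


class TestNaming:
    def test_table1_centroid_profile_names_match(self, table1_cohort):
        res = SubtypeModel(table1_cohort).fit(k=3, seed=11)
        raw = res.model.centroids_raw()
        raw.index = [res.subgroup_names[c] for c in range(3)]
        # SIRD-RII carries the worst glycaemia, MARD-II the oldest onset
        assert raw.loc["SIRD-RII", "hba1c"] == raw["hba1c"].max()
        assert raw.loc["MARD-II", "onset_age"] > raw.loc["MOD", "onset_age"]
        assert raw.loc["MOD", "homa2b"] == raw["homa2b"].max()

    def test_named_labels_recover_planted_subgroups(self, table1_cohort):
        res = SubtypeModel(table1_cohort).fit(k=3, seed=11)
        agreement, kappa = concordance(res.labels, table1_cohort["subgroup_true"])
        assert agreement > 0.75
        assert kappa > 0.6
        # naming is consistent: majority of each named cluster is the
        # matching planted subgroup
        tab = pd.crosstab(res.labels, table1_cohort["subgroup_true"])
        for name in ("MOD", "SIRD-RII", "MARD-II"):
            assert tab.loc[name].idxmax() == name

    def test_degenerate_and_wrong_k_fall_back_to_generic(self):
        from diabsub.cluster import ClusterModel

        model = ClusterModel(k=3, centroids=np.zeros((3, 5)),
                             labels=np.array([0, 1, 2]), wss=0.0,
                             classifier_names=tuple(CLASSIFIERS))
        with pytest.warns(UserWarning):
            assert name_subgroups(model) == ["cluster_1", "cluster_2", "cluster_3"]
        model2 = ClusterModel(k=2, centroids=np.zeros((2, 5)),
                              labels=np.array([0, 1]), wss=0.0)
        with pytest.warns(UserWarning):
            assert name_subgroups(model2) == ["cluster_1", "cluster_2"]


class TestSexResidualConcordance:
    def test_residualized_clustering_concordant_with_primary(self, table1_cohort):
        """Sex-residualised classifiers reproduce the primary partition."""
        res = SubtypeModel(table1_cohort).fit(k=3, seed=11)
        sex = (table1_cohort["sex"] == "male").to_numpy(float)
        analysis = table1_cohort.loc[:, list(CLASSIFIERS)].copy()
        for c in LOG_COLUMNS:
            analysis[c] = np.log(analysis[c])
        resid = residualize_on_covariate(analysis, sex)
        Zr, _ = standardize(resid)
        model_r = kmeans_fit(Zr, k=3, restarts=25, seed=11)
        agreement, kappa = concordance(res.model.labels, model_r.labels)
        assert agreement > 0.85
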