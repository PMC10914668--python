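"""Predictor encoding, PLS correctness, LOO protocol and permutation null."""

import numpy as np
import pytest

from aptaxa import (
    AdjustedMatrix,
    ClinicalProfile,
    GroupingScheme,
    encode_predictors,
    fit_pls,
    impute_clinical_training,
    loo_median_error,
    permutation_test,
)


def profile(scores, drugs=None, observed=None):
    scores = np.asarray(scores, dtype=float)
    drugs = drugs or [f"d{i}" for i in range(scores.shape[0])]
    effects = [f"e{j}" for j in range(scores.shape[1])]
    observed = np.asarray(observed, bool) if observed is not None else ~np.isnan(scores)
    return ClinicalProfile(drugs=drugs, effects=effects, scores=scores, observed=observed)


def grouping(labels, name="g"):
    return GroupingScheme(
        name=name, assignment={f"d{i}": str(lab) for i, lab in enumerate(labels)}
    )


class TestEncodePredictors:
    def test_one_hot_rows_sum_to_one(self):
        scheme = grouping([0, 1, 2, 0, 1, 2, 0])
        pm = encode_predictors(scheme)
        assert pm.D == 3
        np.testing.assert_allclose(pm.X.sum(axis=1), 1.0)

    def test_fingerprint_passthrough(self, rng):
        values = rng.standard_normal((5, 7))
        adj = AdjustedMatrix(
            drugs=[f"d{i}" for i in range(5)],
            receptors=[f"R{j}" for j in range(7)],
            values=values,
            observed=np.ones((5, 7), dtype=bool),
        )
        pm = encode_predictors(adj)
        assert pm.D == 7 and pm.source == "receptor_profile"
        np.testing.assert_array_equal(pm.X, values)

    def test_incomplete_fingerprints_rejected(self, rng):
        adj = AdjustedMatrix(
            drugs=["a", "b"], receptors=["R1"],
            values=np.array([[1.0], [2.0]]),
            observed=np.array([[True], [False]]),
        )
        with pytest.raises(ValueError, match="impute"):
            encode_predictors(adj)

    def test_single_category_warns(self, caplog):
        with caplog.at_level("WARNING"):
            pm = encode_predictors(grouping([0] * 5))
        assert pm.D == 1
        assert any("single category" in m for m in caplog.messages)


class TestImputeClinicalTraining:
    def test_complete_data_identity(self, rng):
        clin = profile(rng.standard_normal((8, 4)))
        out = impute_clinical_training(clin, q=2, seed=0)
        np.testing.assert_array_equal(out, clin.scores)

    def test_rank1_missing_cell_completed(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([3.0, 7.0, 11.0])
        scores = np.outer(a, b)
        observed = np.ones_like(scores, dtype=bool)
        observed[4, 1] = False
        clin = profile(np.where(observed, scores, np.nan), observed=observed)
        out = impute_clinical_training(clin, q=1, seed=0)
        assert out[4, 1] == pytest.approx(a[4] * b[1], abs=1e-3)

    def test_fully_missing_effect_column_rejected(self):
        scores = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]])
        clin = profile(scores)
        with pytest.raises(ValueError, match="fully missing"):
            impute_clinical_training(clin, q=1, seed=0)


class TestFitPLS:
    def test_exact_fit_in_linear_case(self, rng):
        X = rng.standard_normal((20, 4))
        B = rng.standard_normal((4, 3))
        Y = X @ B + 1.0
        model = fit_pls(X, Y, n_components=4)
        np.testing.assert_allclose(model.predict(X), Y, atol=1e-8)

    def test_full_rank_pls_equals_least_squares(self, rng):
        X = rng.standard_normal((25, 5))
        Y = rng.standard_normal((25, 4))
        model = fit_pls(X, Y, n_components=5)
        Xc = np.c_[np.ones(25), X]
        beta = np.linalg.lstsq(Xc, Y, rcond=None)[0]  # normal-equations oracle
        Xt = rng.standard_normal((7, 5))
        np.testing.assert_allclose(
            model.predict(Xt), np.c_[np.ones(7), Xt] @ beta, atol=1e-6
        )

    def test_row_permutation_invariance(self, rng):
        X = rng.standard_normal((15, 3))
        Y = rng.standard_normal((15, 2))
        perm = rng.permutation(15)
        m1 = fit_pls(X, Y, n_components=2)
        m2 = fit_pls(X[perm], Y[perm], n_components=2)
        Xt = rng.standard_normal((4, 3))
        np.testing.assert_allclose(m1.predict(Xt), m2.predict(Xt), atol=1e-10)

    def test_component_count_validated(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(X, Y, n_components=4)
        with pytest.raises(ValueError, match="3 training rows"):
            fit_pls(X[:2], Y[:2], n_components=1)


class TestLeaveOneOut:
    def test_group_constant_targets_zero_error(self):
        # each group >= 2 members and Y constant within group: held-out
        # drug's prediction is its group's training mean, exactly its value
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        Y = np.array([[10.0, -1.0], [10.0, -1.0], [10.0, -1.0],
                      [20.0, 2.0], [20.0, 2.0], [20.0, 2.0],
                      [5.0, 0.5], [5.0, 0.5], [5.0, 0.5]])
        report = loo_median_error(
            encode_predictors(grouping(labels)), profile(Y), n_components=2
        )
        assert report.observed_median_error == pytest.approx(0.0, abs=1e-10)

    def test_hand_worked_two_group_case(self):
        # 4 drugs, 2 groups of 2, 1 PLS component (full rank after centering):
        # the held-out drug's prediction is its partner's Y, so each per-drug
        # error is the median cross-partner |difference|
        labels = [0, 0, 1, 1]
        Y = np.array([[1.0, 5.0], [3.0, 9.0], [10.0, 0.0], [14.0, 2.0]])
        report = loo_median_error(
            encode_predictors(grouping(labels)), profile(Y), n_components=1
        )
        # partner differences: d0/d1: |1-3|=2, |5-9|=4 -> median 3
        # d2/d3: |10-14|=4, |0-2|=2 -> median 3
        per_drug = report.per_drug_errors
        assert all(e == pytest.approx(3.0, abs=1e-8) for e in per_drug.values())
        assert report.observed_median_error == pytest.approx(3.0, abs=1e-8)

    def test_pure_noise_has_positive_error(self, rng):
        Y = rng.standard_normal((12, 4))
        report = loo_median_error(
            encode_predictors(grouping([i % 3 for i in range(12)])), profile(Y)
        )
        assert report.observed_median_error > 0.1

    def test_errors_scored_only_on_observed_effects(self, rng):
        Y = rng.standard_normal((8, 3))
        observed = np.ones_like(Y, dtype=bool)
        observed[0, :2] = False  # d0 scored on its single observed effect
        clin = profile(np.where(observed, Y, np.nan), observed=observed)
        report = loo_median_error(
            encode_predictors(grouping([i % 2 for i in range(8)])), clin, q_impute=1
        )
        assert "d0" in report.per_drug_errors

    def test_no_leakage_from_held_out_drug(self, rng):
        # poisoning the held-out drug's clinical values must not change its
        # own prediction, only the residual it is scored against (its values
        # legitimately enter the training data of the *other* folds)
        labels = [i % 3 for i in range(9)]
        Y = rng.standard_normal((9, 4))
        pm = encode_predictors(grouping(labels))
        base = loo_median_error(pm, profile(Y))
        poisoned = Y.copy()
        poisoned[4] += 1000.0
        rep = loo_median_error(pm, profile(poisoned))
        np.testing.assert_allclose(
            rep.predictions["d4"], base.predictions["d4"], atol=1e-9
        )


class TestPermutationTest:
    def test_perfect_signal_gives_minimal_p(self):
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        Y = np.array([[float(10 * (lab + 1))] for lab in labels])
        rep = permutation_test(
            encode_predictors(grouping(labels)), profile(Y), n_perm=49, seed=0
        )
        assert rep.p_value == pytest.approx(1 / 50)
        assert rep.null_median_errors.shape == (49,)

    def test_p_value_strictly_positive_and_at_most_one(self, rng):
        Y = rng.standard_normal((9, 3))
        rep = permutation_test(
            encode_predictors(grouping([i % 3 for i in range(9)])),
            profile(Y), n_perm=19, seed=1,
        )
        assert 0 < rep.p_value <= 1

    def test_seed_reproducibility(self, rng):
        Y = rng.standard_normal((9, 3))
        pm = encode_predictors(grouping([i % 3 for i in range(9)]))
        r1 = permutation_test(pm, profile(Y), n_perm=19, seed=7)
        r2 = permutation_test(pm, profile(Y), n_perm=19, seed=7)
        np.testing.assert_array_equal(r1.null_median_errors, r2.null_median_errors)
        assert r1.p_value == r2.p_value

    def test_invalid_n_perm_rejected(self, rng):
        Y = rng.standard_normal((6, 2))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(
                encode_predictors(grouping([0, 0, 0, 1, 1, 1])), profile(Y), n_perm=0
            )

    def test_planted_grouping_discriminated_from_random(self, benchmark):
        # strong planted group->effect link: true grouping significant,
        # random grouping not — the core predictive-validity contrast
        true_rep = permutation_test(
            encode_predictors(benchmark.schemes["true_clusters"]),
            benchmark.clinical, n_perm=99, seed=5,
        )
        rand_rep = permutation_test(
            encode_predictors(benchmark.schemes["random_grouping"]),
            benchmark.clinical, n_perm=99, seed=5,
        )
        assert true_rep.p_value < 0.05
        assert rand_rep.p_value > 0.1
        assert true_rep.observed_median_error < rand_rep.observed_median_error
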