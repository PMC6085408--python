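"""Lasso repeated CV, permutation null, U -> d conversion, feature ranking."""

import collections
import math

import numpy as np
import pandas as pd
import pytest

import bingedbs as bd
from bingedbs.classify import permutation_null


def brute_force_effect_size(x, y):
    """Independent U -> d computation: pairwise counting + multiplicity loop."""
    n1, n2 = len(x), len(y)
    U = 0.0
    for xi in x:
        for yj in y:
            U += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    counts = collections.Counter(list(x) + list(y))
    N = n1 + n2
    tie_term = sum(t**3 - t for t in counts.values()) / (N * (N - 1))
    sigma2 = n1 * n2 / 12 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return U, 0.0
    z = (U - n1 * n2 / 2) / math.sqrt(sigma2)
    r = z / math.sqrt(N)
    return U, 2 * r / math.sqrt(1 - r**2)


class TestEffectSize:
    def test_central_u_gives_zero_d(self):
        rep = bd.compare_distributions([1.0, 4.0], [2.0, 3.0])
        assert rep.U == 2.0  # = n1 n2 / 2
        assert rep.d == 0.0

    def test_matches_brute_force_on_small_samples(self):
        rng = np.random.default_rng(0)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                for _ in range(5):
                    x = rng.integers(0, 4, size=n1).astype(float)  # many ties
                    y = rng.integers(0, 4, size=n2).astype(float)
                    rep = bd.compare_distributions(x, y)
                    U_ref, d_ref = brute_force_effect_size(x, y)
                    assert rep.U == pytest.approx(U_ref)
                    assert rep.d == pytest.approx(d_ref, abs=1e-9)

    def test_swapping_samples_flips_sign_only(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
        a = bd.compare_distributions(x, y)
        b = bd.compare_distributions(y, x)
        assert a.d == pytest.approx(-b.d)
        assert a.direction == "observed>null"

    def test_complete_separation_matches_closed_form(self):
        x = np.arange(100, 200, dtype=float)
        y = np.arange(0, 100, dtype=float)
        rep = bd.compare_distributions(x, y)
        assert rep.U == 100 * 100
        _, d_ref = brute_force_effect_size(x, y)
        assert rep.d == pytest.approx(d_ref)

    def test_identical_constant_samples_degenerate(self):
        rep = bd.compare_distributions([1.0, 1.0], [1.0, 1.0])
        assert rep.degenerate and rep.d == 0.0


class TestLassoRepeatedCV:
    def test_separated_classes_classify_near_perfectly(self, planted_design):
        cv = bd.fit_lasso_repeated_cv(planted_design, reps=20, seed=0)
        assert cv.mean > 0.95
        assert cv.survival_pct["f00"] > 90.0

    def test_null_cohort_hovers_near_chance(self, null_design):
        cv = bd.fit_lasso_repeated_cv(null_design, reps=20, seed=0)
        assert 0.35 < cv.mean < 0.65

    def test_constant_feature_never_selected(self, planted_design):
        X = planted_design.X.copy()
        X["const"] = 3.14
        dm = bd.DesignMatrix(X=X, y=planted_design.y, groups=planted_design.groups)
        cv = bd.fit_lasso_repeated_cv(dm, reps=5, seed=0)
        assert cv.survival_pct["const"] == 0.0

    def test_duplicated_feature_splits_selections(self, planted_design):
        base = bd.fit_lasso_repeated_cv(planted_design, reps=10, seed=1)
        X = planted_design.X.copy()
        X["f00_copy"] = X["f00"]
        dup = bd.fit_lasso_repeated_cv(
            bd.DesignMatrix(X=X, y=planted_design.y, groups=planted_design.groups),
            reps=10,
            seed=1,
        )
        combined = dup.survival_pct["f00"] + dup.survival_pct["f00_copy"]
        assert combined <= base.survival_pct["f00"] + 110.0  # no survival inflation
        assert dup.survival_pct["f00_copy"] < base.survival_pct["f00"] + 1e-9

    def test_survival_bounded_and_consistent(self, planted_design):
        cv = bd.fit_lasso_repeated_cv(planted_design, reps=5, seed=2)
        assert ((cv.survival_pct >= 0) & (cv.survival_pct <= 100)).all()
        assert cv.n_models == 5 * 4
        assert np.all((cv.accuracies >= 0) & (cv.accuracies <= 1))

    def test_rejects_single_class_or_tiny_cohorts(self, null_design):
        with pytest.raises(ValueError):
            bd.DesignMatrix(X=null_design.X, y=np.zeros(24, int), groups=null_design.groups)
        dm = bd.DesignMatrix(
            X=null_design.X.iloc[:4],
            y=[0, 0, 1, 1],
            groups=["a", "a", "b", "b"],
        )
        with pytest.raises(ValueError, match=">= 2 animals"):
            bd.fit_lasso_repeated_cv(dm)

    def test_sessions_of_an_animal_share_fold_labels(self, null_design):
        with pytest.raises(ValueError, match="inconsistent labels"):
            bd.DesignMatrix(
                X=null_design.X,
                y=np.arange(24) % 2,  # splits animals across classes
                groups=null_design.groups,
            )


class TestPermutationNull:
    def test_planted_effect_vanishes_under_permutation(self, planted_design):
        cv = bd.fit_lasso_repeated_cv(planted_design, reps=15, seed=0)
        null = permutation_null(planted_design, n_perms=3, reps=15, seed=0)
        assert cv.mean > 0.9
        assert abs(null.pooled_accuracies.mean() - 0.5) < 0.12
        rep = bd.compare_distributions(cv.accuracies, null.pooled_accuracies)
        assert rep.d > 1.0

    def test_marginal_label_counts_preserved(self, planted_design):
        animals, labels = planted_design.animal_labels()
        rng = np.random.default_rng(0)
        permuted = labels.copy()
        rng.shuffle(permuted)
        assert sorted(permuted) == sorted(labels)

    def test_zero_permutations_rejected(self, null_design):
        with pytest.raises(ValueError):
            permutation_null(null_design, n_perms=0)


class TestUnivariate:
    def test_constant_feature_tracks_training_majority(self, null_design):
        # balanced classes: removing an animal makes its class the training
        # minority, so an uninformative model is wrong on every split
        acc, _ = bd.univariate_logistic_loocv(
            np.full(24, 2.5), null_design.y, null_design.groups
        )
        assert acc <= 0.5

    def test_label_leak_feature_perfect_and_up(self, null_design):
        rng = np.random.default_rng(0)
        x = null_design.y + 0.01 * rng.standard_normal(24)
        acc, direction = bd.univariate_logistic_loocv(x, null_design.y, null_design.groups)
        assert acc == pytest.approx(1.0)
        assert direction == "↑"

    def test_planted_feature_outranks_median_feature(self, planted_design):
        accs = {
            name: bd.univariate_logistic_loocv(
                planted_design.X[name], planted_design.y, planted_design.groups
            )[0]
            for name in ["f00", "f01", "f02", "f03", "f04"]
        }
        others = [v for k, v in accs.items() if k != "f00"]
        assert accs["f00"] > np.median(others)


class TestFeatureReport:
    def test_schema_and_planted_feature_heads_rankings(self, planted_design):
        cv = bd.fit_lasso_repeated_cv(planted_design, reps=10, seed=0)
        univ = {
            n: bd.univariate_logistic_loocv(planted_design.X[n], planted_design.y, planted_design.groups)
            for n in planted_design.feature_names
        }
        report = bd.build_feature_report(cv, univ, k=5)
        assert list(report.logistic_top.columns) == ["direction", "feature", "pct_accuracy"]
        assert list(report.lasso_top.columns) == ["direction", "feature", "pct_survival"]
        assert report.logistic_top.iloc[0]["feature"] == "f00"
        assert report.lasso_top.iloc[0]["feature"] == "f00"
        assert report.logistic_top.iloc[0]["direction"] == "↑"

    def test_oversized_k_truncates_with_warning(self, planted_design, caplog):
        cv = bd.fit_lasso_repeated_cv(planted_design, reps=2, seed=0)
        univ = {
            n: (0.5, "↑") for n in planted_design.feature_names
        }
        report = bd.build_feature_report(cv, univ, k=1000)
        assert len(report.lasso_top) == 60
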