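"""Weighted accuracy, nested selection, stacking, and permutation tests."""

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

from oddballeeg import (
    ClassifierSpec,
    loocv,
    nested_select,
    permutation_test,
    stack_mmse,
    weighted_accuracy,
)
from oddballeeg.classify import (
    ClassificationReport,
    evaluate,
    fit_predict_nb,
)
from oddballeeg.containers import ValidationError


def _two_clouds(rng, n_pos=10, n_neg=14, sep=6.0, d=3):
    X = np.vstack(
        [
            rng.standard_normal((n_pos, d)) + sep,
            rng.standard_normal((n_neg, d)),
        ]
    )
    y = np.array(["ASD"] * n_pos + ["TD"] * n_neg)
    return X, y


class TestWeightedAccuracy:
    def test_perfect_predictions(self):
        y = np.array(["ASD", "ASD", "TD", "TD", "TD"])
        assert weighted_accuracy(y, y) == 1.0

    def test_constant_predictor_scores_half(self):
        y = np.array(["ASD"] * 3 + ["TD"] * 17)
        assert weighted_accuracy(y, np.array(["ASD"] * 20)) == 0.5

    def test_printed_formula_case(self):
        # 19 vs 30 subjects, 13 and 27 correct: (30*13 + 19*27)/(2*19*30)
        truth = np.array(["ASD"] * 19 + ["TD"] * 30)
        pred = np.concatenate(
            [
                ["ASD"] * 13, ["TD"] * 6,
                ["TD"] * 27, ["ASD"] * 3,
            ]
        )
        assert weighted_accuracy(truth, pred) == pytest.approx(
            (30 * 13 + 19 * 27) / (2 * 19 * 30)
        )
        assert weighted_accuracy(truth, pred) == pytest.approx(0.7921, abs=5e-5)

    def test_matches_balanced_accuracy_on_random_tables(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 30))
            y = rng.choice(["ASD", "TD"], size=n)
            if len(np.unique(y)) < 2:
                continue
            pred = rng.choice(["ASD", "TD"], size=n)
            assert weighted_accuracy(y, pred) == pytest.approx(
                balanced_accuracy_score(y, pred), abs=1e-12
            )

    def test_label_swap_symmetry(self, rng):
        y = rng.choice(["ASD", "TD"], size=20)
        y[:2] = ["ASD", "TD"]
        pred = rng.choice(["ASD", "TD"], size=20)
        swap = {"ASD": "TD", "TD": "ASD"}
        y2 = np.array([swap[v] for v in y])
        p2 = np.array([swap[v] for v in pred])
        assert weighted_accuracy(y, pred) == pytest.approx(
            weighted_accuracy(y2, p2)
        )

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValidationError):
            weighted_accuracy(np.array(["TD", "TD"]), np.array(["TD", "TD"]))


class TestLOOCV:
    def test_separable_toy_set_all_correct(self, rng):
        X, y = _two_clouds(rng, n_pos=2, n_neg=2, sep=20.0)
        preds, chosen = loocv(ClassifierSpec(kind="nb"), X, y)
        assert list(preds) == list(y)
        assert len(chosen) == 4  # one fit (and hyperparameter) per subject

    def test_order_equivariance_nb(self, rng):
        X, y = _two_clouds(rng, n_pos=6, n_neg=8, sep=2.0)
        preds, _ = loocv(ClassifierSpec(kind="nb"), X, y)
        perm = rng.permutation(len(y))
        preds_p, _ = loocv(ClassifierSpec(kind="nb"), X[perm], y[perm])
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert list(preds_p[inv]) == list(preds)

    def test_too_small_class_rejected(self, rng):
        X = rng.standard_normal((4, 2))
        y = np.array(["ASD", "TD", "TD", "TD"])
        with pytest.raises(ValidationError):
            loocv(ClassifierSpec(kind="nb"), X, y)

    @pytest.mark.parametrize("kind", ["svm", "logreg"])
    def test_margin_classifiers_learn_separable_data(self, rng, kind):
        X, y = _two_clouds(rng, n_pos=6, n_neg=8, sep=8.0)
        preds, chosen = loocv(ClassifierSpec(kind=kind), X, y, seed=0)
        assert weighted_accuracy(y, preds) == 1.0
        assert all(c in ClassifierSpec(kind=kind).c_grid for c in chosen)


class TestNestedSelect:
    def test_single_value_grid_returned(self, rng):
        X, y = _two_clouds(rng, n_pos=5, n_neg=5)
        spec = ClassifierSpec(kind="svm", c_grid=np.array([0.25]))
        assert nested_select(spec, X, y, seed=0) == 0.25

    def test_ties_resolve_to_smallest(self):
        # degenerate data: every C yields the same predictions, so all
        # grid values tie and the most regularised one must win
        X = np.zeros((12, 3))
        y = np.array(["ASD", "TD"] * 6)
        spec = ClassifierSpec(kind="svm")
        assert nested_select(spec, X, y, seed=0) == float(min(spec.c_grid))

    def test_regularisation_helps_on_noise_dimensions(self):
        rng = np.random.default_rng(3)
        n = 24
        signal = np.concatenate([np.full(n // 2, 1.0), np.full(n // 2, -1.0)])
        y = np.where(signal > 0, "ASD", "TD")
        X = np.column_stack(
            [signal * 0.3 + rng.standard_normal(n) * 0.4,
             rng.standard_normal((n, 40)) * 3.0 @ np.eye(40)]
        )
        spec = ClassifierSpec(kind="svm")
        chosen = nested_select(spec, X, y, seed=0)
        assert chosen < float(max(spec.c_grid))


class TestNaiveBayes:
    def test_separated_clouds_classified_perfectly(self, rng):
        X_train, y_train = _two_clouds(rng, sep=10.0)
        X_test = np.vstack([np.full(3, 10.0), np.zeros(3)])
        preds, _ = fit_predict_nb(X_train, y_train, X_test)
        assert list(preds) == ["ASD", "TD"]

    def test_threshold_near_half_on_symmetric_data(self, rng):
        X, y = _two_clouds(rng, n_pos=12, n_neg=12, sep=3.0)
        _, t = fit_predict_nb(X, y, X[:1])
        assert 0.3 <= t <= 0.7

    def test_posterior_matches_hand_computed_likelihood_ratio(self):
        from oddballeeg.classify import _nb_posteriors

        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array(["ASD", "ASD", "ASD", "TD", "TD", "TD"])
        x_new = np.array([[4.0]])
        post = _nb_posteriors(X, y, x_new)[0]
        mu_a, var_a = 1.0, np.var([0, 1, 2])
        mu_t, var_t = 11.0, np.var([10, 11, 12])
        like = lambda x, mu, var: np.exp(-((x - mu) ** 2) / (2 * var)) / np.sqrt(
            2 * np.pi * var
        )
        expected = like(4, mu_t, var_t) / (
            like(4, mu_t, var_t) + like(4, mu_a, var_a)
        )
        assert post == pytest.approx(expected, abs=1e-6)


class TestStacking:
    def test_output_width_24(self, rng):
        sel = rng.standard_normal((10, 23))
        mmse = rng.standard_normal((10, 40))
        y = np.array(["ASD"] * 5 + ["TD"] * 5)
        assert stack_mmse(sel, mmse, y).shape == (10, 24)

    def test_predictive_block_reproduces_labels(self, rng):
        sel = rng.standard_normal((12, 23))
        y = np.array(["ASD"] * 6 + ["TD"] * 6)
        mmse = np.where(y == "ASD", 5.0, -5.0)[:, None] + 0.01 * rng.standard_normal(
            (12, 8)
        )
        out = stack_mmse(sel, mmse, y)
        np.testing.assert_array_equal(out[:, 23], (y == "ASD").astype(float))

    def test_appended_value_ignores_own_label(self, rng):
        sel = rng.standard_normal((12, 23))
        mmse = rng.standard_normal((12, 8))
        y = np.array(["ASD"] * 6 + ["TD"] * 6)
        base = stack_mmse(sel, mmse, y, seed=0)
        y_flip = y.copy()
        y_flip[3] = "TD"
        flipped = stack_mmse(sel, mmse, y_flip, seed=0)
        # subject 3's out-of-fold value is trained without subject 3,
        # so flipping its label cannot change its own stacked feature
        assert flipped[3, 23] == base[3, 23]

    def test_mismatched_blocks_rejected(self, rng):
        with pytest.raises(ValidationError):
            stack_mmse(
                rng.standard_normal((5, 23)),
                rng.standard_normal((6, 8)),
                np.array(["ASD"] * 3 + ["TD"] * 3),
            )


class TestPermutation:
    def test_separable_cohort_minimal_p(self, rng):
        X, y = _two_clouds(rng, n_pos=5, n_neg=7, sep=15.0)
        obs, p, perm = permutation_test(
            ClassifierSpec(kind="nb"), X, y, n_perm=19, seed=0
        )
        assert obs == 1.0
        assert (perm < obs).all()
        assert p == pytest.approx(1 / 20)

    def test_noise_features_score_near_chance(self, rng):
        X = rng.standard_normal((20, 5))
        y = np.array(["ASD"] * 9 + ["TD"] * 11)
        obs, p, _ = permutation_test(
            ClassifierSpec(kind="nb"), X, y, n_perm=19, seed=1
        )
        assert 0.25 <= obs <= 0.75
        assert p > 0.05

    def test_zero_permutations_rejected(self, rng):
        X, y = _two_clouds(rng)
        with pytest.raises(ValidationError):
            permutation_test(ClassifierSpec(kind="nb"), X, y, n_perm=0)


class TestEvaluate:
    def test_closed_form_report_metrics(self):
        truth = np.array(["ASD"] * 19 + ["TD"] * 30)
        all_td = np.array(["TD"] * 49)
        rep = ClassificationReport.from_predictions(truth, all_td)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0
        assert rep.weighted_accuracy == 0.5

    def test_deterministic_rerun(self, rng):
        X, y = _two_clouds(rng, n_pos=5, n_neg=6, sep=2.0)
        sets = {"ours": X}
        specs = [ClassifierSpec(kind="nb")]
        a = evaluate(sets, y, specs, seed=4)
        b = evaluate(sets, y, specs, seed=4)
        ka, kb = a[("ours", "nb")], b[("ours", "nb")]
        assert list(ka.predictions) == list(kb.predictions)
        assert ka.weighted_accuracy == kb.weighted_accuracy

    def test_degenerate_subgroup_skipped_with_warning(self, rng):
        X, y = _two_clouds(rng, n_pos=4, n_neg=4, sep=5.0)
        sub = {"odd": np.array([True] + [False] * 7)}
        with pytest.warns(UserWarning, match="odd"):
            out = evaluate({"ours": X}, y, [ClassifierSpec(kind="nb")],
                           subgroups=sub)
        assert ("ours", "nb @ odd") not in out
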