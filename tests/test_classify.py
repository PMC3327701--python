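"""SVM training, cross-validated evaluation, posterior combination, and the
permutation test mechanics."""

import numpy as np
import pytest

from tlemorph import (
    ClassifierSpec,
    combine_side_classifiers,
    evaluate_repeated_kfold,
    metrics_from_confusion,
    permutation_test,
    train_with_grid,
)
from tlemorph.classify import (
    GridChoice,
    PosteriorModel,
    infer_positive_label,
    train_posterior_model,
)

from conftest import make_two_group_cohort


def reduced(scheme="volumetric", **kw):
    return ClassifierSpec.reduced(scheme=scheme, **kw)


class TestClassifierSpec:
    def test_scheme_fixes_kernel(self):
        assert ClassifierSpec(scheme="volumetric").kernel == "rbf"
        assert ClassifierSpec(scheme="spectral").kernel == "linear"

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(C_grid=())
        with pytest.raises(ValueError):
            ClassifierSpec(gamma_grid=(0.0, 1.0))
        with pytest.raises(ValueError):
            ClassifierSpec(D_grid=(0,))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            ClassifierSpec(scheme="quantum")


class TestMetrics:
    def test_closed_form_confusion(self):
        m = metrics_from_confusion(tp=60, fn=0, tn=26, fp=2)
        assert m.sensitivity == pytest.approx(100.0)
        assert m.specificity == pytest.approx(100.0 * 26 / 28)
        assert m.accuracy == pytest.approx(100.0 * 86 / 88)
        assert m.undefined == ()

    def test_perfect_and_worst_cases(self):
        perfect = metrics_from_confusion(10, 0, 10, 0)
        assert (perfect.accuracy, perfect.sensitivity, perfect.specificity) == (
            100.0, 100.0, 100.0,
        )
        worst = metrics_from_confusion(0, 10, 0, 10)
        assert (worst.accuracy, worst.sensitivity, worst.specificity) == (
            0.0, 0.0, 0.0,
        )

    def test_undefined_metrics_flagged_not_zeroed(self):
        m = metrics_from_confusion(tp=0, fn=0, tn=8, fp=2)
        assert np.isnan(m.sensitivity)
        assert m.undefined == ("sensitivity",)
        m2 = metrics_from_confusion(tp=5, fn=5, tn=0, fp=0)
        assert np.isnan(m2.specificity)
        assert m2.undefined == ("specificity",)

    def test_accuracy_consistent_with_class_rates(self):
        m = metrics_from_confusion(tp=7, fn=3, tn=12, fp=8)
        n_pos, n_neg = 10, 20
        recombined = (m.sensitivity * n_pos + m.specificity * n_neg) / (n_pos + n_neg)
        assert m.accuracy == pytest.approx(recombined)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            metrics_from_confusion(0, 0, 0, 0)


class TestInferPositiveLabel:
    def test_patients_beat_controls(self):
        assert infer_positive_label(["control", "TLE-HA"]) == "TLE-HA"

    def test_left_focus_positive_in_lateralization(self):
        assert infer_positive_label(["TLE-HA_R", "TLE-HA_L"]) == "TLE-HA_L"

    def test_fallback_is_sorted_first(self):
        assert infer_positive_label(["beta", "alpha"]) == "alpha"


class TestTrainWithGrid:
    def test_separable_clusters_reach_perfect_loo(self, rng):
        x = np.concatenate([rng.normal(-5, 0.2, 8), rng.normal(5, 0.2, 8)])
        y = np.array(["a"] * 8 + ["b"] * 8)
        model, choice = train_with_grid(x[:, None], y, reduced())
        assert choice.loo_accuracy == 1.0
        assert model.predict([[-5.0]])[0] == "a"
        assert model.predict([[5.0]])[0] == "b"

    def test_ties_resolve_to_smallest_hyperparameters(self, rng):
        # trivially separable data: every grid point scores 100%, so the
        # tie rule must pick the smallest D, then C, then gamma
        x = np.concatenate([rng.normal(-5, 0.1, 6), rng.normal(5, 0.1, 6)])
        X = np.column_stack([x, x])
        y = np.array(["a"] * 6 + ["b"] * 6)
        spec = reduced()
        _, choice = train_with_grid(X, y, spec)
        assert choice.D == min(spec.D_grid)
        assert choice.C == min(spec.C_grid)
        assert choice.gamma == min(spec.gamma_grid)

    def test_single_structure_grid(self, rng):
        x = np.concatenate([rng.normal(-3, 0.5, 5), rng.normal(3, 0.5, 5)])
        y = np.array(["a"] * 5 + ["b"] * 5)
        spec = ClassifierSpec(C_grid=(1.0,), gamma_grid=(0.5,), D_grid=(1,))
        _, choice = train_with_grid(x[:, None], y, spec)
        assert choice.D == 1

    def test_infeasible_d_grid_rejected(self, rng):
        X = rng.normal(0, 1, (10, 1))
        y = np.array(["a"] * 5 + ["b"] * 5)
        spec = ClassifierSpec(D_grid=(5,))
        with pytest.raises(ValueError, match="no feasible D"):
            train_with_grid(X, y, spec)

    def test_small_classes_rejected(self, rng):
        X = rng.normal(0, 1, (4, 1))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            train_with_grid(X, y, reduced())

    def test_linear_scheme_ignores_gamma(self, rng):
        x = np.concatenate([rng.normal(-4, 0.5, 6), rng.normal(4, 0.5, 6)])
        # one structure block of k = 2 spectral feature columns
        X = np.column_stack([x, x])
        y = np.array(["a"] * 6 + ["b"] * 6)
        _, choice = train_with_grid(X, y, reduced(scheme="spectral"))
        assert choice.gamma is None


class TestEvaluateRepeatedKfold:
    def test_planted_effect_classified_accurately(self, planted_cohort):
        report = evaluate_repeated_kfold(
            planted_cohort, spec=reduced(), folds=5, repeats=2, seed=0
        )
        assert report.accuracy_mean >= 90.0
        assert report.positive_label == "patient_L"
        assert report.accuracy.shape == (2,)

    def test_same_seed_reproduces_everything(self, planted_cohort):
        kw = dict(spec=reduced(), folds=5, repeats=2, seed=7)
        r1 = evaluate_repeated_kfold(planted_cohort, **kw)
        r2 = evaluate_repeated_kfold(planted_cohort, **kw)
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)
        np.testing.assert_array_equal(r1.accuracy, r2.accuracy)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)

    def test_different_seeds_draw_different_folds(self, planted_cohort):
        r1 = evaluate_repeated_kfold(planted_cohort, spec=reduced(), folds=5,
                                     repeats=1, seed=1)
        r2 = evaluate_repeated_kfold(planted_cohort, spec=reduced(), folds=5,
                                     repeats=1, seed=2)
        assert not np.array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_folds_equal_to_n_is_leave_one_out(self, planted_cohort):
        n = len(planted_cohort)
        report = evaluate_repeated_kfold(
            planted_cohort, spec=reduced(), folds=n, repeats=1, seed=0
        )
        # every subject is its own test fold
        assert sorted(report.fold_assignments[0]) == list(range(n))
        assert report.folds == n

    def test_stratification_keeps_both_classes_in_training(self, planted_cohort):
        y = planted_cohort.labels()
        report = evaluate_repeated_kfold(
            planted_cohort, spec=reduced(), folds=5, repeats=2, seed=3
        )
        for r in range(report.repeats):
            for f in range(report.folds):
                train = report.fold_assignments[r] != f
                assert len(np.unique(y[train])) == 2

    def test_unnormalized_cohort_rejected(self, base_fractions):
        cohort = make_two_group_cohort(base_fractions, seed=5, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            evaluate_repeated_kfold(cohort, spec=reduced())

    def test_spectral_scheme_runs_with_train_only_embedding(self, planted_cohort):
        report = evaluate_repeated_kfold(
            planted_cohort,
            spec=reduced(scheme="spectral", embedding="train_only"),
            folds=5,
            repeats=1,
            seed=0,
        )
        assert report.accuracy_mean >= 80.0

    def test_summary_fields(self, planted_cohort):
        report = evaluate_repeated_kfold(
            planted_cohort, spec=reduced(), folds=5, repeats=2, seed=0
        )
        s = report.summary()
        assert s["scheme"] == "volumetric"
        assert 0 <= s["accuracy_mean"] <= 100
        assert s["chosen_D_mode"] in (1, 2, 4, 8)
        assert report.to_json()


class _StubModel:
    def __init__(self, p):
        self._p = p

    def patient_posterior(self, subject_features):
        return self._p


class TestCombineSideClassifiers:
    def test_both_low_posteriors_give_control(self):
        label, p = combine_side_classifiers(_StubModel(0.1), _StubModel(0.1), {})
        assert (label, p) == ("control", 0.1)

    def test_max_rule_takes_the_confident_side(self):
        label, p = combine_side_classifiers(_StubModel(0.9), _StubModel(0.2), {})
        assert (label, p) == ("patient", 0.9)

    def test_boundary_is_strictly_greater_than_half(self):
        label, p = combine_side_classifiers(_StubModel(0.5), _StubModel(0.5), {})
        assert (label, p) == ("control", 0.5)

    def test_trained_side_pair_detects_patients(self, base_fractions, catalog):
        from tlemorph import CohortConfig, GroupSpec, generate_cohort, normalize_by_icv

        eff_l = {"Hippocampus_L": 0.35, "Amygdala_L": 0.2}
        eff_r = catalog.mirror_effects(eff_l)
        cfg = CohortConfig(
            groups=(
                GroupSpec("TLE-HA_L", 12, 1400.0, 130.0, eff_l),
                GroupSpec("TLE-HA_R", 12, 1400.0, 130.0, eff_r),
                GroupSpec("control", 14, 1480.0, 160.0, {}),
            ),
            base_fractions=base_fractions,
            seed=17,
        )
        cohort = normalize_by_icv(generate_cohort(cfg))
        feats = ["Hippocampus_L", "Hippocampus_R", "Amygdala_L", "Amygdala_R"]
        model_l = train_posterior_model(cohort, feats, ["TLE-HA_L"], "control")
        model_r = train_posterior_model(cohort, feats, ["TLE-HA_R"], "control")
        correct = 0
        records = cohort.records()
        for rec in records:
            label, _ = combine_side_classifiers(model_l, model_r, rec.volumes)
            truth = "control" if rec.group == "control" else "patient"
            correct += label == truth
        assert correct / len(records) >= 0.8

    def test_missing_feature_errors(self, base_fractions):
        cohort = make_two_group_cohort(base_fractions, seed=19)
        model = train_posterior_model(
            cohort, ["Hippocampus_L"], ["patient_L"], "control"
        )
        with pytest.raises(KeyError, match="Hippocampus_L"):
            model.patient_posterior({"Amygdala_L": 0.001})


class TestPermutationTest:
    def test_planted_effect_is_significant(self, base_fractions):
        # a near-noise-free 50% reduction gives 100% observed LOO accuracy,
        # which no label permutation matches: p hits its floor 1/(B+1)
        cohort = make_two_group_cohort(
            base_fractions, n_patients=15, n_controls=15,
            effects={"Hippocampus_L": 0.5}, noise_cv=0.03, seed=31,
        )
        res = permutation_test(
            cohort, spec=reduced(), n_permutations=99, seed=0, D=2
        )
        assert res.observed_accuracy == 100.0
        assert res.p_value == pytest.approx(1 / 100)
        assert res.statistic > 2.0
        assert res.null_accuracies.shape == (99,)

    def test_null_effect_is_not_significant(self, null_cohort):
        res = permutation_test(
            null_cohort, spec=reduced(), n_permutations=99, seed=1, D=2
        )
        assert res.p_value > 0.05

    def test_p_value_formula_bounds(self, null_cohort):
        res = permutation_test(
            null_cohort, spec=reduced(), n_permutations=99, seed=2, D=2
        )
        assert 1 / 100 <= res.p_value <= 1.0

    def test_deterministic_given_seed(self, null_cohort):
        kw = dict(spec=reduced(), n_permutations=99, seed=3, D=2)
        r1 = permutation_test(null_cohort, **kw)
        r2 = permutation_test(null_cohort, **kw)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_accuracies, r2.null_accuracies)

    def test_too_few_permutations_rejected(self, null_cohort):
        with pytest.raises(ValueError, match="99"):
            permutation_test(null_cohort, spec=reduced(), n_permutations=50)

    def test_json_serialization(self, null_cohort):
        res = permutation_test(
            null_cohort, spec=reduced(), n_permutations=99, seed=4, D=2
        )
        assert '"p_value"' in res.to_json()
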