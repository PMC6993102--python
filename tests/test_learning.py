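"""Partitioning, metrics, grid search, iterative ranking and evaluation."""

import math

import numpy as np
import pytest

from mzmarker.exceptions import ConfigError
from mzmarker.io import normalize_rows
from mzmarker.learning import (
    ConfusionCounts,
    IterationRecord,
    RankingTrace,
    TreesFunction,
    compare_classifiers,
    compute_metrics,
    evaluate_on_test,
    grid_search_trees,
    iterate_ranking,
    majority_vote,
    make_experiments,
    select_optimal,
    split_fit_test,
    train_diagnosis_classifier,
)


class TestMetrics:
    def test_final_test_confusion_table(self):
        """The unique 18+18-patient table (17,1,14,4) in report percentages."""
        metrics = compute_metrics(ConfusionCounts(tp=17, tn=14, fp=4, fn=1))
        assert metrics.as_percent() == {
            "sensitivity": 94.4,
            "specificity": 77.8,
            "precision": 81.0,
            "f1": 87.2,
            "accuracy": 86.1,
        }

    def test_perfect_counts_give_all_hundred(self):
        metrics = compute_metrics(ConfusionCounts(10, 10, 0, 0))
        assert all(v == 100.0 for v in metrics.as_percent().values())

    def test_zero_denominator_yields_nan_sentinel(self):
        metrics = compute_metrics(ConfusionCounts(0, 5, 0, 0))
        assert math.isnan(metrics.sensitivity)
        assert math.isnan(metrics.accuracy)  # propagates, never silently 0

    def test_accuracy_is_balanced_not_raw(self):
        # raw accuracy would be (90+10)/200 = 0.5; balanced is 0.75... no:
        # Stv=90/100=0.9, Spc=10/100=0.1 -> (0.9+0.1)/2 = 0.5; use an
        # asymmetric table where the two definitions genuinely differ
        metrics = compute_metrics(ConfusionCounts(tp=90, fn=10, tn=5, fp=5))
        assert metrics.accuracy == pytest.approx((0.9 + 0.5) / 2)
        assert metrics.accuracy != pytest.approx((90 + 5) / 110)

    def test_f1_is_harmonic_mean_identity(self):
        metrics = compute_metrics(ConfusionCounts(17, 14, 4, 1))
        expected = 2 * metrics.precision * metrics.sensitivity / (
            metrics.precision + metrics.sensitivity
        )
        assert metrics.f1 == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            ConfusionCounts(-1, 0, 0, 0)


class TestPartitioning:
    PATIENTS = {f"P{i}": "case" for i in range(90)} | {
        f"C{i}": "control" for i in range(90)
    }

    def test_study_scale_split_sizes(self):
        plan = split_fit_test(self.PATIENTS, 0.2, seed=1)
        assert {len(v) for v in plan.test_patients.values()} == {18}
        assert {len(v) for v in plan.fit_patients.values()} == {72}

    def test_fractional_counts_floor_per_stratum(self):
        patients = {f"P{i}": "case" for i in range(7)} | {
            f"C{i}": "control" for i in range(7)
        }
        plan = split_fit_test(patients, 0.25, seed=0)
        assert {len(v) for v in plan.test_patients.values()} == {1}  # floor(1.75)

    def test_same_seed_reproduces_plan(self):
        assert split_fit_test(self.PATIENTS, 0.2, seed=5) == split_fit_test(
            self.PATIENTS, 0.2, seed=5
        )

    def test_experiment_sizes_match_fit_fractions(self):
        # 82 fit patients per class at 20% validation -> 65 train + 17 val
        patients = {f"P{i}": "case" for i in range(103)} | {
            f"C{i}": "control" for i in range(103)
        }
        plan = split_fit_test(patients, 0.204, seed=0)
        assert {len(v) for v in plan.fit_patients.values()} == {82}
        plan = make_experiments(plan, 10, 0.2, seed=0)
        assert len(plan.experiments) == 10
        for exp in plan.experiments:
            assert {len(v) for v in exp.train.values()} == {65}
            assert {len(v) for v in exp.val.values()} == {17}

    def test_train_and_val_unite_to_fit(self):
        plan = make_experiments(split_fit_test(self.PATIENTS, 0.2, seed=2), 3, 0.2, 0)
        for exp in plan.experiments:
            assert exp.train_patients() | exp.val_patients() == plan.all_fit()

    def test_no_leakage_asserted(self):
        plan = make_experiments(split_fit_test(self.PATIENTS, 0.2, seed=2), 2, 0.2, 0)
        plan.assert_no_leakage()
        assert not plan.all_test() & plan.all_fit()

    def test_single_experiment_allowed(self):
        plan = make_experiments(split_fit_test(self.PATIENTS, 0.2, 0), 1, 0.2, 0)
        assert len(plan.experiments) == 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ConfigError):
            split_fit_test({"a": "case", "b": "control"}, 0.2, 0)


class TestMajorityVote:
    def test_three_of_five_positive_wins(self):
        assert majority_vote(["case", "case", "case", "control", "control"]) == "case"

    def test_even_tie_goes_positive(self):
        assert majority_vote(["case", "control"]) == "case"

    def test_clear_negative(self):
        assert majority_vote(["control", "control", "case"]) == "control"


@pytest.fixture(scope="module")
def fitted_setup(small_cohort_module):
    matrix, truth = small_cohort_module
    norm = normalize_rows(matrix)
    plan = make_experiments(split_fit_test(norm.patient_class, 0.2, 3), 4, 0.25, 3)
    fit = norm.subset_patients(plan.all_fit())
    return norm, fit, plan, truth


def _separable_spec():
    from mzmarker.synthetic import DependentGroupSpec, NoiseModel, SyntheticSpec

    return SyntheticSpec(
        n_per_class=12, replicates_per_patient=3, n_channels=30,
        channel_mz_start=250, marker_channels=((5, 3.0), (17, 3.0)),
        dependent_groups=(DependentGroupSpec(22, (25, 28), (0.7, 0.4)),),
        noise_model=NoiseModel(base_peak_channels=(10,)), seed=7,
    )


@pytest.fixture(scope="module")
def small_cohort_module():
    from mzmarker.synthetic import generate_cohort

    return generate_cohort(_separable_spec())


class TestGridSearch:
    def test_single_cell_grid_selected(self, fitted_setup):
        _, fit, plan, _ = fitted_setup
        trees_fn = grid_search_trees(fit, plan, [8], [15], seed=0)
        assert trees_fn.mapping == {8: 15}
        assert trees_fn.trees_for(1) == 15 and trees_fn.trees_for(500) == 15

    def test_tie_breaks_toward_fewer_trees(self):
        import pandas as pd

        records = pd.DataFrame(
            [
                {"length": 8, "n_trees": 40, "mean_f1": 0.9, "mean_accuracy": 0.9},
                {"length": 8, "n_trees": 10, "mean_f1": 0.9, "mean_accuracy": 0.9},
            ]
        )
        best = records.sort_values(
            by=["mean_f1", "mean_accuracy", "n_trees"],
            ascending=[False, False, True], kind="mergesort",
        ).iloc[0]
        fn = TreesFunction(records=records, mapping={8: int(best["n_trees"])})
        assert fn.trees_for(8) == 10

    def test_nearest_length_mapping(self):
        import pandas as pd

        fn = TreesFunction(records=pd.DataFrame(), mapping={4: 10, 16: 50})
        assert fn.trees_for(5) == 10
        assert fn.trees_for(14) == 50
        assert fn.trees_for(10) == 10  # equidistant: smaller length wins

    def test_invalid_tree_count_rejected(self, fitted_setup):
        _, fit, plan, _ = fitted_setup
        with pytest.raises(ConfigError):
            grid_search_trees(fit, plan, [4], [0], seed=0)


class TestIterateRanking:
    def test_lengths_follow_floor_rule_to_one(self, fitted_setup):
        _, fit, plan, _ = fitted_setup
        sub = fit.select_channels([int(m) for m in fit.mz[:10]])
        trees_fn = TreesFunction.__new__(TreesFunction)
        trees_fn.records = None
        trees_fn.mapping = {10: 10}
        trace = iterate_ranking(sub, plan, trees_fn, 0.9, seed=0)
        assert [it.length for it in trace.iterations] == [10, 9, 8, 7, 6, 5, 4, 3, 2, 1]

    def test_surviving_channels_nested(self, fitted_setup):
        _, fit, plan, _ = fitted_setup
        trees_fn = grid_search_trees(fit, plan, [8], [15], seed=1)
        trace = iterate_ranking(fit, plan, trees_fn, 0.9, seed=1)
        for earlier, later in zip(trace.iterations, trace.iterations[1:]):
            assert set(later.channels) <= set(earlier.channels)

    def test_planted_markers_reach_optimal_set(self, fitted_setup):
        _, fit, plan, truth = fitted_setup
        trees_fn = grid_search_trees(fit, plan, [8], [15], seed=1)
        trace = iterate_ranking(fit, plan, trees_fn, 0.9, seed=1)
        optimal = select_optimal(trace)
        assert set(truth.marker_mz) <= set(trace.iterations[0].channels)
        assert len(set(truth.marker_mz) & set(optimal)) >= 1


class TestSelectOptimal:
    def _trace(self, pairs):
        return RankingTrace(
            iterations=tuple(
                IterationRecord(
                    length=length, n_trees=10,
                    channels=tuple(range(250, 250 + length)),
                    importance={}, metric_means={"f1": f1}, metric_rsds={},
                )
                for length, f1 in pairs
            )
        )

    def test_engineered_peak_selected(self):
        trace = self._trace([(10, 0.7), (9, 0.95), (8, 0.8), (1, 0.6)])
        assert len(select_optimal(trace)) == 9

    def test_monotone_increasing_prefers_smallest(self):
        trace = self._trace([(4, 0.7), (3, 0.8), (2, 0.9), (1, 0.95)])
        assert len(select_optimal(trace)) == 1

    def test_equal_peaks_tie_to_smaller_length(self):
        trace = self._trace([(6, 0.9), (4, 0.9), (2, 0.8)])
        assert len(select_optimal(trace)) == 4


class TestFinalClassifier:
    def test_fixed_seed_reproducible_and_training_optimism(self, fitted_setup):
        norm, fit, plan, truth = fitted_setup
        trees_fn = grid_search_trees(fit, plan, [6], [20], seed=2)
        selected = sorted(truth.marker_mz)
        clf1 = train_diagnosis_classifier(norm, plan, selected, trees_fn, seed=2)
        clf2 = train_diagnosis_classifier(norm, plan, selected, trees_fn, seed=2)
        np.testing.assert_array_equal(clf1.predict(norm), clf2.predict(norm))
        fit_metrics, _ = evaluate_on_test(
            clf1, norm,
            plan.__class__(test_patients=plan.fit_patients,
                           fit_patients=plan.test_patients),
        )
        assert fit_metrics.f1 >= 0.9  # scoring the training patients is optimistic

    def test_unseen_channel_rejected(self, fitted_setup):
        norm, fit, plan, _ = fitted_setup
        trees_fn = grid_search_trees(fit, plan, [4], [10], seed=0)
        with pytest.raises(ConfigError):
            train_diagnosis_classifier(norm, plan, [9999], trees_fn, seed=0)

    def test_majority_vote_aggregation_on_test(self, fitted_setup):
        norm, fit, plan, truth = fitted_setup
        trees_fn = grid_search_trees(fit, plan, [6], [20], seed=4)
        clf = train_diagnosis_classifier(norm, plan, sorted(truth.marker_mz), trees_fn, 4)
        metrics, counts = evaluate_on_test(clf, norm, plan, aggregation="patient")
        n_test = sum(len(v) for v in plan.test_patients.values())
        assert counts.tp + counts.tn + counts.fp + counts.fn == n_test
        vec_metrics, vec_counts = evaluate_on_test(clf, norm, plan, aggregation="vector")
        n_rows = norm.subset_patients(plan.all_test()).n_rows
        assert sum([vec_counts.tp, vec_counts.tn, vec_counts.fp, vec_counts.fn]) == n_rows


class TestCompareClassifiers:
    def test_same_learner_twice_gives_identical_rows(self, fitted_setup):
        _, fit, plan, truth = fitted_setup
        table = compare_classifiers(
            fit, plan, sorted(truth.marker_mz),
            learners=("decision_tree", "decision_tree"), seed=0,
        )
        first, second = table.drop(columns="learner").iloc[0], table.drop(columns="learner").iloc[1]
        assert first.equals(second)

    def test_separable_cohort_all_learners_strong(self):
        import dataclasses

        from mzmarker.synthetic import generate_cohort

        spec = dataclasses.replace(
            _separable_spec(), marker_channels=((5, 5.0), (17, 5.0)),
            marker_prevalence=1.0,
        )
        matrix, truth = generate_cohort(spec)
        norm = normalize_rows(matrix)
        plan = make_experiments(split_fit_test(norm.patient_class, 0.2, 0), 4, 0.25, 0)
        fit = norm.subset_patients(plan.all_fit())
        table = compare_classifiers(fit, plan, sorted(truth.marker_mz), seed=0)
        assert set(table.learner) == {
            "random_forest", "svm_smo", "svm_isda", "decision_tree"
        }
        assert (table.mean_f1 >= 0.9).all()

    def test_single_feature_table_well_formed(self, fitted_setup):
        _, fit, plan, truth = fitted_setup
        table = compare_classifiers(
            fit, plan, [sorted(truth.marker_mz)[0]],
            learners=("random_forest",), seed=0,
        )
        assert len(table) == 1 and not table.mean_f1.isna().any()

    def test_unknown_learner_rejected(self, fitted_setup):
        _, fit, plan, truth = fitted_setup
        with pytest.raises(ConfigError, match="unknown learner"):
            compare_classifiers(fit, plan, sorted(truth.marker_mz),
                                learners=("boosting",), seed=0)
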