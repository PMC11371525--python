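"""Metrics, score summaries, the outer evaluation loop, benchmarking."""

import numpy as np
import pandas as pd
import pytest

from podqsar import (
    CVSpec,
    ForestSpec,
    InvalidInputError,
    SchemaError,
    SelectionSpec,
    benchmark,
    compute_metrics,
    nested_cv,
    summarize_scores,
)
from podqsar.estimators import register_estimator


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == (0.0, 0.0, 1.0)

    def test_two_point_hand_calculation(self):
        # residuals (-1, 1): SS_res = SS_tot = 2
        m = compute_metrics([0.0, 2.0], [1.0, 1.0])
        assert m.rmse == 1.0 and m.medae == 1.0 and m.r2 == 0.0

    def test_mean_baseline_gives_r2_zero(self):
        y = np.array([1.0, 2.0, 6.0])
        m = compute_metrics(y, np.full(3, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_constant_truth_r2_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="R²"):
            m = compute_metrics([2.0, 2.0], [1.0, 3.0])
        assert np.isnan(m.r2) and m.rmse == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_metrics([1.0, 2.0], [1.0])


class TestSummarize:
    def test_identical_scores(self):
        s = summarize_scores([0.5] * 10)
        assert s["median"] == s["p5"] == s["p95"] == 0.5

    def test_median_of_1_to_100(self):
        assert summarize_scores(range(1, 101))["median"] == 50.5

    def test_three_values(self):
        assert summarize_scores([0.64, 0.76, 0.69])["median"] == 0.69

    def test_nan_excluded(self):
        s = summarize_scores([1.0, float("nan"), 3.0])
        assert s["median"] == 2.0


class TestNestedCV:
    def test_replicate_count_and_fold_coverage(self, labeled_data, fast_specs):
        table, pods = labeled_data
        forest, sel = fast_specs
        cv = CVSpec(outer_folds=3, outer_repeats=2, seed=1)
        report = nested_cv(table, pods, forest, sel, cv)
        assert len(report.replicate_scores) == 6  # 2 repeats x 3 folds
        # each chemical tested exactly once per repeat
        for repeat in (0, 1):
            tested = [c for r in report.replicates if r.repeat == repeat
                      for c in r.test_ids]
            assert sorted(tested) == sorted(pods.chemical_ids)

    def test_bitwise_reproducible_given_seed(self, labeled_data, fast_specs):
        table, pods = labeled_data
        forest, sel = fast_specs
        cv = CVSpec(outer_folds=3, outer_repeats=1, seed=9)
        a = nested_cv(table, pods, forest, sel, cv)
        b = nested_cv(table, pods, forest, sel, cv)
        assert a.replicate_scores == b.replicate_scores
        for ra, rb in zip(a.replicates, b.replicates):
            np.testing.assert_array_equal(ra.y_pred, rb.y_pred)
            assert ra.selected_features == rb.selected_features

    def test_oracle_estimator_scores_perfectly(self, labeled_data, fast_specs):
        """A plug-in that looks up the true label gets RMSE 0, R² 1."""
        table, pods = labeled_data
        forest, _ = fast_specs
        truth = {
            tuple(np.round(row, 6)): y
            for row, y in zip(table.values.to_numpy(),
                              pods.log10_pod.to_numpy())
        }

        class Oracle:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.asarray(
                    [truth[tuple(np.round(row, 6))] for row in X]
                )

        register_estimator("oracle", lambda spec, nf: Oracle())
        # oracle needs the unmasked table: use a missing-free copy
        from podqsar import FeatureTable

        clean = FeatureTable(values=table.values.copy())
        report = nested_cv(
            clean, pods, forest, None, CVSpec(2, 1, seed=0),
            estimator="oracle", feature_selection=False,
        )
        for m in report.replicate_scores:
            assert m.rmse == pytest.approx(0.0, abs=1e-9)
            assert m.r2 == pytest.approx(1.0)

    def test_label_feature_mismatch_lists_ids(self, labeled_data, fast_specs):
        table, pods = labeled_data
        forest, sel = fast_specs
        missing_chem = table.subset(table.chemical_ids[:-5])
        with pytest.raises(SchemaError, match="missing from feature table"):
            nested_cv(missing_chem, pods, forest, sel, CVSpec(2, 1))

    def test_outer_test_perturbation_leaks_nothing(self, fast_specs):
        """Perturbing a held-out chemical's features leaves its replicate's
        selection and its co-tested chemicals' predictions unchanged."""
        from podqsar import FeatureTable, simulate

        forest, sel = fast_specs
        spec = simulate.SyntheticSpec(
            n_chemicals=40, n_features=6,
            informative_features=((0, 1.0), (1, 1.0)),
            binary_features=(), missingness=0.0, seed=3,
        )
        table, pods = simulate.generate_labeled_data(spec)
        cv = CVSpec(outer_folds=2, outer_repeats=1, seed=5)
        base = nested_cv(table, pods, forest, sel, cv)

        victim = base.replicates[0].test_ids[0]
        poisoned = table.values.copy()
        poisoned.loc[victim] = 250.0
        table2 = FeatureTable(values=poisoned,
                              feature_kind=dict(table.feature_kind))
        perturbed = nested_cv(table2, pods, forest, sel, cv)

        r0, r0p = base.replicates[0], perturbed.replicates[0]
        assert r0.test_ids == r0p.test_ids
        assert r0.selected_features == r0p.selected_features
        keep = [i for i, c in enumerate(r0.test_ids) if c != victim]
        np.testing.assert_array_equal(r0.y_pred[keep], r0p.y_pred[keep])

    def test_report_frames_and_summary(self, labeled_data, fast_specs):
        table, pods = labeled_data
        forest, sel = fast_specs
        report = nested_cv(table, pods, forest, sel, CVSpec(2, 2, seed=0))
        frame = report.scores_frame()
        assert len(frame) == 4
        summ = report.summary()
        for metric in ("rmse", "medae", "r2"):
            s = summ[metric]
            assert s["p5"] <= s["median"] <= s["p95"]
        oos = report.mean_oos_prediction()
        assert sorted(oos.index) == sorted(pods.chemical_ids)


class TestBenchmark:
    def test_identical_sets(self):
        preds = {"A": 1.0, "B": 2.0, "C": 3.0}
        metrics, n = benchmark(preds, preds)
        assert metrics == (0.0, 0.0, 1.0) and n == 3

    def test_disjoint_keys_rejected(self):
        with pytest.raises(InvalidInputError):
            benchmark({"A": 1.0, "B": 2.0}, {"C": 1.0, "D": 2.0})

    def test_constant_offset_closed_form(self):
        ref = {"A": 0.0, "B": 1.0, "C": 5.0}
        shifted = {k: v + 0.7 for k, v in ref.items()}
        metrics, n = benchmark(shifted, ref)
        assert metrics.rmse == pytest.approx(0.7)
        assert metrics.medae == pytest.approx(0.7)
        assert metrics.r2 <= 1.0

    def test_intersection_only(self):
        pred = {"A": 1.0, "B": 2.0, "X": 9.0}
        ref = {"A": 1.0, "B": 2.0, "Y": -9.0}
        metrics, n = benchmark(pred, ref)
        assert n == 2 and metrics.rmse == 0.0
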