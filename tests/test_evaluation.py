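"""Metrics and cross-validation harnesses, including the leakage audit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurowalk.evaluation import (
    ConfusionCounts,
    compute_metrics,
    confusion_from_predictions,
    leave_one_site_out,
    stratified_kfold,
)
from neurowalk.pipeline import GraphEmbeddingPipeline


def fast_pipeline_factory(cache):
    """Smallest honest pipeline: full per-fold refitting, tiny budgets."""

    def factory():
        return GraphEmbeddingPipeline(
            scenario="s3",
            connectivity_kind="tangent",
            d=8,
            walks_per_node=2,
            walk_length=10,
            window=3,
            epochs_sg=1,
            cnn_epochs=2,
            cnn_patience=None,
            validation_fraction=0.0,
            seed=0,
            embedding_cache=cache,
        )

    return factory


class TestMetrics:
    def test_worked_example_all_metrics_0_8(self):
        m = compute_metrics(ConfusionCounts(TP=8, FP=2, FN=2, TN=8))
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.8)
        assert m.fscore == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.8)

    def test_perfect_prediction_all_ones(self):
        m = compute_metrics(ConfusionCounts(TP=5, FP=0, FN=0, TN=5))
        assert (m.accuracy, m.precision, m.recall, m.fscore) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominators_reported_as_undefined(self):
        m = compute_metrics(ConfusionCounts(TP=0, FP=0, FN=3, TN=7))
        assert m.precision is None
        assert m.recall == 0.0
        assert m.accuracy == pytest.approx(0.7)

    @settings(max_examples=1000, deadline=None)
    @given(
        st.integers(1, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
    )
    def test_fscore_identity_both_formulas_agree(self, tp, fp, fn, tn):
        c = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
        m = compute_metrics(c)  # internal assert compares both forms to 1e-12
        if m.precision is not None and m.recall is not None and m.precision + m.recall > 0:
            pr_form = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert abs(m.fscore - pr_form) < 1e-12

    def test_confusion_counts_from_predictions(self):
        c = confusion_from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.TP, c.FP, c.FN, c.TN) == (2, 1, 1, 1)
        assert c.total == 5


class TestKFold:
    def test_every_subject_tested_exactly_once(self, small_cohort):
        cache = {}
        res = stratified_kfold(small_cohort.subjects, fast_pipeline_factory(cache), k=4, seed=0)
        assert res.scheme == "kfold"
        assert sum(f.n_subjects for f in res.folds) == len(small_cohort.subjects)

    def test_stratification_balances_classes(self, small_cohort):
        cache = {}
        res = stratified_kfold(small_cohort.subjects, fast_pipeline_factory(cache), k=4, seed=0)
        global_ratio = 0.5
        for f in res.folds:
            assert abs(f.n_positive - global_ratio * f.n_subjects) <= 1

    def test_k_exceeding_minority_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="minority"):
            stratified_kfold(small_cohort.subjects, fast_pipeline_factory({}), k=10, seed=0)

    def test_k_exceeding_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="cohort"):
            stratified_kfold(small_cohort.subjects, fast_pipeline_factory({}), k=30, seed=0)


class TestLeaveOneSiteOut:
    def test_one_fold_per_site_and_full_coverage(self, small_cohort):
        cache = {}
        res = leave_one_site_out(small_cohort.subjects, fast_pipeline_factory(cache))
        assert res.scheme == "leave_one_site_out"
        assert sorted(f.fold_id for f in res.folds) == small_cohort.site_ids
        assert sum(f.n_subjects for f in res.folds) == len(small_cohort.subjects)

    def test_mean_accuracy_is_unweighted_site_mean(self, small_cohort):
        cache = {}
        res = leave_one_site_out(small_cohort.subjects, fast_pipeline_factory(cache))
        per_site = [f.metrics.accuracy for f in res.folds]
        assert res.mean_metrics.accuracy == pytest.approx(np.mean(per_site))

    def test_single_site_rejected(self, small_cohort):
        one_site = [s for s in small_cohort.subjects if s.site_id == "site_01"]
        with pytest.raises(ValueError, match="2 sites"):
            leave_one_site_out(one_site, fast_pipeline_factory({}))

    def test_site_missing_a_class_skipped(self):
        from neurowalk.synthetic import CohortConfig, simulate_cohort

        cohort = simulate_cohort(
            CohortConfig(n_sites=3, subjects_per_site_per_class=3, n_rois=10,
                         n_timepoints=60, n_modules=2, n_effect_edges=4, seed=8)
        )
        subs = [
            s for s in cohort.subjects if not (s.site_id == "site_02" and s.label == "ASD")
        ]
        res = leave_one_site_out(subs, fast_pipeline_factory({}))
        assert [f.fold_id for f in res.folds] == ["site_01", "site_03"]


class TestLeakageAudit:
    def test_fitted_statistics_touch_training_subjects_only(self, small_cohort):
        cache = {}
        for res in (
            leave_one_site_out(small_cohort.subjects, fast_pipeline_factory(cache)),
            stratified_kfold(small_cohort.subjects, fast_pipeline_factory(cache), k=2, seed=1),
        ):
            assert res.leakage_audit, "audit must record fitted statistics"
            stats_seen = {name for _, name, _, _ in res.leakage_audit}
            assert {"connectivity_reference", "graph2img_bounds", "channel_scaler"} <= stats_seen
            for fold_id, name, fit_ids, test_ids in res.leakage_audit:
                assert not (fit_ids & test_ids), f"{name} leaked into fold {fold_id}"

    def test_kfold_deterministic_under_seed(self, small_cohort):
        a = stratified_kfold(small_cohort.subjects, fast_pipeline_factory({}), k=2, seed=7)
        b = stratified_kfold(small_cohort.subjects, fast_pipeline_factory({}), k=2, seed=7)
        for fa, fb in zip(a.folds, b.folds):
            assert (fa.counts.TP, fa.counts.FP, fa.counts.FN, fa.counts.TN) == (
                fb.counts.TP,
                fb.counts.FP,
                fb.counts.FN,
                fb.counts.TN,
            )
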