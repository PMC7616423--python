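"""Metrics identities, stratified splits, voting and protocol bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import confusion_matrix

from iedgan.data import SegmentSet
from iedgan.detector import DetectorConfig
from iedgan.errors import EmptySelectionError, InvalidInputError, ShapeError
from iedgan.evaluation import (MetricsReport, average_vote, compute_metrics,
                               mean_report, run_inter_subject, run_intra_subject,
                               segment_correlation, select_training_subjects,
                               split_intra)
from iedgan.preprocessing import preprocess_paired
from iedgan.synthesis import SynthesisConfig, make_cohort
from iedgan.translator import TranslatorConfig


class TestComputeMetrics:
    def test_worked_example(self):
        labels = [1] * 100 + [0] * 100
        preds = [1] * 65 + [0] * 35 + [0] * 70 + [1] * 30
        r = compute_metrics(labels, preds)
        assert (r.tp, r.fn, r.tn, r.fp) == (65, 35, 70, 30)
        assert (r.sen, r.spc, r.acc) == (0.65, 0.70, 0.675)

    def test_perfect_and_degenerate_classifiers(self):
        labels = np.array([0, 1, 0, 1])
        perfect = compute_metrics(labels, labels)
        assert perfect.acc == perfect.sen == perfect.spc == 1.0
        allpos = compute_metrics(labels, np.ones(4))
        assert (allpos.sen, allpos.spc, allpos.acc) == (1.0, 0.0, 0.5)

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None)
    def test_matches_sklearn_confusion_matrix(self, pairs):
        labels = np.array([p[0] for p in pairs])
        preds = np.array([p[1] for p in pairs])
        r = compute_metrics(labels, preds)
        tn, fp, fn, tp = confusion_matrix(labels, preds, labels=[0, 1]).ravel()
        assert (r.tp, r.tn, r.fp, r.fn) == (tp, tn, fp, fn)
        assert r.acc == pytest.approx((tp + tn) / len(pairs))

    def test_balanced_test_set_identity(self):
        """With balanced labels, ACC is exactly the mean of SEN and SPC."""
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 50)
        preds = rng.integers(0, 2, 100)
        r = compute_metrics(labels, preds)
        assert r.acc == pytest.approx((r.sen + r.spc) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            compute_metrics([], [])
        with pytest.raises(InvalidInputError):
            compute_metrics([1, 0], [1])


class TestSplitIntra:
    def test_sizes_70_10_20(self, rng):
        from iedgan.data import Segment
        segs = SegmentSet([Segment(rng.standard_normal((64, 12)), None, i % 2, "S1")
                           for i in range(100)])
        tr, va, te = split_intra(segs, seed=0)
        assert (len(tr), len(va), len(te)) == (70, 10, 20)

    def test_partition_property(self, tiny_segments):
        tr, va, te = split_intra(tiny_segments, seed=1)
        assert len(tr) + len(va) + len(te) == len(tiny_segments)
        ids = [id(s) for part in (tr, va, te) for s in part]
        assert len(set(ids)) == len(ids)
        assert set(ids) == {id(s) for s in tiny_segments}

    def test_stratification(self, tiny_segments):
        for part in split_intra(tiny_segments[:100], seed=2):
            labels = part.labels
            assert (labels == 1).any() and (labels == 0).any()

    def test_too_few_segments(self, tiny_segments):
        with pytest.raises(InvalidInputError):
            split_intra(tiny_segments[:4], fractions=(0.7, 0.1, 0.2), seed=0)

    def test_bad_fractions(self, tiny_segments):
        with pytest.raises(InvalidInputError):
            split_intra(tiny_segments, fractions=(0.5, 0.2, 0.2), seed=0)


class TestSelectionAndVoting:
    def _reports(self, accs):
        return [MetricsReport(f"S{i+1}", 1, 1, 1, 1, a, a, a)
                for i, a in enumerate(accs)]

    def test_threshold_selection(self):
        ids = select_training_subjects(self._reports([0.78, 0.95, 0.59]), 0.70)
        assert ids == ["S1", "S2"]

    def test_zero_threshold_selects_all(self):
        assert len(select_training_subjects(self._reports([0.1, 0.2]), 0.0)) == 2

    def test_unreachable_threshold_raises(self):
        with pytest.raises(EmptySelectionError):
            select_training_subjects(self._reports([0.9]), 1.01)

    def test_average_vote_examples(self):
        np.testing.assert_allclose(average_vote([[0.2, 0.6], [0.4, 0.8]]), [0.3, 0.7])
        np.testing.assert_allclose(average_vote([[0.1, 0.9]]), [0.1, 0.9])

    def test_vote_convexity(self, rng):
        rows = rng.uniform(0, 1, size=(5, 20))
        v = average_vote(rows)
        assert (v >= rows.min(axis=0)).all() and (v <= rows.max(axis=0)).all()

    def test_ragged_rows_rejected(self):
        with pytest.raises(ShapeError):
            average_vote([[0.1, 0.2], [0.3]])


class TestSegmentCorrelation:
    def test_perfect_and_anti_correlation(self, rng):
        a = rng.standard_normal((4, 64, 12))
        assert segment_correlation(a, 2 * a + 1) == pytest.approx(1.0)
        assert segment_correlation(a, -a) == pytest.approx(-1.0)


@pytest.fixture(scope="module")
def micro_cohort():
    """Three fast subjects for protocol bookkeeping checks."""
    cfg = SynthesisConfig(n_subjects=3, duration_s=70.0, n_ieds_per_subject=30,
                          visibility_fraction=0.3, seed=42)
    return [preprocess_paired(p) for p in make_cohort(cfg)]


_FAST_T = TranslatorConfig(n_epochs=2)
_FAST_D = DetectorConfig(n_epochs=2)


class TestProtocols:
    def test_intra_subject_determinism_and_report_shape(self, micro_cohort):
        a = run_intra_subject(micro_cohort[0], _FAST_T, _FAST_D, seed=3)
        b = run_intra_subject(micro_cohort[0], _FAST_T, _FAST_D, seed=3)
        assert a == b
        assert a.subject_id == "S1"
        assert a.tp + a.tn + a.fp + a.fn == 12      # 20% of 60 balanced segments

    def test_easy_regime_high_accuracy(self):
        """Noise-free, fully scalp-visible recordings are classified near-perfectly."""
        cfg = SynthesisConfig(n_subjects=1, duration_s=150.0, n_ieds_per_subject=60,
                              visibility_fraction=1.0, noise_scale=0.02, seed=9)
        rec = preprocess_paired(make_cohort(cfg)[0])
        rep = run_intra_subject(rec, TranslatorConfig(n_epochs=20),
                                DetectorConfig(n_epochs=25), seed=1)
        assert rep.acc >= 0.9

    def test_loso_bookkeeping(self, micro_cohort):
        reports, details = run_inter_subject(micro_cohort, _FAST_T, _FAST_D,
                                             threshold=0.0, seed=5,
                                             return_details=True)
        assert [r.subject_id for r in reports] == ["S1", "S2", "S3"]
        for fold in details["folds"]:
            assert fold["n_models"] == 2
            assert fold["test_subject"] not in fold["training_subjects"]
            ensemble = average_vote(fold["probability_rows"])
            lo = np.min(fold["probability_rows"], axis=0)
            hi = np.max(fold["probability_rows"], axis=0)
            assert ((ensemble >= lo) & (ensemble <= hi)).all()

    def test_loso_needs_three_subjects(self, micro_cohort):
        with pytest.raises(InvalidInputError):
            run_inter_subject(micro_cohort[:2], _FAST_T, _FAST_D, seed=0)

    def test_mean_report_is_unweighted_mean(self):
        reports = [MetricsReport("S1", 1, 1, 0, 0, 1.0, 1.0, 1.0),
                   MetricsReport("S2", 0, 0, 1, 1, 0.0, 0.0, 0.0)]
        m = mean_report(reports)
        assert m.acc == 0.5 and m.subject_id == "Mean"
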