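"""Statistics tests: confusion matrices, binary collapse metrics with
undefined-denominator semantics, Cohen's kappa against independent oracles,
and the summary-statistics t-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ttest_ind_from_stats
from sklearn.metrics import cohen_kappa_score

from hpagrade.stats import (
    UNDEFINED,
    ConfusionMatrix,
    DurationSummary,
    binary_metrics,
    cohen_kappa,
    confusion_matrix,
    format_report,
    pooled_t,
    read_durations,
    read_label_manifest,
    validation_report,
    welch_t,
)


class TestConfusionMatrix:
    def test_agreeing_lists_give_diagonal(self):
        cm = confusion_matrix(["mild", "severe", "mild"], ["mild", "severe", "mild"])
        assert cm.is_diagonal()
        assert cm.total == 3
        assert cm.accuracy() == 1.0

    def test_direct_counts(self):
        cm = confusion_matrix(["m", "m", "s"], ["m", "s", "s"], classes=("m", "s"))
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["mild"], ["mild", "severe"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["mild"], ["banana"])

    def test_row_sums_are_truth_counts(self):
        rng = np.random.default_rng(0)
        classes = ("none", "mild", "moderate", "severe")
        truth = [classes[i] for i in rng.integers(0, 4, size=100)]
        pred = [classes[i] for i in rng.integers(0, 4, size=100)]
        cm = confusion_matrix(truth, pred, classes)
        for i, c in enumerate(classes):
            assert cm.counts[i].sum() == truth.count(c)


class TestBinaryMetrics:
    def test_hand_worked_2x2(self):
        # TP=5, FN=2, FP=1, TN=10
        cm = ConfusionMatrix(("neg", "pos"), np.array([[10, 1], [2, 5]]))
        m = binary_metrics(cm, ["pos"])
        assert m.sensitivity == pytest.approx(5 / 7)
        assert m.specificity == pytest.approx(10 / 11)
        assert m.f1 == pytest.approx(10 / 13)
        assert m.accuracy == pytest.approx(15 / 18)

    def test_perfect_diagonal_is_all_ones(self):
        cm = ConfusionMatrix(
            ("none", "mild", "moderate", "severe"), np.diag([2, 3, 4, 5])
        )
        m = binary_metrics(cm, ["severe"])
        assert (m.sensitivity, m.specificity, m.accuracy, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_no_negatives_makes_specificity_undefined(self):
        # every field has a defect: no true negatives and no false positives
        cm = ConfusionMatrix(
            ("none", "mild", "moderate", "severe"),
            np.diag([0, 10, 5, 5]),
        )
        m = binary_metrics(cm, ["mild", "moderate", "severe"])
        assert m.specificity is UNDEFINED
        assert m.sensitivity == 1.0
        assert m.tn == 0 and m.fp == 0

    def test_no_positives_makes_sensitivity_and_f1_undefined(self):
        cm = ConfusionMatrix(("none", "severe"), np.array([[7, 0], [0, 0]]))
        m = binary_metrics(cm, ["severe"])
        assert m.sensitivity is UNDEFINED
        assert m.f1 is UNDEFINED
        assert m.specificity == 1.0

    def test_positive_set_must_be_proper_subset(self):
        cm = ConfusionMatrix(("a", "b"), np.eye(2, dtype=int))
        with pytest.raises(ValueError):
            binary_metrics(cm, ["a", "b"])
        with pytest.raises(ValueError):
            binary_metrics(cm, [])

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_collapse_agrees_with_raw_recount(self, pairs):
        classes = ("none", "mild", "moderate", "severe")
        truth = [classes[t] for t, _ in pairs]
        pred = [classes[p] for _, p in pairs]
        cm = confusion_matrix(truth, pred, classes)
        m = binary_metrics(cm, ["severe"])
        tp = sum(t == "severe" and p == "severe" for t, p in zip(truth, pred))
        fn = sum(t == "severe" and p != "severe" for t, p in zip(truth, pred))
        fp = sum(t != "severe" and p == "severe" for t, p in zip(truth, pred))
        tn = sum(t != "severe" and p != "severe" for t, p in zip(truth, pred))
        assert (m.tp, m.fn, m.fp, m.tn) == (tp, fn, fp, tn)
        assert m.tp + m.fp + m.fn + m.tn == len(pairs)


class TestCohenKappa:
    def test_diagonal_is_one(self):
        cm = ConfusionMatrix(("a", "b", "c"), np.diag([3, 5, 2]))
        assert cohen_kappa(cm) == pytest.approx(1.0)

    def test_chance_level_is_zero(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[25, 25], [25, 25]]))
        assert cohen_kappa(cm) == pytest.approx(0.0)

    def test_hand_worked_value(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[45, 5], [5, 45]]))
        assert cohen_kappa(cm) == pytest.approx(0.80, abs=1e-12)

    def test_single_class_degenerate_is_undefined(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[10, 0], [0, 0]]))
        assert cohen_kappa(cm) is UNDEFINED

    def test_one_iff_diagonal(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            counts = rng.integers(0, 6, size=(3, 3))
            if counts.sum() == 0 or counts.sum(axis=1).astype(bool).sum() < 2:
                continue
            cm = ConfusionMatrix(("a", "b", "c"), counts)
            k = cohen_kappa(cm)
            if k is UNDEFINED:
                continue
            assert (k == pytest.approx(1.0)) == cm.is_diagonal()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 9, size=(4, 4))
        cm = ConfusionMatrix(("a", "b", "c", "d"), counts)
        perm = rng.permutation(4)
        cm_p = ConfusionMatrix(tuple("abcd"[i] for i in perm), counts[np.ix_(perm, perm)])
        assert cohen_kappa(cm_p) == pytest.approx(cohen_kappa(cm))

    def test_agrees_with_sklearn_on_random_labels(self):
        rng = np.random.default_rng(5)
        classes = ("none", "mild", "moderate", "severe")
        for _ in range(100):
            n = int(rng.integers(4, 40))
            truth = rng.integers(0, 4, size=n)
            pred = rng.integers(0, 4, size=n)
            cm = confusion_matrix([classes[i] for i in truth], [classes[i] for i in pred], classes)
            ours = cohen_kappa(cm)
            theirs = cohen_kappa_score(truth, pred, labels=range(4))
            if math.isnan(theirs):
                assert ours is UNDEFINED
            else:
                assert ours == pytest.approx(theirs, abs=1e-12)


class TestDurationTTests:
    def test_welch_matches_scipy_over_grid(self):
        for ma, sa, na, mb, sb, nb in [
            (26.5, 3.3, 20, 48.6, 28.4, 20),
            (10.0, 1.0, 5, 12.0, 4.0, 9),
            (0.0, 2.0, 30, 0.5, 2.0, 30),
            (100.0, 10.0, 4, 90.0, 30.0, 12),
        ]:
            ours = welch_t(DurationSummary(ma, sa, na), DurationSummary(mb, sb, nb))
            ref = ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pooled_matches_scipy(self):
        ours = pooled_t(DurationSummary(26.5, 3.3, 20), DurationSummary(48.6, 28.4, 20))
        ref = ttest_ind_from_stats(26.5, 3.3, 20, 48.6, 28.4, 20, equal_var=True)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.df == 38

    def test_equal_n_equal_sd_welch_reduces_to_pooled(self):
        for m_a, m_b, sd, n in [(5.0, 7.0, 2.0, 10), (1.0, 0.0, 0.5, 25)]:
            w = welch_t(DurationSummary(m_a, sd, n), DurationSummary(m_b, sd, n))
            p = pooled_t(DurationSummary(m_a, sd, n), DurationSummary(m_b, sd, n))
            assert w.t == pytest.approx(p.t, rel=1e-12)
            assert w.df == pytest.approx(p.df, rel=1e-12)

    def test_identical_summaries_give_zero(self):
        s = DurationSummary(30.0, 5.0, 12)
        assert welch_t(s, s).t == pytest.approx(0.0)

    def test_degenerate_zero_variance_is_undefined(self):
        s = DurationSummary(30.0, 0.0, 12)
        assert welch_t(s, s).t is UNDEFINED

    def test_summary_validation(self):
        with pytest.raises(ValueError):
            DurationSummary(10.0, -1.0, 5)
        with pytest.raises(ValueError):
            DurationSummary(10.0, 1.0, 1)


class TestReports:
    def test_report_structure_and_text(self):
        truth = ["mild", "moderate", "severe", "severe"]
        rep = validation_report(truth, truth)
        assert rep["kappa"] == pytest.approx(1.0)
        assert rep["any_defect"]["specificity"] == "undefined"
        assert rep["severe_defect"]["f1"] == 1.0
        text = format_report(rep)
        assert "kappa = 1.00" in text
        assert "specificity undefined" in text

    def test_duration_csv_round_trip(self, tmp_path):
        path = tmp_path / "durations.csv"
        rng = np.random.default_rng(9)
        rows = ["record_id,method,seconds"]
        for i in range(20):
            rows.append(f"r{i},auto,{26.5 + rng.normal(0, 3.3):.2f}")
            rows.append(f"r{i},manual,{48.6 + rng.normal(0, 20.0):.2f}")
        path.write_text("\n".join(rows) + "\n")
        durations = read_durations(path)
        assert set(durations) == {"auto", "manual"}
        assert durations["auto"].n == 20
        rep = validation_report(["mild"] * 4, ["mild"] * 3 + ["severe"], durations=durations)
        assert rep["durations"]["welch"]["t"] < 0

    def test_label_manifest_validation(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("record_id,foo\nr0,x\n")
        with pytest.raises(ValueError):
            read_label_manifest(bad)
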