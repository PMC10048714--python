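"""Confusion-matrix metrics: enumeration oracles, published reconstructions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pearfuse.metrics import (
    ConfusionMatrix2x2, WORKED_EXAMPLES, compute_metrics,
    confusion_from_predictions, reconstruct_worked_examples, round_half_up,
)


def brute_force_metrics(y_true, y_pred):
    """Independent per-sample enumeration oracle for the macro metrics."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    acc = np.mean(y_true == y_pred)
    ps, rs, fs = [], [], []
    for cls in (0, 1):
        tp = np.sum((y_true == cls) & (y_pred == cls))
        fp = np.sum((y_true != cls) & (y_pred == cls))
        fn = np.sum((y_true == cls) & (y_pred != cls))
        p = tp / (tp + fp) if tp + fp else (1.0 if tp + fn == 0 else 0.0)
        r = tp / (tp + fn) if tp + fn else 1.0
        f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        ps.append(p); rs.append(r); fs.append(f)
    return acc, np.mean(ps), np.mean(rs), np.mean(fs)


class TestConfusionFromPredictions:
    @pytest.mark.parametrize(
        "truth, pred, expected",
        [
            (list("DDHH"), list("DDHH"), (2, 2, 0, 0)),   # all correct
            (list("DDHH"), list("DHDH"), (1, 1, 1, 1)),   # enumeration example
            (list("DDHH"), list("HHDD"), (0, 0, 2, 2)),   # complement of truth
        ],
    )
    def test_enumeration(self, truth, pred, expected):
        c = confusion_from_predictions(truth, pred, positive_label="D")
        assert (c.tp, c.tn, c.fp, c.fn) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            confusion_from_predictions([0, 1], [0, 1, 1], 1)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_from_predictions([0, 1, 2], [0, 1, 2], 1)


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts, acc, prec",
        [
            # published error counts of the four optimal models (72+72 set)
            ((50, 38, 34, 22), 0.611, 0.614),   # spectral network, 90 hidden
            ((72, 49, 23, 0), 0.840, 0.879),    # image-only best backbone
            ((69, 63, 9, 3), 0.917, 0.920),     # fused, deepest residual tap
            ((65, 72, 0, 7), 0.951, 0.956),     # fused, separable-conv exit
            ((72, 72, 0, 0), 1.0, 1.0),         # perfect matrix
        ],
    )
    def test_published_counts_reproduce_metrics(self, counts, acc, prec):
        tp, tn, fp, fn = counts
        rep = compute_metrics(ConfusionMatrix2x2(tp=tp, tn=tn, fp=fp, fn=fn))
        assert rep.rounded(3)["accuracy"] == pytest.approx(acc, abs=5e-4)
        assert rep.rounded(3)["precision"] == pytest.approx(prec, abs=5e-4)

    def test_spectral_model_full_row(self):
        rep = compute_metrics(ConfusionMatrix2x2(tp=50, tn=38, fp=34, fn=22))
        assert rep.rounded(3) == {"accuracy": 0.611, "precision": 0.614,
                                  "recall": 0.611, "f1": 0.608}

    def test_zero_predicted_positives_convention(self):
        rep = compute_metrics(ConfusionMatrix2x2(tp=0, tn=5, fp=0, fn=5))
        assert rep.per_class["diseased"]["precision"] == 0.0
        assert rep.per_class["not-diseased"]["recall"] == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-negative|empty"):
            ConfusionMatrix2x2(tp=0, tn=0, fp=0, fn=0)

    def test_weighted_equals_macro_on_balanced(self):
        c = ConfusionMatrix2x2(tp=60, tn=50, fp=22, fn=12)
        macro = compute_metrics(c, "macro")
        weighted = compute_metrics(c, "weighted")
        assert macro.precision_macro == pytest.approx(weighted.precision_macro)

    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200),
           st.integers(1, 200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_positive_label_swap_invariance(self, tp, tn, fp, fn):
        c = ConfusionMatrix2x2(tp=tp, tn=tn, fp=fp, fn=fn)
        a, b = compute_metrics(c), compute_metrics(c.swapped())
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.precision_macro == pytest.approx(b.precision_macro)
        assert a.recall_macro == pytest.approx(b.recall_macro)
        assert a.f1_macro == pytest.approx(b.f1_macro)

    @given(st.integers(0, 72), st.integers(0, 72), st.integers(1, 72))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_balanced_set_identity(self, err_pos, err_neg, n_side):
        """Equal class totals force accuracy == macro recall exactly."""
        err_pos, err_neg = err_pos % n_side, err_neg % n_side
        c = ConfusionMatrix2x2(tp=n_side - err_pos, tn=n_side - err_neg,
                               fp=err_neg, fn=err_pos)
        rep = compute_metrics(c)
        assert rep.accuracy == pytest.approx(rep.recall_macro, abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=50))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, pairs):
        y_true = [a for a, _ in pairs]
        y_pred = [b for _, b in pairs]
        c = confusion_from_predictions(y_true, y_pred, 1)
        rep = compute_metrics(c)
        acc, p, r, f = brute_force_metrics(y_true, y_pred)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.precision_macro == pytest.approx(p)
        assert rep.recall_macro == pytest.approx(r)
        assert rep.f1_macro == pytest.approx(f)

    def test_matches_sklearn_macro(self):
        """Cross-check against scikit-learn on random label vectors."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(4, 60)
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            if len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2:
                continue
            rep = compute_metrics(confusion_from_predictions(y_true, y_pred, 1))
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="macro", zero_division=0)
            assert rep.precision_macro == pytest.approx(p)
            assert rep.recall_macro == pytest.approx(r)
            assert rep.f1_macro == pytest.approx(f)


class TestWorkedExamples:
    def test_reconstruction_matches_printed_accuracy(self):
        df = reconstruct_worked_examples()
        assert len(df) == len(WORKED_EXAMPLES) == 4
        assert np.allclose(df["accuracy_reconstructed"],
                           df["accuracy_printed"], atol=5e-4)
        assert np.allclose(df["precision_reconstructed"],
                           df["precision_printed"], atol=5e-4)

    def test_known_recall_discrepancy_is_flagged_not_matched(self):
        df = reconstruct_worked_examples().set_index("model")
        row = df.loc["MLP_30_ResNet101_layer5"]
        assert row["recall_reconstructed"] == pytest.approx(0.917, abs=5e-4)
        assert row["recall_printed"] == pytest.approx(0.951, abs=5e-4)
        assert row["recall_abs_dev"] > 0.03
        # every other row is fully consistent
        others = df.drop("MLP_30_ResNet101_layer5")
        for metric in ("accuracy", "precision", "recall", "f1"):
            assert np.allclose(others[f"{metric}_reconstructed"],
                               others[f"{metric}_printed"], atol=5e-4)


def test_round_half_up_ties():
    assert round_half_up(0.6115, 3) == 0.612
    assert round_half_up(0.6114, 3) == 0.611
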