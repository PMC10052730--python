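import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmopt.metrics import (
    ConfusionCounts,
    binary_metrics,
    confusion_counts,
    macro_report,
)

counts_strategy = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 50),
    tn=st.integers(0, 50),
    fp=st.integers(0, 50),
    fn=st.integers(0, 50),
)


def brute_force_metrics(y_true, y_pred, positive):
    """Metrics recomputed by direct enumeration of the sample pairs."""
    pairs = list(zip(y_true, y_pred))
    tp = sum(t == positive and p == positive for t, p in pairs)
    tn = sum(t != positive and p != positive for t, p in pairs)
    fp = sum(t != positive and p == positive for t, p in pairs)
    fn = sum(t == positive and p != positive for t, p in pairs)

    def ratio(a, b):
        return None if b == 0 else a / b

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, len(pairs)),
        "precision": ratio(tp, tp + fp),
        "prevalence": ratio(tp + fn, len(pairs)),
        "npv": ratio(tn, tn + fn),
        "ppv": ratio(tp, tp + fp),
    }


class TestConfusionCounts:
    def test_all_correct(self):
        y = np.array(["a"] * 4 + ["b"] * 6)
        c = confusion_counts(y, y, "a")
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 6, 0, 0)

    def test_enumerated_mixed_case(self):
        y_true = ["+", "+", "-", "-"]
        y_pred = ["+", "-", "+", "-"]
        c = confusion_counts(y_true, y_pred, "+")
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_counts_sum_to_n(self, rng):
        y_true = rng.integers(3, size=40)
        y_pred = rng.integers(3, size=40)
        c = confusion_counts(y_true, y_pred, 1)
        assert c.total == 40

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion_counts([1, 2], [1], 1)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestBinaryMetrics:
    def test_perfect_classifier_all_ones(self):
        c = ConfusionCounts(tp=5, tn=5, fp=0, fn=0)
        for convention in ("canonical", "as_printed"):
            r = binary_metrics(c, convention)
            for name in ("sensitivity", "specificity", "accuracy", "precision", "npv"):
                assert getattr(r, name) == pytest.approx(1.0)

    def test_hand_values_canonical(self):
        r = binary_metrics(ConfusionCounts(tp=50, tn=40, fp=5, fn=5))
        assert r.accuracy == pytest.approx(0.90)
        assert r.sensitivity == pytest.approx(50 / 55)
        assert r.precision == pytest.approx(50 / 55)
        assert r.specificity == pytest.approx(40 / 45)
        assert r.npv == pytest.approx(40 / 45)
        assert r.prevalence == pytest.approx(55 / 100)

    def test_printed_convention_deviates_exactly_where_expected(self):
        c = ConfusionCounts(tp=50, tn=40, fp=5, fn=10)
        canon = binary_metrics(c, "canonical")
        printed = binary_metrics(c, "as_printed")
        # shared formulas agree
        assert canon.sensitivity == printed.sensitivity
        assert canon.accuracy == printed.accuracy
        assert canon.precision == printed.precision
        # the printed specificity divides by TN+FN instead of TN+FP
        assert printed.specificity == pytest.approx(40 / 50)
        assert canon.specificity == pytest.approx(40 / 45)
        # the printed prevalence duplicates the accuracy ratio
        assert printed.prevalence == printed.accuracy
        assert canon.prevalence == pytest.approx(60 / 105)
        # the printed NPV divides by TN+FP instead of TN+FN
        assert printed.npv == pytest.approx(40 / 45)
        assert canon.npv == pytest.approx(40 / 50)

    def test_zero_denominator_marked_undefined(self):
        r = binary_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert r.precision is None
        assert r.ppv is None
        assert r.sensitivity is None  # no actual positives either

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(c=counts_strategy)
    def test_sensitivity_specificity_duality(self, c):
        # canonical specificity equals sensitivity with roles swapped
        direct = binary_metrics(c, "canonical").specificity
        swapped = binary_metrics(c.swapped_roles(), "canonical").sensitivity
        assert direct == swapped

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 50))
    def test_formulas_equal_brute_force(self, seed, n):
        gen = np.random.default_rng(seed)
        y_true = gen.integers(2, size=n)
        y_pred = gen.integers(2, size=n)
        r = binary_metrics(confusion_counts(y_true, y_pred, 1), "canonical")
        expected = brute_force_metrics(y_true, y_pred, 1)
        for name, val in expected.items():
            assert getattr(r, name) == val


class TestMacroReport:
    def test_perfect_multiclass_all_ones(self):
        y = np.array(["a", "b", "c", "d"] * 5)
        rep = macro_report(y, y, ["a", "b", "c", "d"])
        for name in ("sensitivity", "specificity", "accuracy", "precision", "npv"):
            assert getattr(rep["macro"], name) == pytest.approx(1.0)

    def test_two_class_macro_identity(self, rng):
        # with two classes, macro sensitivity equals the mean of class-1
        # sensitivity and class-1 specificity (the other class's recall)
        y_true = rng.integers(2, size=60)
        y_pred = rng.integers(2, size=60)
        rep = macro_report(y_true, y_pred, [0, 1])
        r1 = binary_metrics(confusion_counts(y_true, y_pred, 1))
        expected = (r1.sensitivity + r1.specificity) / 2
        assert rep["macro"].sensitivity == pytest.approx(expected)

    def test_macro_invariant_to_class_order(self, rng):
        y_true = rng.integers(3, size=50)
        y_pred = rng.integers(3, size=50)
        a = macro_report(y_true, y_pred, [0, 1, 2])["macro"]
        b = macro_report(y_true, y_pred, [2, 0, 1])["macro"]
        for name in ("sensitivity", "specificity", "accuracy", "precision",
                     "prevalence", "npv", "ppv"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            macro_report([0, 1], [0, 9], [0, 1])
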