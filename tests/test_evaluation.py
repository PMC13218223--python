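import itertools

import numpy as np
import pandas as pd
import pytest

from mtslm import (
    DataError,
    classification_metrics,
    compare_models,
    train_test_split,
    vif,
)
from conftest import make_fit


def _printed_fit(deviance, q, n=500):
    fit = make_fit(np.zeros(q), n_obs=n)
    fit.log_likelihood = -deviance / 2
    return fit


class TestSplit:
    def test_counts_and_partition(self):
        df = pd.DataFrame({"a": np.arange(100.0)})
        y = np.repeat([0, 1], 50)
        tr, te, ytr, yte = train_test_split(df, y, fraction=0.8, seed=1)
        assert len(tr) == 80 and len(te) == 20
        assert sorted(tr.index.tolist() + te.index.tolist()) == list(range(100))

    def test_determinism(self):
        df = pd.DataFrame({"a": np.arange(50.0)})
        y = np.tile([0, 1], 25)
        first = train_test_split(df, y, seed=7)
        second = train_test_split(df, y, seed=7)
        assert first[0].index.tolist() == second[0].index.tolist()

    def test_stratification_preserves_mix(self):
        y = np.repeat([1, 0], [60, 40])
        df = pd.DataFrame({"a": np.arange(100.0)})
        _, _, _, yte = train_test_split(df, y, fraction=0.8, seed=0, stratified=True)
        assert abs(yte.sum() - 12) <= 1  # 60% of 20 test rows

    def test_tiny_stratum_errors(self):
        df = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(DataError):
            train_test_split(df, np.array([1, 0, 0, 0, 0]), seed=0)


class TestClassificationMetrics:
    def test_confusion_counting(self):
        # TP=3, FN=1, TN=2, FP=2 at cutoff 0.5
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        probs = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.3, 0.6, 0.7])
        rep = classification_metrics(probs, y, cutoff=0.5)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (3, 1, 2, 2)
        assert rep.accuracy == pytest.approx(0.625)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.5)
        assert rep.f1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)
        assert rep.tp + rep.fp + rep.tn + rep.fn == y.size

    def test_perfect_separation_auc(self):
        y = np.array([0, 0, 1, 1], dtype=float)
        assert classification_metrics([0.1, 0.2, 0.8, 0.9], y).auc == 1.0

    def test_constant_probs_auc_half(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        assert classification_metrics([0.4] * 4, y).auc == pytest.approx(0.5)

    def test_tie_at_cutoff_maps_to_one(self):
        rep = classification_metrics([0.5, 0.5], np.array([1.0, 0.0]), cutoff=0.5)
        assert (rep.tp, rep.fp) == (1, 1)

    def test_single_class_errors(self):
        with pytest.raises(DataError):
            classification_metrics([0.5, 0.6], np.array([1.0, 1.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_exhaustive_pair_oracle(self, seed):
        """Midrank AUC == concordant-pair proportion (ties count 1/2)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 50)
        probs = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        y = rng.integers(0, 2, size=n).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        rep = classification_metrics(probs, y)
        pairs = [
            0.5 if pp == pn else float(pp > pn)
            for pp, pn in itertools.product(probs[y == 1], probs[y == 0])
        ]
        assert rep.auc == pytest.approx(np.mean(pairs), abs=1e-12)


class TestVIF:
    def test_independent_predictors_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
        assert (vif(df) < 1.01).all()
        assert (vif(df) >= 1.0).all()

    def test_duplicate_column_flags_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        assert np.isinf(vif(df)[["a", "b"]]).all()

    def test_known_correlation_closed_form(self):
        # corr(a,b)=0.8 and independent c: population VIF_a = 1/(1-0.64)
        rng = np.random.default_rng(2)
        n = 40000
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        df = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=n)})
        v = vif(df)
        assert v["a"] == pytest.approx(1 / (1 - 0.64), rel=0.05)
        assert v["c"] == pytest.approx(1.0, abs=0.01)


class TestCompareModels:
    @pytest.mark.parametrize(
        "dev_spline, q_spline, dev_plain, q_plain",
        [(117.2145, 15, 176.6742, 4), (321.637, 12, 341.119, 5)],
    )
    def test_spline_wins_published_comparisons(self, dev_spline, q_spline,
                                               dev_plain, q_plain):
        table = compare_models(_printed_fit(dev_spline, q_spline),
                               _printed_fit(dev_plain, q_plain))
        assert table.attrs["winner"] == "mtslm"
        aic = dict(zip(table["model"], table["aic"]))
        assert aic["mtslm"] == pytest.approx(dev_spline + 2 * q_spline)
        assert aic["binary_logistic"] == pytest.approx(dev_plain + 2 * q_plain)

    def test_identical_fits_tie(self):
        assert compare_models(_printed_fit(100, 3), _printed_fit(100, 3)).attrs[
            "winner"] is None

    def test_mismatched_n_errors(self):
        with pytest.raises(DataError):
            compare_models(_printed_fit(100, 3, n=10), _printed_fit(100, 3, n=20))
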