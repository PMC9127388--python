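"""Random-forest stage: Gini, metric suite, OOB tuning, factor selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from plaquefatigue.forest import (
    ConfusionMatrix,
    ProgressionForestClassifier,
    RFConfig,
    classification_metrics,
    gini_impurity,
    select_factors,
    tune_mtry,
    tune_ntree,
)

# printed confusion matrix of the reproduction target: ground-truth rows
# (non-narrowing: 138 correct / 22 wrong, narrowing: 28 wrong / 117 correct),
# positive class = non-narrowing
TABLE4 = ConfusionMatrix(tp=138, fn=22, fp=28, tn=117)


class TestGini:
    @pytest.mark.parametrize(
        "props, expected",
        [((0.5, 0.5), 0.5), ((1.0, 0.0), 0.0), ((0.8, 0.2), 0.32)],
    )
    def test_values(self, props, expected):
        assert gini_impurity(props) == pytest.approx(expected)

    def test_binary_bounds_and_maximum(self):
        ps = np.linspace(0.0, 1.0, 101)
        vals = [gini_impurity((p, 1 - p)) for p in ps]
        assert min(vals) >= 0.0 and max(vals) <= 0.5
        assert np.argmax(vals) == 50

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            gini_impurity((0.5, 0.4))
        with pytest.raises(ValueError, match="lie in"):
            gini_impurity((1.5, -0.5))


class TestClassificationMetrics:
    def test_published_confusion_matrix_metrics(self):
        m = classification_metrics(TABLE4)
        assert round(m["accuracy"], 2) == 83.61
        assert round(m["sensitivity"], 2) == 86.25
        assert round(m["specificity"], 2) == 80.69
        assert round(m["ppv"], 2) == 83.13
        assert round(m["npv"], 2) == 84.17

    @pytest.mark.parametrize(
        "cm, value",
        [(ConfusionMatrix(10, 0, 0, 10), 100.0), (ConfusionMatrix(5, 5, 5, 5), 50.0)],
    )
    def test_symmetric_matrices(self, cm, value):
        assert all(v == pytest.approx(value)
                   for v in classification_metrics(cm).values())

    def test_accuracy_identity(self):
        """accuracy = (sens * P + spec * N) / (P + N) on random matrices."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            cm = ConfusionMatrix(*(int(v) for v in rng.integers(1, 50, 4)))
            m = classification_metrics(cm)
            p, n = cm.tp + cm.fn, cm.fp + cm.tn
            assert m["accuracy"] == pytest.approx(
                (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
            )

    def test_zero_denominator_is_undefined_not_zero(self):
        m = classification_metrics(ConfusionMatrix(tp=0, fn=0, fp=3, tn=7))
        assert np.isnan(m["sensitivity"])
        assert m["specificity"] == pytest.approx(70.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)


def separable_data(n=120, n_noise=3, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x0 = np.where(y == 0, -2.0, 2.0) + 0.05 * rng.standard_normal(n)
    X = np.column_stack([x0] + [rng.standard_normal(n) for _ in range(n_noise)])
    return X, y


class TestTuning:
    def test_mtry_tie_breaks_to_smallest(self):
        X, y = separable_data()
        cfg = RFConfig(tuning_ntree=100, seed=0)
        best, errors = tune_mtry(X, y, cfg)
        assert best == 1
        assert all(e <= 2.0 for e in errors.values())

    def test_single_class_rejected(self):
        X, _ = separable_data()
        with pytest.raises(ValueError, match="classes"):
            tune_mtry(X, np.zeros(len(X)), RFConfig())

    def test_ntree_stabilizes_at_first_entry_when_separable(self):
        X, y = separable_data()
        cfg = RFConfig(ntree_schedule=(50, 100, 200, 400), seed=0)
        chosen, trace, stabilized = tune_ntree(X, y, 1, cfg)
        assert stabilized
        assert chosen == 50

    def test_ntree_exhaustion_flagged(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 3))
        y = rng.integers(0, 2, 80)
        cfg = RFConfig(ntree_schedule=(5, 10), stabilization_pp=1e-9, seed=0)
        chosen, trace, stabilized = tune_ntree(X, y, 1, cfg)
        assert chosen == 10
        assert not stabilized

    def test_noise_oob_near_chance(self):
        """Pure-noise balanced data: OOB error ~ 50% (within 6 points)."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 10))
        y = np.repeat([0, 1], 150)
        from plaquefatigue.forest import _fit_forest, _oob_error_pct

        rf = _fit_forest(X, y, 3, 500, seed=0)
        assert _oob_error_pct(rf, y) == pytest.approx(50.0, abs=6.0)


class TestSelectFactors:
    def test_single_factor_returned(self):
        X, y = separable_data(n_noise=0)
        sel, ranking = select_factors(pd.DataFrame({"only": X[:, 0]}), y,
                                      RFConfig(tuning_ntree=100))
        assert sel == ["only"]

    def test_selected_subset_ordered_by_importance(self):
        X, y = separable_data(n_noise=6, seed=3)
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        sel, ranking = select_factors(frame, y, RFConfig(tuning_ntree=150, seed=1))
        assert set(sel) <= set(frame.columns)
        imp = ranking[sel] if set(sel) <= set(ranking.index) else None
        assert sel[0] == "f0"  # the informative factor survives and leads

    def test_planted_signal_recovery(self):
        """Two informative factors among noise survive backward elimination."""
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            n = 300
            y = np.repeat([0, 1], n // 2)
            inf1 = np.where(y == 0, -1.0, 1.0) + rng.standard_normal(n)
            inf2 = np.where(y == 0, 1.0, -1.0) + rng.standard_normal(n)
            noise = rng.standard_normal((n, 17))
            frame = pd.DataFrame(
                np.column_stack([inf1, inf2, noise]),
                columns=["a", "b"] + [f"n{i}" for i in range(17)],
            )
            sel, _ = select_factors(frame, y, RFConfig(tuning_ntree=300, seed=seed))
            hits += {"a", "b"} <= set(sel)
        assert hits >= 2


class TestProgressionForestClassifier:
    def test_sklearn_protocol(self):
        clf = ProgressionForestClassifier(mtry=2, ntree=50)
        params = clf.get_params()
        assert params["mtry"] == 2
        clone(clf)  # must be cloneable

    def test_fit_predict_and_oob_attributes(self, surrogate_table):
        from plaquefatigue.features import FACTOR_COLUMNS

        X = surrogate_table[FACTOR_COLUMNS]
        y = surrogate_table.label.to_numpy()
        clf = ProgressionForestClassifier(mtry=4, ntree=300, seed=0).fit(X, y)
        assert clf.oob_error_ < 50.0
        assert clf.confusion_.total == len(y)
        assert set(clf.predict(X)) <= {0, 1}
        res = clf.result()
        assert res.metrics["accuracy"] == pytest.approx(100.0 - res.oob_error, abs=1e-9)

    def test_permuted_labels_degrade_oob_to_chance(self, surrogate_table):
        from plaquefatigue.features import FACTOR_COLUMNS

        X = surrogate_table[FACTOR_COLUMNS]
        y = surrogate_table.label.to_numpy()
        rng = np.random.default_rng(0)
        signal = ProgressionForestClassifier(mtry=4, ntree=300, seed=0).fit(X, y)
        chance = ProgressionForestClassifier(mtry=4, ntree=300, seed=0).fit(
            X, rng.permutation(y))
        assert signal.oob_error_ < chance.oob_error_
        assert chance.oob_error_ == pytest.approx(50.0, abs=10.0)
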