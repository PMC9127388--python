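"""Random-forest prediction of stenosis progression.

The forest's out-of-bag (OOB) error is the sole validation surface: each
sample is scored only by the trees whose bootstrap excluded it, which gives
an essentially unbiased generalization estimate without a holdout split.
``Mtry`` (features tried per split) is chosen by OOB-error grid search at a
fixed large tree count; ``Ntree`` is the smallest count in an increasing
schedule after which the OOB error has stabilized.  Backward elimination in
the style of varSelRF repeatedly drops the least important fifth of the
factors (by mean-decrease-Gini importance) and keeps the smallest set within
one standard error of the best OOB error.

Mean-decrease-Gini importance here is the established estimator: the
impurity decrease attributed to a factor at its split nodes, weighted by the
node sample fraction and averaged over trees (scikit-learn's
``feature_importances_``, which additionally normalizes across factors —
immaterial for ranking and selection).

The positive class for the confusion-matrix metrics is an explicit
parameter.  The printed-metric reproduction target treats the non-narrowing
(label 0) ground-truth row as positive, the only reading under which the
published percentage set is mutually consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "RFConfig",
    "ConfusionMatrix",
    "RFResult",
    "gini_impurity",
    "classification_metrics",
    "tune_mtry",
    "tune_ntree",
    "select_factors",
    "ProgressionForestClassifier",
]


def gini_impurity(class_proportions) -> float:
    """Gini impurity ``1 - sum p_i^2`` of a node's class proportions."""
    p = np.asarray(class_proportions, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum():.12g}, not 1")
    return float(1.0 - np.sum(p**2))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts under a documented positive-class convention."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive_label=0) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive_label
        pos_p = y_pred == positive_label
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )


def _ratio_pct(num: int, den: int) -> float:
    """Percentage, or NaN when the denominator is zero (undefined, not 0)."""
    return 100.0 * num / den if den > 0 else float("nan")


def classification_metrics(confusion: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV as percentages.

    Undefined ratios (zero denominators) are reported as NaN.  Rounding is
    left to display code.
    """
    cm = confusion
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "accuracy": _ratio_pct(cm.tp + cm.tn, cm.total),
        "sensitivity": _ratio_pct(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio_pct(cm.tn, cm.fp + cm.tn),
        "ppv": _ratio_pct(cm.tp, cm.tp + cm.fp),
        "npv": _ratio_pct(cm.tn, cm.fn + cm.tn),
    }


@dataclass(frozen=True)
class RFConfig:
    mtry: int | str = "auto"
    ntree: int | str = "auto"
    mtry_grid: tuple[int, ...] | None = None  # default: 1..n_factors
    ntree_schedule: tuple[int, ...] = (250, 500, 1000, 1500, 2000, 3000)
    tuning_ntree: int = 500  # tree count used during the Mtry sweep
    elimination_drop_fraction: float = 0.2
    se_rule_multiplier: float = 1.0
    stabilization_pp: float = 0.5  # percentage points of OOB-error change
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.mtry, int) and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if isinstance(self.ntree, int) and self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not 0.0 < self.elimination_drop_fraction < 1.0:
            raise ValueError("elimination_drop_fraction must lie in (0, 1)")


@dataclass
class RFResult:
    mtry: int
    ntree: int
    oob_error: float  # percent
    gini_importance: pd.Series
    selected_factors: list[str]
    confusion: ConfusionMatrix
    metrics: dict[str, float]
    ntree_stabilized: bool = True
    mtry_trace: dict[int, float] = field(default_factory=dict)
    ntree_trace: dict[int, float] = field(default_factory=dict)


def _fit_forest(X, y, mtry, ntree, seed) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=int(ntree),
        max_features=int(mtry),
        oob_score=True,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # few-tree OOB coverage
        rf.fit(X, y)
    return rf


def _oob_predictions(rf: RandomForestClassifier) -> np.ndarray:
    proba = rf.oob_decision_function_
    # samples never out of bag (possible at tiny ntree) fall back to majority
    bad = ~np.isfinite(proba).all(axis=1)
    proba = np.where(bad[:, None], 0.5, proba)
    return rf.classes_[np.argmax(proba, axis=1)]


def _oob_error_pct(rf: RandomForestClassifier, y) -> float:
    return 100.0 * float(np.mean(_oob_predictions(rf) != np.asarray(y)))


def _check_two_classes(y) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def tune_mtry(X, y, config: RFConfig = RFConfig()):
    """OOB-error grid search over Mtry; ties break to the smaller value."""
    _check_two_classes(y)
    X = np.asarray(X)
    grid = config.mtry_grid or tuple(range(1, X.shape[1] + 1))
    errors = {}
    for m in grid:
        rf = _fit_forest(X, y, m, config.tuning_ntree, config.seed)
        errors[int(m)] = _oob_error_pct(rf, y)
    best = min(sorted(errors), key=lambda m: errors[m])  # ties -> smallest mtry
    return int(best), errors


def tune_ntree(X, y, mtry: int, config: RFConfig = RFConfig()):
    """Smallest tree count in the schedule with a stabilized OOB error.

    An entry is stabilized when every subsequent change along the schedule
    stays below ``stabilization_pp`` percentage points, so a trace that is
    flat from entry k onward returns schedule[k] (the first entry for
    trivially separable data).  If no entry stabilizes before the schedule
    runs out, the last entry is returned with ``stabilized=False``.
    """
    _check_two_classes(y)
    trace = {}
    sched = list(config.ntree_schedule)
    for nt in sched:
        rf = _fit_forest(X, y, mtry, nt, config.seed)
        trace[int(nt)] = _oob_error_pct(rf, y)
    errs = [trace[nt] for nt in sched]
    diffs = [abs(b - a) for a, b in zip(errs, errs[1:])]
    for k in range(len(sched) - 1):
        if all(d < config.stabilization_pp for d in diffs[k:]):
            return int(sched[k]), trace, True
    return int(sched[-1]), trace, False


def select_factors(X: pd.DataFrame, y, config: RFConfig = RFConfig(),
                   mtry: int | None = None, ntree: int | None = None):
    """Backward elimination by mean-decrease-Gini with the 1-SE OOB rule.

    Repeatedly drops the lowest ``elimination_drop_fraction`` of the current
    factors by importance and refits; among all visited factor sets, returns
    the smallest one whose OOB error is within ``se_rule_multiplier``
    standard errors of the minimum (SE of a binomial error rate at the
    cohort size).  Also returns the full importance ranking from the
    all-factor fit for cross-checking the selection.
    """
    _check_two_classes(y)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X),
                         columns=[f"f{i}" for i in range(np.asarray(X).shape[1])])
    if X.shape[1] < 1:
        raise ValueError("need at least one factor")
    y = np.asarray(y)
    n = len(y)
    ntree = int(ntree or config.tuning_ntree)

    def fit_set(cols):
        m = mtry if (mtry and mtry <= len(cols)) else max(1, int(np.sqrt(len(cols))))
        rf = _fit_forest(X[cols].to_numpy(), y, m, ntree, config.seed)
        imp = pd.Series(rf.feature_importances_, index=cols).sort_values(ascending=False)
        return _oob_error_pct(rf, y), imp

    cols = list(X.columns)
    oob, full_ranking = fit_set(cols)
    history = [(cols, oob, full_ranking)]
    while len(cols) > 1:
        imp = history[-1][2]
        n_drop = max(1, int(np.floor(config.elimination_drop_fraction * len(cols))))
        cols = list(imp.index[: len(cols) - n_drop])
        oob, imp = fit_set(cols)
        history.append((cols, oob, imp))

    errors = np.array([h[1] for h in history])
    best = errors.min()
    se = 100.0 * np.sqrt((best / 100.0) * (1.0 - best / 100.0) / n)
    threshold = best + config.se_rule_multiplier * se
    # smallest set within the threshold
    admissible = [h for h in history if h[1] <= threshold]
    chosen = min(admissible, key=lambda h: len(h[0]))
    selected = list(chosen[2].index)  # ordered by importance
    return selected, full_ranking


class ProgressionForestClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest progression classifier with OOB-based self-tuning.

    Parameters mirror :class:`RFConfig`; with ``mtry="auto"`` /
    ``ntree="auto"`` the forest tunes both from the OOB error before the
    final fit.  With ``select=True`` backward elimination restricts the
    model to the selected factor subset.  Fitted attributes carry the OOB
    error, the importance ranking, the OOB confusion matrix and the derived
    metrics (positive class per ``positive_label``).
    """

    def __init__(self, mtry="auto", ntree="auto", mtry_grid=None,
                 ntree_schedule=(250, 500, 1000, 1500, 2000, 3000),
                 tuning_ntree=500, elimination_drop_fraction=0.2,
                 se_rule_multiplier=1.0, stabilization_pp=0.5,
                 select=False, positive_label=0, seed=0):
        self.mtry = mtry
        self.ntree = ntree
        self.mtry_grid = mtry_grid
        self.ntree_schedule = ntree_schedule
        self.tuning_ntree = tuning_ntree
        self.elimination_drop_fraction = elimination_drop_fraction
        self.se_rule_multiplier = se_rule_multiplier
        self.stabilization_pp = stabilization_pp
        self.select = select
        self.positive_label = positive_label
        self.seed = seed

    def _config(self) -> RFConfig:
        return RFConfig(
            mtry=self.mtry, ntree=self.ntree,
            mtry_grid=tuple(self.mtry_grid) if self.mtry_grid else None,
            ntree_schedule=tuple(self.ntree_schedule),
            tuning_ntree=self.tuning_ntree,
            elimination_drop_fraction=self.elimination_drop_fraction,
            se_rule_multiplier=self.se_rule_multiplier,
            stabilization_pp=self.stabilization_pp, seed=self.seed,
        )

    def fit(self, X, y):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            frame = X
        else:
            Xv, y = check_X_y(np.asarray(X), y)
            frame = pd.DataFrame(Xv, columns=[f"f{i}" for i in range(Xv.shape[1])])
        _check_two_classes(y)
        y = np.asarray(y)

        if self.select:
            selected, self.gini_ranking_ = select_factors(frame, y, cfg)
            self.selected_factors_ = selected
            frame = frame[selected]
        else:
            self.selected_factors_ = list(frame.columns)

        Xv = frame.to_numpy()
        if cfg.mtry == "auto":
            self.mtry_, self.mtry_trace_ = tune_mtry(Xv, y, cfg)
        else:
            self.mtry_, self.mtry_trace_ = int(cfg.mtry), {}
        self.mtry_ = min(self.mtry_, Xv.shape[1])
        if cfg.ntree == "auto":
            self.ntree_, self.ntree_trace_, self.ntree_stabilized_ = tune_ntree(
                Xv, y, self.mtry_, cfg)
        else:
            self.ntree_, self.ntree_trace_, self.ntree_stabilized_ = int(cfg.ntree), {}, True

        self.forest_ = _fit_forest(Xv, y, self.mtry_, self.ntree_, cfg.seed)
        self.classes_ = self.forest_.classes_
        self.oob_error_ = _oob_error_pct(self.forest_, y)
        self.importances_ = pd.Series(
            self.forest_.feature_importances_, index=frame.columns
        ).sort_values(ascending=False)
        if not self.select:
            self.gini_ranking_ = self.importances_
        y_oob = _oob_predictions(self.forest_)
        self.confusion_ = ConfusionMatrix.from_labels(y, y_oob, self.positive_label)
        self.metrics_ = classification_metrics(self.confusion_)
        return self

    def _subset(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_factors_].to_numpy()
        return np.asarray(X)

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._subset(X))

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._subset(X))

    def result(self) -> RFResult:
        check_is_fitted(self, "forest_")
        return RFResult(
            mtry=self.mtry_, ntree=self.ntree_, oob_error=self.oob_error_,
            gini_importance=self.gini_ranking_,
            selected_factors=self.selected_factors_,
            confusion=self.confusion_, metrics=self.metrics_,
            ntree_stabilized=self.ntree_stabilized_,
            mtry_trace=self.mtry_trace_, ntree_trace=self.ntree_trace_,
        )
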