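"""Feature filtering, class-weighted linear SVM, LOOCV, and binomial tests.

The classification design follows the study it models: Fisher-z
connectivity features, a univariate two-sample t-test filter comparing the
two diagnostic groups (always the diagnosis contrast, even when the
downstream labels are severity scores), per-feature standardization, a
linear soft-margin SVM with cost 1 and per-class weights 1/n_class, and
leave-one-out cross-validation.  Severity prediction is one-against-all
with argmax decision-value combination (ties broken toward the lowest
label).

Feature selection can run once on the pooled cohort (the described
procedure) or inside every LOOCV fold (the leakage-safe variant); both are
recorded in the result.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

TASKS = ("diagnosis", "gs_gait", "gs_cognition", "gs_urinary")
SEVERITY_TASKS = ("gs_gait", "gs_cognition", "gs_urinary")


@dataclass
class ClassifierConfig:
    cost: float = 1.0
    filter_alpha: float = 0.05
    selection_scope: str = "per_fold"  # or "pooled"
    class_weight_mode: str = "inverse_count"  # or "none"
    chance_level: float | None = None  # default: 1 / n observed classes

    def validate(self) -> None:
        if not (0.0 < self.filter_alpha < 1.0):
            raise InvalidInputError("filter_alpha must be in (0, 1)")
        if self.cost <= 0:
            raise InvalidInputError("cost must be positive")
        if self.selection_scope not in ("per_fold", "pooled"):
            raise InvalidInputError(f"unknown selection_scope {self.selection_scope!r}")
        if self.class_weight_mode not in ("inverse_count", "none"):
            raise InvalidInputError(
                f"unknown class_weight_mode {self.class_weight_mode!r}"
            )


@dataclass
class LabeledFeatures:
    """Per-subject feature vectors with diagnosis and severity labels."""

    features: np.ndarray  # (n_subjects, n_edges)
    subject_ids: list[str]
    groups: np.ndarray  # "HC" / "iNPH"
    severity: pd.DataFrame  # columns gs_gait, gs_cognition, gs_urinary
    roi_table_hash: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.groups = np.asarray(self.groups)
        n = self.features.shape[0]
        if not (len(self.subject_ids) == len(self.groups) == n == len(self.severity)):
            raise InvalidInputError("inconsistent subject counts in LabeledFeatures")
        bad = set(self.groups) - {"HC", "iNPH"}
        if bad:
            raise InvalidInputError(f"unknown group labels: {sorted(bad)}")
        hc = self.groups == "HC"
        if np.any(self.severity.loc[hc].to_numpy() != 0):
            raise InvalidInputError("HC subjects must carry severity 0")

    def labels_for(self, task: str) -> np.ndarray:
        if task == "diagnosis":
            return self.groups.copy()
        if task in SEVERITY_TASKS:
            return self.severity[task].to_numpy(dtype=int)
        raise InvalidInputError(f"unknown task {task!r}; expected one of {TASKS}")


@dataclass
class LinearModel:
    """Primal weights of a fitted linear SVM: f(x) = w.x + b."""

    w: np.ndarray
    b: float
    classes: list  # classes_[1] is the positive-decision class


@dataclass
class FoldRecord:
    subject_id: str
    true_label: object
    predicted_label: object
    n_selected: int
    degenerate: bool = False


@dataclass
class CvResult:
    task: str
    folds: list[FoldRecord]
    selected_pooled: list[int] | None
    accuracy: float
    n_correct: int
    n_folds: int
    p_binomial: float
    chance_level: float
    config: dict
    restricted_accuracy: float | None = None
    restricted_correct: int | None = None
    restricted_n: int | None = None
    restricted_p_binomial: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True, default=str)


def ttest_filter(features, group_labels, alpha: float = 0.05) -> np.ndarray:
    """Indices of edges whose iNPH-vs-HC pooled-variance t-test has p < alpha.

    The grouping variable is always diagnosis; zero-variance-in-both-groups
    edges are excluded with a log entry.
    """
    x = np.asarray(features, dtype=float)
    g = np.asarray(group_labels)
    classes = np.unique(g)
    if classes.size != 2:
        raise InvalidInputError(f"need exactly 2 groups, got {classes.tolist()}")
    a = x[g == classes[0]]
    b = x[g == classes[1]]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidInputError("each group needs at least 2 subjects")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance edges yield NaN p-values, handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    dead = ~np.isfinite(p)
    if dead.any():
        logger.info("t-filter excluded %d zero-variance edge(s)", int(dead.sum()))
    p = np.where(dead, 1.0, p)
    return np.flatnonzero(p < alpha)


def scale_features(train, apply_to=None, sd_floor: float = 1e-12):
    """Standardize columns by TRAIN-set mean/SD; apply to held-out rows too.

    Returns (train_scaled, apply_scaled_or_None, (mean, sd)).  Constant
    columns are floored at ``sd_floor`` (scaled to ~0) with a log entry.
    """
    tr = np.asarray(train, dtype=float)
    if tr.size == 0:
        raise InvalidInputError("empty training set")
    mean = tr.mean(axis=0)
    sd = tr.std(axis=0, ddof=0)
    floored = sd < sd_floor
    if floored.any():
        logger.info("scale_features floored %d constant column(s)", int(floored.sum()))
    sd = np.where(floored, 1.0, sd)
    tr_scaled = (tr - mean) / sd
    tr_scaled[:, floored] = 0.0
    ap_scaled = None
    if apply_to is not None:
        ap = np.asarray(apply_to, dtype=float)
        ap_scaled = (ap - mean) / sd
        ap_scaled[:, floored] = 0.0
    return tr_scaled, ap_scaled, (mean, sd)


def _class_weights(labels, mode: str):
    if mode == "none":
        return None
    vals, counts = np.unique(labels, return_counts=True)
    return {v: 1.0 / c for v, c in zip(vals.tolist(), counts.tolist())}


def fit_linear_svm(train_features, train_labels, config: ClassifierConfig | None = None) -> LinearModel:
    """Soft-margin linear C-classification with per-class cost C/n_class.

    The solver is libsvm's C-SVC (linear kernel); primal weights and bias
    are exposed for downstream weight interpretation.
    """
    config = config or ClassifierConfig()
    config.validate()
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidInputError("training set contains a single class")
    if classes.size > 2:
        raise InvalidInputError("fit_linear_svm is binary; use one_vs_all_fit")
    clf = SVC(
        kernel="linear",
        C=config.cost,
        class_weight=_class_weights(y, config.class_weight_mode),
    )
    clf.fit(x, y)
    return LinearModel(
        w=np.asarray(clf.coef_[0], dtype=float),
        b=float(clf.intercept_[0]),
        classes=list(clf.classes_),
    )


def predict_binary(model: LinearModel, features) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    f = x @ model.w + model.b
    neg, pos = model.classes
    return np.where(f > 0, pos, neg)


def one_vs_all_fit(train_features, train_labels, config: ClassifierConfig | None = None) -> dict:
    """One binary machine per label value present in the training data.

    Each machine separates its value from the rest, with inverse-count
    weights on the binarized classes; its decision value is positive for
    "this value".
    """
    config = config or ClassifierConfig()
    config.validate()
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidInputError("training set contains a single class")
    machines = {}
    for v in classes.tolist():
        y_bin = (y == v).astype(int)
        clf = SVC(
            kernel="linear",
            C=config.cost,
            class_weight=_class_weights(y_bin, config.class_weight_mode),
        )
        clf.fit(x, y_bin)
        sign = 1.0 if clf.classes_[1] == 1 else -1.0
        machines[v] = LinearModel(
            w=sign * np.asarray(clf.coef_[0], dtype=float),
            b=sign * float(clf.intercept_[0]),
            classes=[0, 1],
        )
    return machines


def predict_one_vs_all(machines: dict, features) -> np.ndarray:
    """Argmax of per-class decision values; ties go to the lowest label."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    labels = sorted(machines.keys())  # ascending: ties resolve to lowest
    scores = np.column_stack([x @ machines[v].w + machines[v].b for v in labels])
    best = np.argmax(scores, axis=1)  # first (lowest label) wins ties
    return np.asarray([labels[k] for k in best])


def loocv(dataset: LabeledFeatures, task: str, config: ClassifierConfig | None = None) -> CvResult:
    """Leave-one-out cross-validation for one prediction task.

    Every subject serves once as the test case.  With ``per_fold`` scope the
    t-test filter and the scaler see only the 21 training subjects of each
    fold; with ``pooled`` scope the filter runs once on the full cohort and
    only scaling/training stay inside the fold.
    """
    config = config or ClassifierConfig()
    config.validate()
    if task not in TASKS:
        raise InvalidInputError(f"unknown task {task!r}")
    n = dataset.features.shape[0]
    if n < 3:
        raise InvalidInputError("LOOCV needs at least 3 subjects")
    labels = dataset.labels_for(task)
    if task == "diagnosis" and np.unique(labels).size < 2:
        raise InvalidInputError("diagnosis task needs both groups present")

    pooled_sel = None
    if config.selection_scope == "pooled":
        pooled_sel = ttest_filter(dataset.features, dataset.groups, config.filter_alpha)

    folds: list[FoldRecord] = []
    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        if config.selection_scope == "per_fold":
            sel = ttest_filter(
                dataset.features[train], dataset.groups[train], config.filter_alpha
            )
        else:
            sel = pooled_sel
        degenerate = False
        if sel.size == 0:
            # nothing survives the filter: majority-vote fallback, flagged
            degenerate = True
            vals, counts = np.unique(labels[train], return_counts=True)
            pred = vals[np.argmax(counts)]
            folds.append(FoldRecord(dataset.subject_ids[i], labels[i], pred, 0, True))
            logger.warning("fold %d: empty feature selection", i)
            continue
        x_tr, x_te, _ = scale_features(
            dataset.features[np.ix_(train, sel)], dataset.features[[i]][:, sel]
        )
        y_tr = labels[train]
        if np.unique(y_tr).size < np.unique(labels).size:
            degenerate = True
            logger.info(
                "fold %d (%s): class absent from training set",
                i,
                dataset.subject_ids[i],
            )
        if task == "diagnosis":
            model = fit_linear_svm(x_tr, y_tr, config)
            pred = predict_binary(model, x_te)[0]
        else:
            machines = one_vs_all_fit(x_tr, y_tr, config)
            pred = predict_one_vs_all(machines, x_te)[0]
        folds.append(
            FoldRecord(
                dataset.subject_ids[i], labels[i], pred, int(sel.size), degenerate
            )
        )

    correct = np.asarray([f.true_label == f.predicted_label for f in folds])
    n_correct = int(correct.sum())
    if config.chance_level is not None:
        chance = config.chance_level
    elif task == "diagnosis":
        chance = 0.5
    else:
        chance = 1.0 / np.unique(labels).size
    result = CvResult(
        task=task,
        folds=folds,
        selected_pooled=None if pooled_sel is None else pooled_sel.tolist(),
        accuracy=n_correct / n,
        n_correct=n_correct,
        n_folds=n,
        p_binomial=binomial_test(n_correct, n, chance),
        chance_level=float(chance),
        config=asdict(config),
    )
    if task in SEVERITY_TASKS:
        # specificity check: restrict the test rounds to the patients
        mask = dataset.groups == "iNPH"
        sub_correct = int(correct[mask].sum())
        sub_n = int(mask.sum())
        result.restricted_correct = sub_correct
        result.restricted_n = sub_n
        result.restricted_accuracy = sub_correct / sub_n if sub_n else None
        if sub_n:
            result.restricted_p_binomial = binomial_test(sub_correct, sub_n, chance)
    return result


def binomial_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p: min(1, 2 min(P(X<=k), P(X>=k)))."""
    if not (0 <= k <= n) or int(k) != k or int(n) != n:
        raise InvalidInputError(f"invalid counts k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise InvalidInputError(f"chance level must be in (0, 1), got {p0}")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def binomial_band(n: int, p: float, confidence: float = 0.95) -> tuple[int, int]:
    """Central equal-tail binomial acceptance band [lo, hi] on counts."""
    alpha = 1.0 - confidence
    lo = int(stats.binom.ppf(alpha / 2, n, p))
    hi = int(stats.binom.ppf(1 - alpha / 2, n, p))
    return lo, hi


def accuracy_percent(k: int, n: int) -> int:
    """Accuracy as a truncated integer percent (14/22 -> 63, 18/22 -> 81)."""
    if not (0 <= k <= n) or n <= 0:
        raise InvalidInputError(f"invalid counts k={k}, n={n}")
    return int(100 * k // n)
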