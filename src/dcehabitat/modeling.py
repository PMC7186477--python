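"""Univariate screening and leakage-free LOOCV classification.

Every fold fits the full chain — variance filter, correlation filter,
selector, standardization and SVM — on the training rows alone, then
scores the single held-out case. Per-feature selection counts across
folds provide the importance ranking.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .errors import CohortError, DomainError
from .evaluation import delong_auc_ci, delong_components
from .selection import FilterThresholds, correlation_filter, run_selector, variance_filter


@dataclass
class UnivariateResult:
    feature: str
    auc: float
    ci_lower: float
    ci_upper: float
    p_value: float | None = None

    @property
    def flagged(self) -> bool:
        return not np.isfinite(self.auc)


def univariate_auc(
    values: np.ndarray, labels: np.ndarray, feature: str = ""
) -> UnivariateResult:
    """AUC of a single-feature logistic classifier with a DeLong 95% CI.

    The fitted probabilities of a one-feature logistic model are a
    monotone transform of the feature, so the AUC equals the Mann-Whitney
    AUC of the raw values, oriented by the fitted slope sign.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 3:
        raise CohortError("univariate_auc needs >= 3 cases per class")
    if np.ptp(x) == 0:
        return UnivariateResult(feature, float("nan"), float("nan"), float("nan"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
        model.fit(x[:, None], y)
    sign = 1.0 if model.coef_.ravel()[0] >= 0 else -1.0
    auc, lo, hi = delong_auc_ci(sign * x, y)
    return UnivariateResult(feature, auc, lo, hi)


@dataclass
class FittedSVM:
    svc: SVC
    platt: LogisticRegression


def svm_fit(
    rows: np.ndarray,
    labels: np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> FittedSVM:
    """SVM plus a Platt-style sigmoid fitted on the training rows only."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise CohortError("svm_fit requires both classes in the training set")
    svc = SVC(kernel=kernel, C=C, random_state=seed)
    svc.fit(rows, y)
    decision = svc.decision_function(rows).reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        platt = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
        platt.fit(decision, y)
    return FittedSVM(svc=svc, platt=platt)


def svm_score(model: FittedSVM, rows: np.ndarray) -> np.ndarray:
    """Calibrated positive-class score in [0, 1]."""
    decision = model.svc.decision_function(np.asarray(rows)).reshape(-1, 1)
    return model.platt.predict_proba(decision)[:, 1]


@dataclass
class CVResult:
    case_ids: list
    scores: np.ndarray  # per-case held-out score, aligned with case_ids
    labels: np.ndarray
    selection_counts: dict[str, int] = field(default_factory=dict)
    selector: str = ""
    classifier: str = ""
    seed: int = 0

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"case_id": self.case_ids, "label": self.labels, "score": self.scores}
        )


@dataclass
class FoldModel:
    """Everything fitted on one fold's training rows."""

    columns: list[str]  # post-filter feature columns
    selection: object  # SelectionResult
    svm: FittedSVM | None  # None when the selection is empty
    fallback_score: float  # uninformative constant, used when svm is None

    def score(self, row: pd.DataFrame) -> float:
        if self.svm is None:
            return self.fallback_score
        reduced = self.selection.transform(row[self.columns])
        return float(svm_score(self.svm, reduced)[0])


def fit_fold(
    table: pd.DataFrame,
    labels: pd.Series,
    held_out,
    selector: str = "lasso",
    thresholds: FilterThresholds = FilterThresholds(),
    kernel: str = "linear",
    C: float = 1.0,
    fold_seed: int = 0,
    selector_kwargs: dict | None = None,
) -> FoldModel:
    """Fit filters, selector and SVM on every row except ``held_out``.

    The held-out row's features and label are excluded before any fitting
    step, so mutating them cannot change the returned model.
    """
    train_ids = sorted(c for c in table.index if c != held_out)
    x_train = table.loc[train_ids]
    y_train = labels.loc[train_ids]
    if y_train.nunique() < 2:
        raise CohortError(f"fold {held_out}: single-class training set")
    filtered, _ = variance_filter(x_train, thresholds.variance_min)
    filtered = correlation_filter(filtered, thresholds.correlation_max)
    result = run_selector(
        selector,
        filtered,
        y_train.to_numpy(),
        seed=fold_seed,
        **(selector_kwargs or {}),
    )
    if result.empty:
        # An empty selection must yield an *uninformative* score. The
        # training prevalence would leak the held-out label's complement
        # (leave-one-out shifts the prevalence against the held-out class),
        # biasing null-cohort AUCs toward 0.
        return FoldModel(
            columns=list(filtered.columns),
            selection=result,
            svm=None,
            fallback_score=0.5,
        )
    z_train = result.transform(filtered)
    model = svm_fit(z_train, y_train.to_numpy(), kernel=kernel, C=C, seed=fold_seed)
    return FoldModel(
        columns=list(filtered.columns),
        selection=result,
        svm=model,
        fallback_score=0.5,
    )


def loocv_run(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    selector: str = "lasso",
    thresholds: FilterThresholds = FilterThresholds(),
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
    selector_kwargs: dict | None = None,
) -> CVResult:
    """Leave-one-out CV with fold-wise filtering, selection and SVM.

    ``table`` holds one row per case (index = case id) and one column per
    feature; no NaN values are allowed (flagged cases must be dropped
    listwise beforehand). The held-out row's features and label never
    enter any fold fitting step; folds that would train on a single class
    raise. The score vector is invariant to input row order because each
    fold sorts its training rows by case id.
    """
    if table.isna().any().any():
        raise DomainError("feature table contains NaN; drop flagged cases first")
    labels = pd.Series(np.asarray(labels, dtype=int), index=table.index)
    if len(table) < 10:
        raise CohortError("loocv_run requires at least 10 cases")
    if labels.nunique() < 2:
        raise CohortError("loocv_run requires both classes")
    if table.index.has_duplicates:
        raise DomainError("duplicate case ids in feature table")
    selector_kwargs = selector_kwargs or {}

    ordered_ids = sorted(table.index)
    scores: dict = {}
    counts: Counter = Counter()
    for position, case in enumerate(ordered_ids):
        fold = fit_fold(
            table,
            labels,
            case,
            selector=selector,
            thresholds=thresholds,
            kernel=kernel,
            C=C,
            fold_seed=seed * 100003 + position,
            selector_kwargs=selector_kwargs,
        )
        fold.selection.fold_index = position
        scores[case] = fold.score(table.loc[[case]])
        if fold.svm is None:
            continue
        if fold.selection.selector == "pca":
            counts.update(fold.selection.feature_names)
        else:
            counts.update(fold.selection.selected)

    original_ids = list(table.index)
    return CVResult(
        case_ids=original_ids,
        scores=np.array([scores[c] for c in original_ids]),
        labels=labels.loc[original_ids].to_numpy(),
        selection_counts=dict(counts),
        selector=selector,
        classifier=f"svm-{kernel}",
        seed=seed,
    )


def feature_importance(
    cv: CVResult, catalogue: tuple[str, ...] | None = None
) -> list[tuple[str, int]]:
    """Features ranked by fold-wise selection count (descending).

    Ties are broken by catalogue order when a catalogue is supplied, else
    by name.
    """
    if catalogue is not None:
        order = {name: i for i, name in enumerate(catalogue)}
        tie_key = lambda name: order.get(name, len(order))  # noqa: E731
    else:
        tie_key = lambda name: name  # noqa: E731
    return sorted(
        cv.selection_counts.items(), key=lambda kv: (-kv[1], tie_key(kv[0]))
    )


def permutation_auc_band(
    scores: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Null band for the AUC of fixed scores under label permutation."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    aucs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(y)
        aucs[i] = delong_components(np.asarray(scores), perm)[0]
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
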