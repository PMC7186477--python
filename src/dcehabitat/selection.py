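"""Feature-table pre-filters and the three fold-wise selectors.

All selectors fit exclusively on training rows: z-scoring statistics,
PCA loadings, LASSO penalties and stepwise subsets are stored on the
returned :class:`SelectionResult` so held-out rows can be transformed
without ever touching their labels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .errors import CohortError, DomainError, EmptyTableError

SELECTOR_NAMES = ("pca", "lasso", "stepwise")


@dataclass(frozen=True)
class FilterThresholds:
    variance_min: float = 0.01
    correlation_max: float = 0.95

    def __post_init__(self) -> None:
        if self.variance_min < 0:
            raise DomainError("variance_min must be >= 0")
        if not 0 < self.correlation_max < 1:
            raise DomainError("correlation_max must lie in (0, 1)")


def variance_filter(
    table: pd.DataFrame, variance_min: float = 0.01
) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns whose population variance is below the threshold."""
    if len(table) < 2:
        raise EmptyTableError("variance filter needs at least 2 rows")
    variances = table.var(axis=0, ddof=0)
    dropped = list(table.columns[variances < variance_min])
    kept = table.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise EmptyTableError("variance filter removed every column")
    return kept, dropped


def correlation_filter(
    table: pd.DataFrame, correlation_max: float = 0.95
) -> pd.DataFrame:
    """Greedy de-correlation in catalogue (column) order.

    A column is dropped when its absolute Pearson correlation with any
    earlier kept column exceeds the threshold; surviving pairs therefore
    all satisfy |r| <= correlation_max.
    """
    if len(table) < 3:
        raise EmptyTableError("correlation filter needs at least 3 rows")
    values = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(values, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    kept: list[int] = []
    for j in range(values.shape[1]):
        if all(corr[j, k] <= correlation_max for k in kept):
            kept.append(j)
    return table.iloc[:, kept]


@dataclass
class SelectionResult:
    """Fitted fold-wise selector state, sufficient to transform new rows."""

    selector: str
    feature_names: list[str]  # input columns, in order
    selected: list[str]  # selected feature names ([] for pure PCA reduction)
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray | None = None  # (k, n_features) PCA loadings
    params: dict = field(default_factory=dict)
    fold_index: int | None = None

    @property
    def empty(self) -> bool:
        if self.selector == "pca":
            return self.components is None or self.components.shape[0] == 0
        return len(self.selected) == 0

    def transform(self, rows: pd.DataFrame) -> np.ndarray:
        """Standardize with stored train statistics, then reduce."""
        x = rows[self.feature_names].to_numpy(dtype=float)
        z = (x - self.mean) / self.scale
        if self.selector == "pca":
            return z @ self.components.T
        idx = [self.feature_names.index(name) for name in self.selected]
        return z[:, idx]


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (x - mean) / scale, mean, scale


def pca_select(
    train: pd.DataFrame, cumulative_contribution: float = 0.95
) -> SelectionResult:
    """Smallest component count whose cumulative explained variance ratio
    exceeds the contribution threshold (always >= 1 component)."""
    x = train.to_numpy(dtype=float)
    z, mean, scale = _standardize(x)
    pca = PCA(svd_solver="full")
    pca.fit(z)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), cumulative_contribution) + 1)
    k = max(1, min(k, len(ratios)))
    return SelectionResult(
        selector="pca",
        feature_names=list(train.columns),
        selected=[],
        mean=mean,
        scale=scale,
        components=pca.components_[:k],
        params={
            "n_components": k,
            "explained_variance_ratio": ratios[:k].tolist(),
            "cumulative_contribution": cumulative_contribution,
        },
    )


def lasso_select(
    train: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
    Cs: int | np.ndarray = 15,
    C: float | None = None,
) -> SelectionResult:
    """L1-penalized logistic selection.

    The penalty is chosen by inner stratified ``n_folds``-fold
    cross-validated deviance on the training rows, unless a fixed ``C``
    is supplied. Selected features are those with nonzero coefficients.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise CohortError("lasso_select requires both classes in training rows")
    x = train.to_numpy(dtype=float)
    z, mean, scale = _standardize(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        if C is not None:
            model = LogisticRegression(
                penalty="l1", C=C, solver="liblinear", random_state=seed, max_iter=2000
            )
            model.fit(z, y)
            coef = model.coef_.ravel()
            chosen_c = C
        else:
            n_folds_eff = min(n_folds, int(np.bincount(y).min()))
            cv = StratifiedKFold(
                n_splits=max(2, n_folds_eff), shuffle=True, random_state=seed
            )
            model = LogisticRegressionCV(
                penalty="l1",
                solver="liblinear",
                Cs=Cs,
                cv=cv,
                scoring="neg_log_loss",
                random_state=seed,
                max_iter=2000,
            )
            model.fit(z, y)
            coef = model.coef_.ravel()
            chosen_c = float(model.C_[0])
    selected = [c for c, w in zip(train.columns, coef) if abs(w) > 1e-10]
    return SelectionResult(
        selector="lasso",
        feature_names=list(train.columns),
        selected=selected,
        mean=mean,
        scale=scale,
        params={"C": chosen_c, "seed": seed},
    )


def _logistic_loglik(x: np.ndarray, y: np.ndarray) -> float:
    """Unpenalized logistic log-likelihood (robust to separation)."""
    if x.shape[1] == 0:
        p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        return float(y.sum() * np.log(p) + (len(y) - y.sum()) * np.log(1 - p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500)
        model.fit(x, y)
        eta = model.decision_function(x)
    # log-likelihood = sum y*eta - log(1 + exp(eta))
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def stepwise_select(
    train: pd.DataFrame,
    labels: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.1,
) -> SelectionResult:
    """Bidirectional stepwise logistic selection.

    Likelihood-ratio chi-square p-values drive both moves: add the best
    candidate when p < p_enter, remove the worst current feature when
    p > p_remove. Iterations are capped at 2 x n_features.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise CohortError("stepwise_select requires both classes in training rows")
    x = train.to_numpy(dtype=float)
    z, mean, scale = _standardize(x)
    columns = list(train.columns)

    current: list[int] = []
    loglik_cache: dict[tuple[int, ...], float] = {}

    def loglik(idx: list[int]) -> float:
        key = tuple(sorted(idx))
        if key not in loglik_cache:
            loglik_cache[key] = _logistic_loglik(z[:, list(key)], y)
        return loglik_cache[key]

    for _ in range(2 * len(columns)):
        changed = False
        ll_current = loglik(current)
        # Forward step: best candidate by LR p-value.
        best_p, best_j = np.inf, None
        for j in range(len(columns)):
            if j in current:
                continue
            lr = 2.0 * (loglik(current + [j]) - ll_current)
            p_val = float(chi2.sf(max(lr, 0.0), df=1))
            if p_val < best_p:
                best_p, best_j = p_val, j
        if best_j is not None and best_p < p_enter:
            current.append(best_j)
            changed = True
        # Backward step: worst current feature by LR p-value.
        if current:
            ll_current = loglik(current)
            worst_p, worst_j = -np.inf, None
            for j in current:
                reduced = [k for k in current if k != j]
                lr = 2.0 * (ll_current - loglik(reduced))
                p_val = float(chi2.sf(max(lr, 0.0), df=1))
                if p_val > worst_p:
                    worst_p, worst_j = p_val, j
            if worst_j is not None and worst_p > p_remove:
                current.remove(worst_j)
                changed = True
        if not changed:
            break

    selected = [columns[j] for j in sorted(current)]
    return SelectionResult(
        selector="stepwise",
        feature_names=columns,
        selected=selected,
        mean=mean,
        scale=scale,
        params={"p_enter": p_enter, "p_remove": p_remove},
    )


def run_selector(
    method: str,
    train: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    **kwargs,
) -> SelectionResult:
    """Dispatch to one of the three fold-wise selectors by name."""
    if method == "pca":
        return pca_select(train, **kwargs)
    if method == "lasso":
        return lasso_select(train, labels, seed=seed, **kwargs)
    if method == "stepwise":
        return stepwise_select(train, labels, **kwargs)
    raise DomainError(f"unknown selector {method!r}; choose from {SELECTOR_NAMES}")
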