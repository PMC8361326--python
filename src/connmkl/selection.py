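"""Edge-feature ranking and selection: F-score filter and lasso.

The F-score of feature i contrasts the squared deviations of the two group
means from the overall mean against the sum of the two within-group sample
variances::

    F(i) = [(mean_pos_i - mean_i)^2 + (mean_neg_i - mean_i)^2]
           / [var_pos_i + var_neg_i]

with variances computed with n-1 in the denominator.  Larger is more
discriminative.  The lasso alternative regresses the +/-1 labels on the
standardized features under an L1 penalty chosen by nested fivefold CV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold


@dataclass
class SelectionResult:
    """Scores, the descending ranking, and (optionally) the selected subset."""

    scores: np.ndarray
    ranked_indices: np.ndarray
    method: str
    selected: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dataframe(self, provenance_names: list[str] | None = None) -> pd.DataFrame:
        p = len(self.scores)
        rank = np.empty(p, dtype=int)
        rank[self.ranked_indices] = np.arange(p)
        sel = np.zeros(p, dtype=bool)
        if self.selected is not None:
            sel[self.selected] = True
        df = pd.DataFrame({
            "feature": np.arange(p),
            "score": self.scores,
            "rank": rank,
            "selected": sel,
        })
        if provenance_names is not None:
            df.insert(1, "name", provenance_names)
        return df


def _check_classes(labels: np.ndarray, min_per_class: int) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not np.all(pos | neg):
        raise ValueError("labels must be -1 or +1")
    if pos.sum() < min_per_class or neg.sum() < min_per_class:
        raise ValueError(f"each class needs at least {min_per_class} samples")
    return pos, neg


def f_scores(features: np.ndarray, labels) -> SelectionResult:
    """Rank features by F-score; ties broken by lower column index.

    A zero within-group denominator with a non-zero numerator (constant inside
    each group, different group means: a perfect separator) scores +inf and
    ranks first; zero over zero scores 0.
    """
    X = np.asarray(features, dtype=float)
    pos, neg = _check_classes(labels, min_per_class=2)
    mean_all = X.mean(axis=0)
    mean_pos = X[pos].mean(axis=0)
    mean_neg = X[neg].mean(axis=0)
    var_pos = X[pos].var(axis=0, ddof=1)
    var_neg = X[neg].var(axis=0, ddof=1)
    num = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    den = var_pos + var_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[(den == 0) & (num > 0)] = np.inf
    scores[(den == 0) & (num == 0)] = 0.0
    order = np.argsort(-scores, kind="stable")
    return SelectionResult(
        scores=scores, ranked_indices=order, method="fscore",
        diagnostics={
            "mean_all": mean_all, "mean_pos": mean_pos, "mean_neg": mean_neg,
            "var_pos": var_pos, "var_neg": var_neg,
        },
    )


def select_top(result: SelectionResult, count_or_fraction) -> SelectionResult:
    """Keep the top-k ranked features; a fraction f maps to max(1, round(f*p))."""
    p = len(result.scores)
    if isinstance(count_or_fraction, (int, np.integer)):
        k = int(count_or_fraction)
        if not 1 <= k <= p:
            raise ValueError(f"count {k} outside [1, {p}]")
    else:
        frac = float(count_or_fraction)
        if not 0 < frac < 1:
            raise ValueError("fraction must be in (0, 1)")
        k = max(1, int(round(frac * p)))
        if k > p:
            raise ValueError(f"fraction {frac} selects more than {p} features")
    return SelectionResult(
        scores=result.scores, ranked_indices=result.ranked_indices,
        method=result.method, selected=result.ranked_indices[:k].copy(),
        diagnostics=result.diagnostics,
    )


# ---------------------------------------------------------------------------
# Lasso
# ---------------------------------------------------------------------------

def fit_lasso(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Coefficients of (1/2n)||y - b - Xw||^2 + alpha*||w||_1; alpha=0 is OLS."""
    if alpha == 0:
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        return w
    model = Lasso(alpha=alpha, fit_intercept=True, max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_


def lasso_alpha_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 30,
                     decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalties from the full-shrinkage point down ``decades``."""
    n = X.shape[0]
    yc = y - y.mean()
    alpha_max = np.max(np.abs(X.T @ yc)) / n
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max) - decades, n_alphas)


def lasso_select(features: np.ndarray, labels, n_folds: int = 5,
                 seed: int = 0) -> SelectionResult:
    """L1-penalized least squares on standardized features with CV-chosen penalty.

    The penalty minimizing mean squared prediction error over ``n_folds``
    shuffled folds is used (ties resolved toward the larger penalty, i.e. the
    sparser model).  Selected features are those with non-zero coefficients,
    ordered by |coefficient| descending.  If the optimum shrinks everything to
    zero, the largest grid penalty with at least one non-zero coefficient is
    used instead.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    _check_classes(labels, min_per_class=1)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples for {n_folds}-fold CV")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    alphas = lasso_alpha_grid(Xs, y)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))
    cv_mse = np.zeros(len(alphas))
    for tr, te in splits:
        mu_tr = Xs[tr].mean(axis=0)
        for a_idx, alpha in enumerate(alphas):
            w = fit_lasso(Xs[tr], y[tr], alpha)
            b = y[tr].mean() - mu_tr @ w
            pred = Xs[te] @ w + b
            cv_mse[a_idx] += np.mean((y[te] - pred) ** 2)
    cv_mse /= len(splits)
    best = int(np.argmin(cv_mse))  # grid is descending: first min = sparser

    chosen_alpha = alphas[best]
    coef = fit_lasso(Xs, y, chosen_alpha)
    if not np.any(coef != 0):
        for alpha in alphas:  # descending; first non-empty = sparsest model
            coef = fit_lasso(Xs, y, alpha)
            if np.any(coef != 0):
                chosen_alpha = alpha
                break
    scores = np.abs(coef)
    order = np.argsort(-scores, kind="stable")
    selected = order[: max(1, int(np.count_nonzero(coef)))]
    if not np.any(coef != 0):
        selected = np.array([], dtype=int)
    return SelectionResult(
        scores=scores, ranked_indices=order, method="lasso", selected=selected,
        diagnostics={"alpha": float(chosen_alpha), "cv_mse": cv_mse,
                     "alphas": alphas},
    )
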