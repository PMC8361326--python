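"""Leakage-safe leave-one-out cross-validation and performance metrics.

Each LOOCV fold holds out one subject and, strictly on the remaining training
rows, fits the z-score normalization, ranks and selects features, computes
the per-network kernels and trains the (multi-)kernel SVM; the held-out
subject is then scaled with the *training* statistics and scored.  Grid
search re-runs the complete LOOCV at every (C, feature-fraction) cell — the
same optimistically-biased protocol the reported accuracies use, by design.

Metrics: accuracy = (TP+TN)/(TP+FN+TN+FP), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP); the positive class is the patient group.  ROC/AUC
pool the per-fold decision values, with AUC computed from the Mann-Whitney
rank statistic (ties counted 1/2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .connectome import FeatureTable, NETWORK_KINDS
from .selection import f_scores, lasso_select, select_top
from .svm import (KernelSpec, decision_values, fit_mkl_classifier,
                  primal_weights_linear)

MODES = ("multi_kernel", "single_kernel_fused",
         "single_network:FN", "single_network:FA", "single_network:MD")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def fit_scaler(train_features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and SD (n-1) of the training rows; zero SD maps to 1."""
    X = np.asarray(train_features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two training rows to fit a scaler")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return mean, sd


def apply_scaler(features: np.ndarray, scaler) -> np.ndarray:
    mean, sd = scaler
    return (np.asarray(features, dtype=float) - mean) / sd


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_metrics(tp: int, fn: int, tn: int, fp: int
                      ) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from the confusion counts."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("each class must contain at least one subject")
    accuracy = (tp + tn) / (tp + fn + tn + fp)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity


def roc_auc(decision_vals, labels) -> tuple[float, list[tuple[float, float]]]:
    """AUC by the rank statistic plus the swept (FPR, TPR) curve points."""
    f = np.asarray(decision_vals, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = y == 1
    neg = y == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are needed for a ROC curve")
    ranks = rankdata(f)  # average ranks give ties weight 1/2
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, f)
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


# ---------------------------------------------------------------------------
# Fold records and reports
# ---------------------------------------------------------------------------

@dataclass
class FoldRecord:
    test_subject_id: str
    true_label: int
    predicted_label: int
    decision_value: float
    selected_features: np.ndarray
    selected_per_network: dict[str, np.ndarray]
    beta: dict[str, float]
    primal_weights: dict[str, np.ndarray] | None = None

    def to_jsonable(self) -> dict:
        d = {
            "test_subject_id": self.test_subject_id,
            "true_label": self.true_label,
            "predicted_label": self.predicted_label,
            "decision_value": self.decision_value,
            "selected_features": self.selected_features.tolist(),
            "selected_per_network": {k: v.tolist()
                                     for k, v in self.selected_per_network.items()},
            "beta": self.beta,
            "primal_weights": None if self.primal_weights is None else
                              {k: v.tolist() for k, v in self.primal_weights.items()},
        }
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "FoldRecord":
        return cls(
            test_subject_id=d["test_subject_id"],
            true_label=d["true_label"],
            predicted_label=d["predicted_label"],
            decision_value=d["decision_value"],
            selected_features=np.array(d["selected_features"], dtype=int),
            selected_per_network={k: np.array(v, dtype=int)
                                  for k, v in d["selected_per_network"].items()},
            beta=dict(d["beta"]),
            primal_weights=None if d["primal_weights"] is None else
                           {k: np.array(v) for k, v in d["primal_weights"].items()},
        )


@dataclass
class EvaluationReport:
    counts: dict[str, int]
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list[tuple[float, float]]
    folds: list[FoldRecord]
    config: dict = field(default_factory=dict)

    def folds_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "test_subject_id": f.test_subject_id,
            "true_label": f.true_label,
            "predicted_label": f.predicted_label,
            "decision_value": f.decision_value,
            "n_selected": len(f.selected_features),
            **{f"beta_{k}": v for k, v in f.beta.items()},
        } for f in self.folds])

    def to_json(self, path=None) -> str:
        doc = {
            "counts": self.counts,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "roc_points": self.roc_points,
            "config": self.config,
            "folds": [f.to_jsonable() for f in self.folds],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EvaluationReport":
        if isinstance(source, Path) or (
                isinstance(source, str) and not source.lstrip().startswith("{")):
            source = Path(source).read_text()
        doc = json.loads(source)
        return cls(
            counts=doc["counts"], accuracy=doc["accuracy"],
            sensitivity=doc["sensitivity"], specificity=doc["specificity"],
            auc=doc["auc"],
            roc_points=[tuple(p) for p in doc["roc_points"]],
            folds=[FoldRecord.from_jsonable(f) for f in doc["folds"]],
            config=doc["config"],
        )


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def _candidate_columns(table: FeatureTable, mode: str) -> np.ndarray:
    if mode in ("multi_kernel", "single_kernel_fused"):
        return np.arange(table.n_features)
    if mode.startswith("single_network:"):
        kind = mode.split(":", 1)[1]
        if kind not in NETWORK_KINDS:
            raise ValueError(f"unknown network kind {kind!r}")
        return table.network_columns(kind)
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _fold_blocks(table: FeatureTable, selected: np.ndarray, mode: str
                 ) -> tuple[list[str], list[np.ndarray]]:
    """Split pooled selected columns into network blocks for the given mode."""
    if mode == "multi_kernel":
        kinds = list(NETWORK_KINDS)
        per_net = []
        for kind in kinds:
            cols = set(table.network_columns(kind).tolist())
            per_net.append(np.array([j for j in selected if j in cols], dtype=int))
        return kinds, per_net
    if mode == "single_kernel_fused":
        return ["ALL"], [np.asarray(selected, dtype=int)]
    kind = mode.split(":", 1)[1]
    return [kind], [np.asarray(selected, dtype=int)]


def _select_fold_features(X_train, y_train, candidates, selection,
                          count_or_fraction, seed):
    Xc = X_train[:, candidates]
    if selection == "fscore":
        if count_or_fraction is None:
            raise ValueError("fscore selection needs a feature count or fraction")
        res = select_top(f_scores(Xc, y_train), count_or_fraction)
        local = res.selected
    elif selection == "lasso":
        res = lasso_select(Xc, y_train, seed=seed)
        local = res.selected
        if count_or_fraction is not None and len(local):
            res = select_top(res, min(_as_count(count_or_fraction, Xc.shape[1]),
                                      len(local)))
            local = res.selected
    else:
        raise ValueError(f"unknown selection method {selection!r}")
    return candidates[np.asarray(local, dtype=int)]


def _as_count(count_or_fraction, p: int) -> int:
    if isinstance(count_or_fraction, (int, np.integer)):
        return int(count_or_fraction)
    return max(1, int(round(float(count_or_fraction) * p)))


def loocv(table: FeatureTable, C: float, count_or_fraction,
          kernel: KernelSpec | None = None, selection: str = "fscore",
          mode: str = "multi_kernel", seed: int = 0) -> EvaluationReport:
    """Leave-one-out evaluation of the connectome classifier.

    ``count_or_fraction`` is an absolute feature count or a fraction of the
    candidate columns (all 3 blocks pooled for ``multi_kernel`` and
    ``single_kernel_fused``; one block for ``single_network:<kind>``).
    """
    kernel = kernel or KernelSpec()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    n = table.n_subjects
    y = table.labels
    if n < 4 or (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("LOOCV needs n >= 4 with both classes >= 2")
    candidates = _candidate_columns(table, mode)
    X = table.features
    folds: list[FoldRecord] = []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        scaler = fit_scaler(X[train])
        X_tr = apply_scaler(X[train], scaler)
        X_te = apply_scaler(X[i:i + 1], scaler)
        selected = _select_fold_features(
            X_tr, y[train], candidates, selection, count_or_fraction,
            seed=(seed + i) % (2 ** 31),
        )
        kinds, per_net = _fold_blocks(table, selected, mode)
        model = fit_mkl_classifier(
            blocks=[X_tr[:, cols] for cols in per_net],
            labels=y[train], C=C, spec=kernel, network_kinds=kinds,
            selected_per_network=per_net, scaler=scaler,
        )
        f_val = float(decision_values(model, [X_te[:, cols] for cols in per_net])[0])
        pred = 1 if f_val >= 0 else -1
        primal = None
        if kernel.kind == "linear":
            ws = primal_weights_linear(model)
            primal = {k: w for k, w in zip(kinds, ws)}
        folds.append(FoldRecord(
            test_subject_id=table.subject_ids[i],
            true_label=int(y[i]), predicted_label=pred, decision_value=f_val,
            selected_features=np.asarray(selected, dtype=int),
            selected_per_network={k: cols for k, cols in zip(kinds, per_net)},
            beta={k: float(b) for k, b in zip(kinds, model.beta)},
            primal_weights=primal,
        ))
    true = np.array([f.true_label for f in folds])
    pred = np.array([f.predicted_label for f in folds])
    tp = int(np.sum((true == 1) & (pred == 1)))
    fn_ = int(np.sum((true == 1) & (pred == -1)))
    tn = int(np.sum((true == -1) & (pred == -1)))
    fp = int(np.sum((true == -1) & (pred == 1)))
    acc, sens, spec = confusion_metrics(tp, fn_, tn, fp)
    decf = np.array([f.decision_value for f in folds])
    auc, roc_points = roc_auc(decf, true)
    config = {
        "C": C,
        "count_or_fraction": count_or_fraction,
        "kernel": asdict(kernel),
        "selection": selection,
        "mode": mode,
        "seed": seed,
    }
    return EvaluationReport(
        counts={"TP": tp, "FN": fn_, "TN": tn, "FP": fp},
        accuracy=acc, sensitivity=sens, specificity=spec,
        auc=auc, roc_points=roc_points, folds=folds, config=config,
    )


def plot_roc(reports: dict[str, "EvaluationReport"], path=None):
    """Overlay ROC curves of several evaluation reports (optional matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        pts = np.asarray(rep.roc_points)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC {rep.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def default_c_grid() -> list[float]:
    """C from 0.5 to 5.0 in steps of 0.5 (10 values)."""
    return [round(0.5 * k, 10) for k in range(1, 11)]


def default_fraction_grid() -> list[float]:
    """Feature fraction from 0.0014 to 0.0028 in steps of 0.00005 (29 values)."""
    return [round(0.0014 + 0.00005 * k, 10) for k in range(29)]


def grid_search(table: FeatureTable, C_grid=None, fraction_grid=None,
                kernel: KernelSpec | None = None, selection: str = "fscore",
                mode: str = "multi_kernel", seed: int = 0
                ) -> tuple[dict, pd.DataFrame]:
    """Full LOOCV at every (C, fraction) cell; returns best config + surface.

    Best = maximal accuracy, ties broken toward the smaller feature count,
    then the smaller C.
    """
    C_grid = list(C_grid) if C_grid is not None else default_c_grid()
    fraction_grid = (list(fraction_grid) if fraction_grid is not None
                     else default_fraction_grid())
    if not C_grid or not fraction_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    p = len(_candidate_columns(table, mode))
    for frac in fraction_grid:
        for C in C_grid:
            rep = loocv(table, C=C, count_or_fraction=frac, kernel=kernel,
                        selection=selection, mode=mode, seed=seed)
            rows.append({"C": C, "fraction": frac,
                         "n_features": _as_count(frac, p),
                         "accuracy": rep.accuracy, "auc": rep.auc})
    surface = pd.DataFrame(rows)
    best_row = surface.sort_values(
        by=["accuracy", "n_features", "C"], ascending=[False, True, True],
        kind="stable",
    ).iloc[0]
    best = {"C": float(best_row["C"]), "fraction": float(best_row["fraction"]),
            "accuracy": float(best_row["accuracy"])}
    return best, surface
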