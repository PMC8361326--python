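"""Kernels, single-kernel SVM duals, and multiple-kernel learning.

The classifier solves the soft-margin SVM dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j k(x_i, x_j)
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C

on a mixed kernel  k = sum_m beta_m k_m  whose per-network weights beta live
on the probability simplex (beta_m >= 0, sum beta_m = 1).  Following the
simpleMKL scheme, beta is optimized by alternating the SVM solve (for fixed
beta) with a reduced-gradient descent step on the simplex: the dual optimum
J(beta) is convex in beta and, at the optimum alpha*, dJ/dbeta_m =
-1/2 (alpha* o y)' K_m (alpha* o y).

The inner dual is solved by libsvm's SMO (scikit-learn ``SVC`` with a
precomputed kernel) behind the :func:`train_svm` interface.  Each training
kernel is divided by its mean diagonal entry before mixing so that beta is
comparable across networks of different scales; the same factor is applied at
test time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel
from sklearn.svm import SVC

try:  # fast path: libsvm's SMO without the estimator validation overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - layout differences across versions
    _libsvm = None

logger = logging.getLogger(__name__)

#: Iteration cap for the SMO backend; degenerate low-rank kernels can make
#: libsvm cycle for a very long time at tight tolerances.
SMO_MAX_ITER = 1_000_000

KERNEL_KINDS = ("linear", "polynomial", "rbf")


@dataclass
class KernelSpec:
    """Kernel family and hyperparameters.

    ``gamma="auto"`` resolves to 1/d where d is the network's selected
    feature count.  Polynomial kernels are (x.y + coef0)^degree.
    """

    kind: str = "linear"
    degree: int = 3
    gamma: float | str = "auto"
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.gamma != "auto" and not float(self.gamma) > 0:
            raise ValueError("gamma must be positive or 'auto'")

    def resolve(self, n_features: int) -> "KernelSpec":
        """Return a copy with a numeric gamma."""
        gamma = self.gamma
        if gamma == "auto":
            gamma = 1.0 / max(n_features, 1)
        return KernelSpec(kind=self.kind, degree=self.degree,
                          gamma=float(gamma), coef0=self.coef0)


def compute_kernel(rows_a: np.ndarray, rows_b: np.ndarray,
                   spec: KernelSpec) -> np.ndarray:
    """Kernel matrix K[i, j] = k(rows_a[i], rows_b[j])."""
    A = np.atleast_2d(np.asarray(rows_a, dtype=float))
    B = np.atleast_2d(np.asarray(rows_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"column mismatch: {A.shape[1]} vs {B.shape[1]}")
    if spec.kind == "linear":
        return linear_kernel(A, B)
    spec = spec.resolve(A.shape[1])
    if spec.kind == "polynomial":
        return polynomial_kernel(A, B, degree=spec.degree, gamma=1.0,
                                 coef0=spec.coef0)
    return rbf_kernel(A, B, gamma=spec.gamma)


def kernel_norm_factor(train_kernel: np.ndarray) -> float:
    """Mean diagonal entry (1.0 when degenerate), the per-network scale."""
    d = float(np.mean(np.diag(train_kernel)))
    return d if d > 0 else 1.0


def _check_square_psd(K: np.ndarray, tol: float = 1e-8) -> None:
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel matrix must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kernel matrix must be symmetric")
    w_min = float(np.linalg.eigvalsh(K)[0])
    scale = max(1.0, float(np.abs(np.diag(K)).max()))
    if w_min < -tol * scale:
        raise ValueError(f"kernel matrix is not PSD (min eigenvalue {w_min:.3e})")


def dual_objective(K: np.ndarray, y: np.ndarray, alpha: np.ndarray) -> float:
    """Value of the dual objective at alpha."""
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def train_svm(kernel: np.ndarray, labels, C: float,
              check_psd: bool = True, tol: float = 1e-8
              ) -> tuple[np.ndarray, float]:
    """Solve the single-kernel SVM dual; returns (alpha, bias).

    alpha satisfies the box constraints 0 <= alpha_i <= C and the equality
    sum_i alpha_i y_i = 0 up to solver tolerance; the bias comes from the
    margin support vectors (handled inside the SMO backend, which falls back
    to the bound-constraint midpoint when none are free).
    """
    K = np.asarray(kernel, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes, coded -1/+1")
    if K.shape[0] != len(y):
        raise ValueError("kernel size does not match label count")
    if check_psd:
        _check_square_psd(K)
    if _libsvm is not None:
        yf = np.asarray(y, dtype=np.float64)
        out = _libsvm.fit(np.ascontiguousarray(K, dtype=np.float64), yf,
                          svm_type=0, kernel="precomputed", C=float(C),
                          tol=tol, shrinking=0, max_iter=SMO_MAX_ITER)
        support, _, _, sv_coef, intercept = out[:5]
        # sv_coef holds +/-(y_i alpha_i); its global sign follows libsvm's
        # internal class ordering, so take |.| for alpha and -rho for the bias
        alpha = np.zeros(len(y))
        alpha[support] = np.abs(sv_coef[0])
        return alpha, float(-intercept[0])
    svc = SVC(C=C, kernel="precomputed", tol=tol, shrinking=False,
              max_iter=SMO_MAX_ITER)
    svc.fit(K, y)
    alpha = np.zeros(len(y))
    # dual_coef_ holds y_i * alpha_i for the support vectors
    alpha[svc.support_] = np.abs(svc.dual_coef_[0])
    bias = float(svc.intercept_[0])
    return alpha, bias


# ---------------------------------------------------------------------------
# Multiple-kernel learning
# ---------------------------------------------------------------------------

@dataclass
class MKLResult:
    alpha: np.ndarray
    bias: float
    beta: np.ndarray
    objective: float
    n_iter: int
    converged: bool


def train_mkl(kernels: list[np.ndarray], labels, C: float,
              tol_beta: float = 1e-4, tol_obj: float = 1e-5,
              max_outer: int = 200, check_psd: bool = True) -> MKLResult:
    """Learn simplex kernel weights by reduced-gradient descent.

    Alternates (i) the SVM dual solve on the mixed kernel sum_m beta_m K_m
    with (ii) a descent step on beta along the reduced gradient, with a
    backtracking line search bounded by the simplex.  Stops when the beta
    update or the objective change falls below tolerance, at a KKT point, or
    at ``max_outer`` iterations (then the best iterate is returned with a
    warning).
    """
    M = len(kernels)
    if M == 0:
        raise ValueError("need at least one kernel")
    y = np.asarray(labels, dtype=int)
    kernels = [np.asarray(K, dtype=float) for K in kernels]
    shape = kernels[0].shape
    for K in kernels:
        if K.shape != shape:
            raise ValueError("all kernels must share one shape")
        if check_psd:
            _check_square_psd(K)

    def solve(beta):
        K = sum(b * Km for b, Km in zip(beta, kernels))
        alpha, bias = train_svm(K, y, C, check_psd=False)
        return alpha, bias, dual_objective(K, y, alpha)

    beta = np.full(M, 1.0 / M)
    alpha, bias, J = solve(beta)
    if M == 1:
        return MKLResult(alpha, bias, beta, J, 0, True)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_outer + 1):
        ay = alpha * y
        grad = np.array([-0.5 * ay @ Km @ ay for Km in kernels])
        mu = int(np.argmax(beta))
        reduced = grad - grad[mu]
        D = -reduced
        D[(beta <= 1e-12) & (reduced > 0)] = 0.0
        D[mu] = 0.0
        D[mu] = -D.sum()
        if np.max(np.abs(D)) < 1e-12:
            converged = True  # KKT point on the simplex
            break
        # largest simplex-feasible step
        neg = D < 0
        gamma_max = float(np.min(-beta[neg] / D[neg])) if np.any(neg) else 1.0
        gamma = gamma_max
        improved = False
        for _ in range(15):
            cand = np.clip(beta + gamma * D, 0.0, None)
            cand /= cand.sum()
            a_c, b_c, J_c = solve(cand)
            if J_c < J - 1e-12:
                improved = True
                break
            gamma *= 0.5
        if not improved:
            converged = True
            break
        delta_beta = float(np.max(np.abs(cand - beta)))
        delta_J = J - J_c
        beta, alpha, bias, J = cand, a_c, b_c, J_c
        if delta_beta < tol_beta or delta_J < tol_obj:
            converged = True
            break
    if not converged:
        logger.warning("MKL did not converge in %d iterations; returning best "
                       "iterate", max_outer)
    return MKLResult(alpha, bias, beta, J, n_iter, converged)


# ---------------------------------------------------------------------------
# Trained model container
# ---------------------------------------------------------------------------

@dataclass
class TrainedMKLModel:
    """Everything needed to score new subjects.

    ``train_rows`` holds the post-scaling selected feature rows per network;
    ``kernel_norms`` the per-network mean-diagonal factors;
    ``selected_per_network`` the pooled feature-table column indices each
    network block uses; ``scaler`` the per-feature train mean/SD.
    """

    alpha: np.ndarray
    bias: float
    beta: np.ndarray
    C: float
    kernel: KernelSpec
    network_kinds: list[str]
    network_specs: list[KernelSpec]
    kernel_norms: list[float]
    selected_per_network: list[np.ndarray]
    train_rows: list[np.ndarray]
    train_labels: np.ndarray
    scaler: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if np.any(self.alpha < -1e-8) or np.any(self.alpha > self.C + 1e-8):
            raise ValueError("alpha violates the box constraints")
        if abs(float(self.alpha @ self.train_labels)) > 1e-6:
            raise ValueError("alpha violates the equality constraint")
        if np.any(self.beta < -1e-12) or abs(self.beta.sum() - 1.0) > 1e-8:
            raise ValueError("beta must lie on the probability simplex")

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "alpha": self.alpha.tolist(),
            "bias": self.bias,
            "beta": self.beta.tolist(),
            "C": self.C,
            "kernel": asdict(self.kernel),
            "network_kinds": self.network_kinds,
            "network_specs": [asdict(s) for s in self.network_specs],
            "kernel_norms": self.kernel_norms,
            "selected_per_network": [s.tolist() for s in self.selected_per_network],
            "train_rows": [r.tolist() for r in self.train_rows],
            "train_labels": self.train_labels.tolist(),
            "scaler": None if self.scaler is None else
                      [self.scaler[0].tolist(), self.scaler[1].tolist()],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TrainedMKLModel":
        if isinstance(source, Path) or (
                isinstance(source, str) and not source.lstrip().startswith("{")):
            source = Path(source).read_text()
        doc = json.loads(source)
        return cls(
            alpha=np.array(doc["alpha"]),
            bias=doc["bias"],
            beta=np.array(doc["beta"]),
            C=doc["C"],
            kernel=KernelSpec(**doc["kernel"]),
            network_kinds=list(doc["network_kinds"]),
            network_specs=[KernelSpec(**s) for s in doc["network_specs"]],
            kernel_norms=[float(v) for v in doc["kernel_norms"]],
            selected_per_network=[np.array(s, dtype=int)
                                  for s in doc["selected_per_network"]],
            train_rows=[np.array(r) for r in doc["train_rows"]],
            train_labels=np.array(doc["train_labels"], dtype=int),
            scaler=None if doc["scaler"] is None else
                   (np.array(doc["scaler"][0]), np.array(doc["scaler"][1])),
        )


def fit_mkl_classifier(blocks: list[np.ndarray], labels, C: float,
                       spec: KernelSpec, network_kinds: list[str],
                       selected_per_network: list[np.ndarray] | None = None,
                       scaler=None) -> TrainedMKLModel:
    """Train the multi-kernel classifier on per-network feature blocks.

    Blocks with zero columns are dropped from the mixture (their beta is
    forced to 0; the trained betas over the remaining networks sum to 1).
    """
    y = np.asarray(labels, dtype=int)
    if selected_per_network is None:
        selected_per_network = [np.arange(b.shape[1]) for b in blocks]
    keep = [m for m, b in enumerate(blocks) if b.shape[1] > 0]
    if not keep:
        raise ValueError("every network block is empty")
    specs_all, norms_all = [], []
    kernels = []
    for m, b in enumerate(blocks):
        s = spec.resolve(b.shape[1]) if b.shape[1] else spec.resolve(1)
        specs_all.append(s)
        if m in keep:
            K = compute_kernel(b, b, s)
            norm = kernel_norm_factor(K)
            kernels.append(K / norm)
            norms_all.append(norm)
        else:
            norms_all.append(1.0)
    result = train_mkl(kernels, y, C)
    beta = np.zeros(len(blocks))
    for b_val, m in zip(result.beta, keep):
        beta[m] = b_val
    return TrainedMKLModel(
        alpha=result.alpha, bias=result.bias, beta=beta, C=C, kernel=spec,
        network_kinds=list(network_kinds), network_specs=specs_all,
        kernel_norms=norms_all,
        selected_per_network=[np.asarray(s, dtype=int) for s in selected_per_network],
        train_rows=[np.asarray(b, dtype=float) for b in blocks],
        train_labels=y, scaler=scaler,
    )


def decision_values(model: TrainedMKLModel,
                    test_rows_per_network: list[np.ndarray]) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i sum_m beta_m k_m(x_i, x) + b for each test row."""
    if len(test_rows_per_network) != len(model.train_rows):
        raise ValueError("wrong number of network blocks")
    ay = model.alpha * model.train_labels
    n_test = None
    mix = None
    for m, (train_b, test_b) in enumerate(zip(model.train_rows,
                                              test_rows_per_network)):
        test_b = np.atleast_2d(np.asarray(test_b, dtype=float))
        if test_b.shape[1] != train_b.shape[1]:
            raise ValueError(f"network {m}: column mismatch "
                             f"{test_b.shape[1]} vs {train_b.shape[1]}")
        if n_test is None:
            n_test = test_b.shape[0]
            mix = np.zeros((train_b.shape[0], n_test))
        if model.beta[m] == 0 or train_b.shape[1] == 0:
            continue
        K = compute_kernel(train_b, test_b, model.network_specs[m])
        mix += model.beta[m] * (K / model.kernel_norms[m])
    return ay @ mix + model.bias


def predict(model: TrainedMKLModel, test_rows_per_network) -> np.ndarray:
    """Predicted labels sign(f(x)), with sign(0) = +1."""
    f = decision_values(model, test_rows_per_network)
    return np.where(f >= 0, 1, -1)


def primal_weights_linear(model: TrainedMKLModel) -> list[np.ndarray]:
    """Per-network hyperplane coefficients w_m (linear kernel only).

    w_m = (1/norm_m) sum_i alpha_i y_i x_i_m, on the normalized-kernel scale
    and before beta weighting, so that
    sum_m beta_m (w_m . x_m) + b reproduces the decision values exactly.
    """
    if model.kernel.kind != "linear":
        raise ValueError("hyperplane coefficients are defined only for the "
                         "linear kernel")
    ay = model.alpha * model.train_labels
    return [(b.T @ ay) / norm
            for b, norm in zip(model.train_rows, model.kernel_norms)]
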