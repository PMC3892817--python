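"""SVM training, prediction and leave-one-out validation.

The classifier is a soft-margin support vector machine on short feature
vectors (by default the A8 wavelet entropy and the LF/HF ratio of a
1-minute HRV window), with drowsy = +1 and alert = -1.  Both a linear and
an RBF kernel are supported, with the hyperparameter grid
``C in {10, 1, 0.1}`` and ``gamma in {10, 1, 0.1}`` (RBF only).

The quadratic-programming backend is scikit-learn's libsvm solver; every
fit is verified against the dual constraints (``0 <= lambda_j <= C`` and
``sum(lambda_j * y_j) = 0``), so the trained object is a checked solution
of the SVM dual rather than an opaque model.

Because the wavelet entropy is of order 1e4 while LF/HF is of order 1,
features are z-scored before training (learned on the training fold only
— in leave-one-out validation the held-out sample influences neither the
scaler nor the model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "TrainedModel",
    "EvalMetrics",
    "train",
    "predict",
    "decision_values",
    "loo_validate",
    "metrics",
    "default_grid",
]

GRID_C = (10.0, 1.0, 0.1)
GRID_GAMMA = (10.0, 1.0, 0.1)
KKT_TOL = 1e-3
SOLVER_TOL = 1e-6


@dataclass(frozen=True)
class SVMConfig:
    """Kernel and hyperparameters of one grid cell."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float = 0.1
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


def default_grid() -> list[SVMConfig]:
    """The hyperparameter search grid: linear x C, plus rbf x C x gamma."""
    grid = [SVMConfig(kernel="linear", C=c) for c in GRID_C]
    grid += [SVMConfig(kernel="rbf", C=c, gamma=g)
             for c, g in product(GRID_C, GRID_GAMMA)]
    return grid


@dataclass
class TrainedModel:
    """A fitted SVM: support vectors, dual multipliers, bias and scaler."""

    config: SVMConfig
    support_vectors: np.ndarray
    dual_coef: np.ndarray        # lambda_j * y_j, one per support vector
    bias: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    n_features: int

    @property
    def multipliers(self) -> np.ndarray:
        """Lagrange multipliers lambda_j (non-negative)."""
        return np.abs(self.dual_coef)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.config.kernel == "linear":
            return A @ B.T
        sq = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
              - 2.0 * A @ B.T)
        return np.exp(-self.config.gamma * np.maximum(sq, 0.0))


def _check_kkt(model: TrainedModel, y_sv: np.ndarray) -> None:
    lam = model.multipliers
    C = model.config.C
    if np.any(lam < -KKT_TOL) or np.any(lam > C + KKT_TOL):
        raise RuntimeError("dual infeasible: multipliers outside [0, C]")
    if abs(float(np.sum(lam * y_sv))) > KKT_TOL:
        raise RuntimeError("dual infeasible: sum(lambda * y) != 0")


def train(features: np.ndarray, labels: np.ndarray,
          cfg: SVMConfig = SVMConfig()) -> TrainedModel:
    """Fit the SVM dual on labelled feature vectors.

    Labels are +1 (drowsy) / -1 (alert); both must be present.  The dual
    constraints are verified on the returned solution.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be +1 (drowsy) or -1 (alert)")
    if np.unique(y).size < 2:
        raise ValueError("single-class input: both labels must be present")

    if cfg.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale

    svc = SVC(kernel=cfg.kernel, C=cfg.C,
              gamma=cfg.gamma if cfg.kernel == "rbf" else "scale",
              tol=SOLVER_TOL, shrinking=False)
    svc.fit(Xs, y)

    model = TrainedModel(
        config=cfg,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        scaler_mean=mean,
        scaler_scale=scale,
        n_features=X.shape[1],
    )
    _check_kkt(model, y[svc.support_])
    return model


def decision_values(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Signed distance surrogate: the kernel expansion plus bias."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: expected {model.n_features}, "
            f"got {X.shape[1]}")
    Xs = model._standardize(X)
    K = model._kernel(Xs, model.support_vectors)
    return K @ model.dual_coef + model.bias


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Classify points: sign of the decision function.

    An exact zero is mapped to +1 (drowsy) — the fail-safe direction for
    a drowsiness alarm — with a warning.
    """
    dec = decision_values(model, X)
    if np.any(dec == 0.0):
        warnings.warn("decision value exactly 0; classified as drowsy (+1)",
                      stacklevel=2)
    return np.where(dec >= 0.0, 1, -1)


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and the derived accuracy/sensitivity/specificity."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


def metrics(tp: int, tn: int, fp: int, fn: int) -> EvalMetrics:
    """Accuracy, sensitivity and specificity from confusion counts.

    Sensitivity = TP/(TP+FN) (drowsy detection rate), specificity =
    TN/(TN+FP); a zero denominator yields NaN for that rate.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero confusion counts")
    acc = (tp + tn) / total
    se = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    sp = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn,
                       accuracy=acc, sensitivity=se, specificity=sp)


def loo_single(features: np.ndarray, labels: np.ndarray,
               cfg: SVMConfig) -> EvalMetrics:
    """Leave-one-out validation of one grid cell.

    For each sample: standardise and train on the remaining samples,
    predict the held-out one, accumulate the confusion counts.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    tp = tn = fp = fn = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train(X[mask], y[mask], cfg)
        pred = int(predict(model, X[i:i + 1])[0])
        if y[i] == 1:
            tp += pred == 1
            fn += pred == -1
        else:
            tn += pred == -1
            fp += pred == 1
    return metrics(tp, tn, fp, fn)


def loo_validate(features: np.ndarray, labels: np.ndarray,
                 grid: list[SVMConfig] | None = None
                 ) -> tuple[dict[SVMConfig, EvalMetrics], SVMConfig]:
    """Leave-one-out validation over the full hyperparameter grid.

    Returns the metrics of every grid cell and the best configuration by
    accuracy, ties broken toward the linear kernel, then smaller C.

    Requires at least 2 samples of each class (otherwise some training
    folds are single-class).
    """
    y = np.asarray(labels, dtype=float)
    if np.sum(y == 1) < 2 or np.sum(y == -1) < 2:
        raise ValueError("need at least 2 samples per class for LOO")
    if grid is None:
        grid = default_grid()
    results = {cfg: loo_single(features, y, cfg) for cfg in grid}
    best = max(
        results,
        key=lambda c: (results[c].accuracy, c.kernel == "linear", -c.C),
    )
    return results, best
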