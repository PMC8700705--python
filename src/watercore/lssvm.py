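"""Least-squares support vector machine (classification) with RBF kernel.

LS-SVM replaces the SVM's inequality constraints with equalities, so training
reduces to one symmetric linear system in the dual variables:

    [ 0   y^T          ] [ b     ]   [ 0 ]
    [ y   Omega + I/γ  ] [ alpha ] = [ 1 ]

with Omega_ij = y_i y_j K(x_i, x_j) and K the RBF kernel
K(x, z) = exp(-||x - z||^2 / sigma2).  The decision function is
sign(sum_i alpha_i y_i K(x, x_i) + b).

Hyperparameters (regularization γ, kernel width σ²) are tuned by a coarse
log10 grid followed by a refined 5x5 grid around the coarse optimum, scored
by stratified 10-fold cross-validated accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, DegenerateInputError, SingularSystemError
from .synthetic import HEALTHY, WATERCORE

_COARSE_GRID = tuple(10.0 ** np.arange(-2, 7))  # 1e-2 .. 1e6


@dataclass(frozen=True)
class LSSVMConfig:
    gamma_grid: tuple[float, ...] = _COARSE_GRID
    sigma2_grid: tuple[float, ...] = _COARSE_GRID
    n_folds: int = 10
    standardize: bool = True
    seed: int = 0
    refine: bool = True

    def __post_init__(self) -> None:
        if not self.gamma_grid or not self.sigma2_grid:
            raise ConfigurationError("hyperparameter grids must be nonempty")
        if any(g <= 0 for g in self.gamma_grid) or any(s <= 0 for s in self.sigma2_grid):
            raise ConfigurationError("grid values must be positive")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")


@dataclass
class LSSVMModel:
    alpha: np.ndarray
    b: float
    gamma: float
    sigma2: float
    training_inputs: np.ndarray  # standardized if standardization was applied
    training_labels: np.ndarray
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "model_type": "lssvm",
            "alpha": self.alpha.tolist(),
            "b": self.b,
            "gamma": self.gamma,
            "sigma2": self.sigma2,
            "training_inputs": self.training_inputs.tolist(),
            "training_labels": self.training_labels.tolist(),
            "mean": None if self.mean_ is None else self.mean_.tolist(),
            "scale": None if self.scale_ is None else self.scale_.tolist(),
        }
        path.write_text(json.dumps(payload, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LSSVMModel":
        p = json.loads(Path(path).read_text())
        return cls(
            alpha=np.asarray(p["alpha"], dtype=float),
            b=float(p["b"]),
            gamma=float(p["gamma"]),
            sigma2=float(p["sigma2"]),
            training_inputs=np.asarray(p["training_inputs"], dtype=float),
            training_labels=np.asarray(p["training_labels"], dtype=int),
            mean_=None if p["mean"] is None else np.asarray(p["mean"], dtype=float),
            scale_=None if p["scale"] is None else np.asarray(p["scale"], dtype=float),
        )


def rbf_kernel(x: np.ndarray, z: np.ndarray, sigma2: float) -> float:
    """exp(-||x - z||^2 / sigma2) for two feature vectors."""
    if sigma2 <= 0:
        raise ConfigurationError(f"sigma2 must be positive, got {sigma2}")
    d2 = float(np.sum((np.asarray(x, float) - np.asarray(z, float)) ** 2))
    return float(np.exp(-d2 / sigma2))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    D2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-D2 / sigma2)


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant features pass through centred
    return mean, scale


def _solve_dual(K: np.ndarray, y: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    n = y.size
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = (y[:, None] * y[None, :]) * K
    A[1:, 1:] += np.eye(n) / gamma
    rhs = np.zeros(n + 1)
    rhs[1:] = 1.0
    try:
        sol = scipy.linalg.solve(A, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise SingularSystemError(
            "LS-SVM dual system is singular; increase the ridge by using a smaller gamma"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise SingularSystemError(
            "LS-SVM dual system is ill-conditioned; increase the ridge (smaller gamma)"
        )
    return float(sol[0]), sol[1:]


def fit(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float,
    sigma2: float,
    standardize: bool = True,
) -> LSSVMModel:
    """Train by solving the dual linear system at fixed (gamma, sigma2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if gamma <= 0 or sigma2 <= 0:
        raise ConfigurationError("gamma and sigma2 must be positive")
    if X.shape[0] != y.size:
        raise DegenerateInputError("X rows and y length must match")
    if HEALTHY not in y or WATERCORE not in y:
        raise DegenerateInputError("both classes must be present for training")
    mean = scale = None
    if standardize:
        mean, scale = _standardize_params(X)
        X = (X - mean) / scale
    K = _kernel_matrix(X, X, sigma2)
    b, alpha = _solve_dual(K, y.astype(float), gamma)
    return LSSVMModel(
        alpha=alpha,
        b=b,
        gamma=gamma,
        sigma2=sigma2,
        training_inputs=X,
        training_labels=y,
        mean_=mean,
        scale_=scale,
    )


def decision_function(model: LSSVMModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.training_inputs.shape[1]:
        raise DegenerateInputError(
            f"feature dimension mismatch: model expects "
            f"{model.training_inputs.shape[1]}, got {X_new.shape[1]}"
        )
    if model.mean_ is not None:
        X_new = (X_new - model.mean_) / model.scale_
    K = _kernel_matrix(X_new, model.training_inputs, model.sigma2)
    return K @ (model.alpha * model.training_labels) + model.b


def predict(model: LSSVMModel, X_new: np.ndarray) -> np.ndarray:
    """Sign of the decision function; an exact zero maps to healthy (+1)."""
    d = decision_function(model, X_new)
    return np.where(d >= 0, HEALTHY, WATERCORE)


def system_residual(model: LSSVMModel) -> float:
    """Max-norm residual of the dual system at the stored solution."""
    y = model.training_labels.astype(float)
    n = y.size
    K = _kernel_matrix(model.training_inputs, model.training_inputs, model.sigma2)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = (y[:, None] * y[None, :]) * K + np.eye(n) / model.gamma
    rhs = np.zeros(n + 1)
    rhs[1:] = 1.0
    sol = np.concatenate([[model.b], model.alpha])
    return float(np.max(np.abs(A @ sol - rhs)))


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified CV folds, shared by tuning and its oracle checks."""
    y = np.asarray(y)
    if y.size < n_folds:
        raise DegenerateInputError(
            f"need at least n_folds={n_folds} samples, got {y.size}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros((y.size, 1)), y)]


@dataclass
class TuneResult:
    gamma: float
    sigma2: float
    cv_accuracy: float
    trace: list[tuple[float, float, float]] = field(default_factory=list)


def _cv_correct_counts(
    prep: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    gamma: float,
    sigma2: float,
) -> int:
    total = 0
    for D2_tr, D2_te, y_tr, y_te in prep:
        K = np.exp(-D2_tr / sigma2)
        b, alpha = _solve_dual(K, y_tr.astype(float), gamma)
        d = np.exp(-D2_te / sigma2) @ (alpha * y_tr) + b
        pred = np.where(d >= 0, HEALTHY, WATERCORE)
        total += int((pred == y_te).sum())
    return total


def tune(X: np.ndarray, y: np.ndarray, config: LSSVMConfig) -> TuneResult:
    """Coarse-to-fine grid search scored by stratified k-fold CV accuracy.

    Squared-distance matrices are precomputed once per fold (standardizing on
    the training portion only), so each (gamma, sigma2) candidate costs one
    exponential map plus one dense solve per fold.  Ties are broken toward
    the smaller gamma, then the smaller sigma2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, config.n_folds, config.seed)
    prep = []
    for tr, te in folds:
        X_tr, X_te = X[tr], X[te]
        if config.standardize:
            mean, scale = _standardize_params(X_tr)
            X_tr = (X_tr - mean) / scale
            X_te = (X_te - mean) / scale
        prep.append(
            (
                cdist(X_tr, X_tr, "sqeuclidean"),
                cdist(X_te, X_tr, "sqeuclidean"),
                y[tr],
                y[te],
            )
        )
    n = y.size
    trace: list[tuple[float, float, float]] = []
    best: tuple[int, float, float] | None = None  # (correct, gamma, sigma2)

    def consider(gammas, sigma2s):
        nonlocal best
        for g in sorted(set(gammas)):
            for s in sorted(set(sigma2s)):
                correct = _cv_correct_counts(prep, g, s)
                trace.append((g, s, correct / n))
                if best is None or correct > best[0] or (
                    correct == best[0] and (g, s) < (best[1], best[2])
                ):
                    best = (correct, g, s)

    consider(config.gamma_grid, config.sigma2_grid)
    assert best is not None
    if config.refine:
        factors = 10.0 ** np.linspace(-1, 1, 5)
        consider(best[1] * factors, best[2] * factors)
    correct, gamma, sigma2 = best
    return TuneResult(gamma=gamma, sigma2=sigma2, cv_accuracy=correct / n, trace=trace)


def write_tuning_trace(result: TuneResult, path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame(result.trace, columns=["gamma", "sigma2", "cv_accuracy"]).to_csv(
        path, index=False
    )
    return path
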