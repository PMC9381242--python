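"""Least-squares support-vector regression with an RBF kernel.

LSSVR replaces the eps-insensitive loss and inequality constraints of
standard SVR with a squared-error loss and equality constraints, so the fit
reduces to one dense linear solve of the KKT saddle system

    [ 0   1^T        ] [ b ]   [ 0 ]
    [ 1   K + I/J    ] [ a ] = [ y ]

where K is the kernel Gram matrix, J > 0 the regularization weight, a the
dual coefficients and b the bias. Prediction is y(x) = sum_i a_i K(x, x_i) + b.
The kernel is K(x, x') = exp(-||x - x'||^2 / sigma2) — note the width
convention has no factor 2 in the denominator (equivalent to the
conventional form up to a reparameterization of sigma2).

Inputs are standardized with training-set mean/SD before kernel evaluation,
so the width sigma2 is tuned on a scale-free space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

__all__ = ["KernelParams", "LSSVRModel", "rbf_kernel", "kernel_matrix",
           "fit", "predict", "save_model", "load_model"]


@dataclass
class KernelParams:
    """Regularization weight J and RBF width sigma2, both strictly positive."""

    J: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.J) and self.J > 0):
            raise ValueError(f"J must be finite and > 0, got {self.J}")
        if not (np.isfinite(self.sigma2) and self.sigma2 > 0):
            raise ValueError(f"sigma2 must be finite and > 0, got {self.sigma2}")


@dataclass
class LSSVRModel:
    support_inputs: np.ndarray   # standardized training inputs
    dual_coeffs: np.ndarray
    bias: float
    params: KernelParams
    x_mean: np.ndarray
    x_scale: np.ndarray


def rbf_kernel(x: np.ndarray, x2: np.ndarray, sigma2: float) -> float:
    """exp(-||x - x2||^2 / sigma2) for a single pair of input vectors."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    return float(np.exp(-np.sum((x - x2) ** 2) / sigma2))


def kernel_matrix(X: np.ndarray, X2: np.ndarray, sigma2: float) -> np.ndarray:
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(X2), metric="sqeuclidean")
    return np.exp(-d2 / sigma2)


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through
    return mean, scale


def fit(X: np.ndarray, y: np.ndarray, params: KernelParams) -> LSSVRModel:
    """Solve the dual KKT system for (bias, dual coefficients).

    The solution satisfies sum(a) = 0 (the equality-constraint row); the
    residual of the full system is checked below 1e-8 after solving.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and y lengths differ")
    mean, scale = _standardizer(X)
    Xs = (X - mean) / scale
    K = kernel_matrix(Xs, Xs, params.sigma2)
    system = np.zeros((n + 1, n + 1))
    system[0, 1:] = 1.0
    system[1:, 0] = 1.0
    system[1:, 1:] = K + np.eye(n) / params.J
    rhs = np.concatenate([[0.0], y])
    try:
        sol = solve(system, rhs, assume_a="sym")
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular LSSVR system (cond ~ {np.linalg.cond(system):.2e}); "
            "check J/sigma2 and for duplicated inputs"
        ) from exc
    residual = np.abs(system @ sol - rhs).max()
    if not np.isfinite(residual) or residual > 1e-8 * max(1.0, np.abs(y).max()):
        raise np.linalg.LinAlgError(
            f"ill-conditioned LSSVR system: residual {residual:.2e}, "
            f"cond ~ {np.linalg.cond(system):.2e}"
        )
    return LSSVRModel(support_inputs=Xs, dual_coeffs=sol[1:], bias=float(sol[0]),
                      params=params, x_mean=mean, x_scale=scale)


def predict(model: LSSVRModel, Xq: np.ndarray) -> np.ndarray:
    """Evaluate y(x) = sum_i a_i K(x, x_i) + b at the query inputs."""
    Xq = np.asarray(Xq, dtype=float)
    if Xq.ndim == 1:
        # 1-D input: a batch of scalar queries for 1-feature models,
        # otherwise a single d-dimensional query
        d = model.support_inputs.shape[1]
        Xq = Xq[:, None] if d == 1 else Xq[None, :]
    if Xq.shape[1] != model.support_inputs.shape[1]:
        raise ValueError(
            f"query dimension {Xq.shape[1]} does not match training "
            f"dimension {model.support_inputs.shape[1]}"
        )
    Xqs = (Xq - model.x_mean) / model.x_scale
    Kq = kernel_matrix(Xqs, model.support_inputs, model.params.sigma2)
    return Kq @ model.dual_coeffs + model.bias


def save_model(model: LSSVRModel, path) -> None:
    doc = {
        "support_inputs": model.support_inputs.tolist(),
        "dual_coeffs": model.dual_coeffs.tolist(),
        "bias": model.bias,
        "J": model.params.J,
        "sigma2": model.params.sigma2,
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> LSSVRModel:
    with open(path) as fh:
        doc = json.load(fh)
    return LSSVRModel(
        support_inputs=np.asarray(doc["support_inputs"], dtype=float),
        dual_coeffs=np.asarray(doc["dual_coeffs"], dtype=float),
        bias=float(doc["bias"]),
        params=KernelParams(J=doc["J"], sigma2=doc["sigma2"]),
        x_mean=np.asarray(doc["x_mean"], dtype=float),
        x_scale=np.asarray(doc["x_scale"], dtype=float),
    )
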