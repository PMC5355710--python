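"""Least-squares support vector machine regression.

An LSSVM replaces the SVM's inequality constraints with equalities, so
training reduces to one linear system.  For training inputs x_1..x_l,
targets y, regularization gamma and kernel K the dual problem is

    [ 0    1^T          ] [ b     ]   [ 0 ]
    [ 1    K + I/gamma  ] [ alpha ] = [ y ]

and the predictor is f(x) = sum_i alpha_i K(x_i, x) + b.  The equality
constraint forces sum(alpha) = 0.  Kernels used here are the RBF
K(u, v) = exp(-||u - v||^2 / sigma2) with sigma2 = 500 and the linear
kernel K(u, v) = u^T v; the study-wide regularization is gamma = 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


def rbf_kernel(U: np.ndarray, V: np.ndarray, sigma2: float = 500.0) -> np.ndarray:
    U = np.atleast_2d(np.asarray(U, float))
    V = np.atleast_2d(np.asarray(V, float))
    return np.exp(-cdist(U, V, "sqeuclidean") / sigma2)


def linear_kernel(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    U = np.atleast_2d(np.asarray(U, float))
    V = np.atleast_2d(np.asarray(V, float))
    return U @ V.T


@dataclass
class LssvmComponent:
    """One trained LSSVM regression component."""

    X: np.ndarray
    alpha: np.ndarray
    bias: float
    kernel: str = "rbf"  # "rbf" | "linear"
    sigma2: float = 500.0
    gamma_reg: float = 100.0

    def kernel_matrix(self, U: np.ndarray) -> np.ndarray:
        if self.kernel == "rbf":
            return rbf_kernel(U, self.X, self.sigma2)
        return linear_kernel(U, self.X)

    def predict(self, U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, float))
        return self.kernel_matrix(U) @ self.alpha + self.bias


def train_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    gamma_reg: float = 100.0,
    sigma2: float = 500.0,
) -> LssvmComponent:
    """Solve the LSSVM dual linear system.

    A singular system (e.g. duplicated samples with the linear kernel at
    huge gamma) is ridge-perturbed on the diagonal by 1e-10 and warned.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    l = X.shape[0]
    if l == 0:
        raise ValueError("at least one training sample required")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("training data must be finite")
    if kernel == "rbf":
        K = rbf_kernel(X, X, sigma2)
    elif kernel == "linear":
        K = linear_kernel(X, X)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    A = np.zeros((l + 1, l + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(l) / gamma_reg
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("singular LSSVM system; ridge-perturbing diagonal", stacklevel=2)
        sol = np.linalg.solve(A + 1e-10 * np.eye(l + 1), rhs)
    return LssvmComponent(X, sol[1:], float(sol[0]), kernel, sigma2, gamma_reg)
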