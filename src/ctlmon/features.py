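"""Feature smoothing and per-channel dimensionality reduction.

Two stages sit between the 56-feature matrix and the classifier:

* **Adaptive exponential smoothing (AES)** removes residual motion
  artifacts without a template.  The smoother
  ``eps(k) = (1 - g) * eps(k-1) + g * x(k)`` switches its gain g among
  three values by the size of the innovation ``|x(k) - eps(k-1)|``
  relative to the series s.d. sigma: small innovations (< a*sigma) get
  g1 = 0.2, intermediate ones (a*sigma .. b*sigma) get the cautious
  g2 = 0.1, and large jumps (>= b*sigma) get g3 = 0.3, with a = 1 and
  b = 2.2.

* **Locality preserving projection (LPP)** maps each EEG channel's five
  band powers to one scalar x' = mu^T x, where mu is the generalized
  eigenvector with the smallest eigenvalue of X^T L X mu = lam X^T D X mu
  (L the graph Laplacian of a heat-kernel weighted k-NN graph, D its
  degree matrix).  One scalar per channel plus heart rate gives the
  12-dimensional salient feature vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import squareform, pdist

from .preprocess import BAND_NAMES, EEG_CHANNELS

REDUCED_COLUMNS = EEG_CHANNELS + ("HR",)


@dataclass
class AesParams:
    """Gain-switching constants of the adaptive exponential smoother."""

    a: float = 1.0
    b: float = 2.2
    g1: float = 0.2
    g2: float = 0.1
    g3: float = 0.3

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError("require a < b")
        for g in (self.g1, self.g2, self.g3):
            if not 0.0 < g <= 1.0:
                raise ValueError("gains must lie in (0, 1]")


def smooth_aes(
    series: np.ndarray,
    params: AesParams | None = None,
    sigma: float | None = None,
    init: float | None = None,
) -> np.ndarray:
    """Adaptive exponential smoothing of one feature series.

    ``sigma`` defaults to the s.d. of the series itself; pass the training
    session's s.d. to smooth a test session with frozen scale.  A zero
    sigma degenerates to pass-through (warned).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if params is None:
        params = AesParams()
    if sigma is None:
        sigma = float(np.std(x))
    if sigma <= 0:
        warnings.warn("zero-variance series: AES pass-through", stacklevel=2)
        return x.copy()
    out = np.empty_like(x)
    eps = x[0] if init is None else float(init)
    out[0] = eps if init is not None else x[0]
    if init is not None:
        dev = abs(x[0] - eps)
        g = params.g1 if dev < params.a * sigma else (
            params.g2 if dev < params.b * sigma else params.g3
        )
        eps = (1.0 - g) * eps + g * x[0]
        out[0] = eps
    for k in range(1, x.size):
        dev = abs(x[k] - eps)
        if dev < params.a * sigma:
            g = params.g1
        elif dev < params.b * sigma:
            g = params.g2
        else:
            g = params.g3
        eps = (1.0 - g) * eps + g * x[k]
        out[k] = eps
    return out


@dataclass
class LppMapping:
    """Fitted per-channel LPP projection: x' = sign * mu^T x."""

    mu: np.ndarray
    sign: float = 1.0
    n_neighbors: int = 5
    kernel_width: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "mu": list(map(float, self.mu)),
            "sign": self.sign,
            "n_neighbors": self.n_neighbors,
            "kernel_width": self.kernel_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LppMapping":
        return cls(
            np.asarray(d["mu"], float), d["sign"], d["n_neighbors"], d["kernel_width"]
        )


def fit_lpp(
    X: np.ndarray, n_neighbors: int = 5, kernel_width: float | None = None
) -> LppMapping:
    """Fit the one-dimensional LPP mapping for one channel's K x 5 band matrix.

    Heat-kernel weights exp(-d^2/t) on a symmetrized k-NN graph with
    t = median squared pairwise distance (unless given).  Rank-deficient
    scatter matrices are handled by solving in the non-null subspace of
    X^T D X (warned).
    """
    X = np.asarray(X, dtype=float)
    K, p = X.shape
    if K < n_neighbors + 1:
        raise ValueError("need more samples than neighbors")
    d2 = squareform(pdist(X, "sqeuclidean"))
    if kernel_width is None:
        off = d2[~np.eye(K, dtype=bool)]
        kernel_width = float(np.median(off))
        if kernel_width <= 0:
            kernel_width = 1.0
    # symmetrized k-NN adjacency (self excluded)
    order = np.argsort(d2, axis=1)
    adj = np.zeros((K, K), dtype=bool)
    rows = np.repeat(np.arange(K), n_neighbors)
    adj[rows, order[:, 1 : n_neighbors + 1].ravel()] = True
    adj |= adj.T
    W = np.where(adj, np.exp(-d2 / kernel_width), 0.0)
    D = np.diag(W.sum(axis=1))
    L = D - W
    A = X.T @ L @ X
    B = X.T @ D @ X
    # restrict to the non-null subspace of B
    evals, evecs = linalg.eigh(B)
    keep = evals > max(evals.max(), 0.0) * 1e-10
    if not keep.all():
        warnings.warn(
            "rank-deficient LPP scatter; solving in the non-null subspace",
            stacklevel=2,
        )
    V = evecs[:, keep]
    Ar = V.T @ A @ V
    Br = V.T @ B @ V
    w, vecs = linalg.eigh(Ar, Br)
    mu = V @ vecs[:, int(np.argmin(w))]
    mu = mu / np.linalg.norm(mu)
    return LppMapping(mu, 1.0, n_neighbors, kernel_width)


def project_lpp(mapping: LppMapping, X: np.ndarray) -> np.ndarray:
    """Project band vectors to the scalar channel feature x' = sign * mu^T x."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != mapping.mu.size:
        raise ValueError(
            f"dimension mismatch: data has {X.shape[-1]} bands, mapping {mapping.mu.size}"
        )
    return mapping.sign * X @ mapping.mu


def orient_mapping(mapping: LppMapping, X: np.ndarray, y: np.ndarray) -> LppMapping:
    """Fix the projection sign so the training correlation with y is nonnegative."""
    scores = np.asarray(X, float) @ mapping.mu
    r = feature_performance_correlation(scores, y, absolute=False)
    if not np.isnan(r) and r < 0:
        mapping.sign = -1.0
    else:
        mapping.sign = 1.0
    return mapping


def feature_performance_correlation(
    x: np.ndarray, y: np.ndarray, absolute: bool = True
) -> float:
    """(Absolute) Pearson correlation between a feature series and performance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return abs(r) if absolute else r


@dataclass
class FeatureReducer:
    """AES smoothing + per-channel LPP, fitted on a training session.

    Reduces the K x 56 feature matrix (11 channels x 5 bands + HR) to the
    K x 12 salient matrix: one LPP scalar per EEG channel plus smoothed HR.
    The per-feature AES sigmas and per-channel mappings are estimated on
    the training session and frozen for test sessions.
    """

    aes: AesParams = field(default_factory=AesParams)
    n_neighbors: int = 5
    mappings: dict[str, LppMapping] = field(default_factory=dict)
    sigmas: dict[str, float] = field(default_factory=dict)

    def fit(self, features: pd.DataFrame, y: np.ndarray) -> "FeatureReducer":
        for col in features.columns:
            self.sigmas[col] = float(np.std(features[col].to_numpy()))
        smoothed = self._smooth(features)
        for ch in EEG_CHANNELS:
            X = smoothed[[f"{ch}_{b}" for b in BAND_NAMES]].to_numpy()
            mapping = fit_lpp(X, n_neighbors=self.n_neighbors)
            self.mappings[ch] = orient_mapping(mapping, X, y)
        return self

    def _smooth(self, features: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in features.columns:
            out[col] = smooth_aes(
                features[col].to_numpy(), self.aes, sigma=self.sigmas.get(col)
            )
        return pd.DataFrame(out, index=features.index)

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if not self.mappings:
            raise RuntimeError("reducer must be fitted first")
        smoothed = self._smooth(features)
        cols = {}
        for ch in EEG_CHANNELS:
            X = smoothed[[f"{ch}_{b}" for b in BAND_NAMES]].to_numpy()
            cols[ch] = project_lpp(self.mappings[ch], X)
        cols["HR"] = smoothed["HR"].to_numpy()
        df = pd.DataFrame(cols, index=features.index, columns=list(REDUCED_COLUMNS))
        df.index.name = "epoch"
        return df

    def fit_transform(self, features: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
        return self.fit(features, y).transform(features)

    def save(self, path) -> None:
        payload = {
            "aes": vars(self.aes),
            "n_neighbors": self.n_neighbors,
            "sigmas": self.sigmas,
            "mappings": {ch: m.to_dict() for ch, m in self.mappings.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "FeatureReducer":
        with open(path) as fh:
            d = json.load(fh)
        red = cls(AesParams(**d["aes"]), d["n_neighbors"])
        red.sigmas = {k: float(v) for k, v in d["sigmas"].items()}
        red.mappings = {ch: LppMapping.from_dict(m) for ch, m in d["mappings"].items()}
        return red
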