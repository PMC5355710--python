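"""Operator task-performance indices and 5-class cognitive task-load labels.

For each 10-s segment of the process-control task (four air-quality
subsystems, n(k) of them under manual control), three indices are computed:

* SIE  s_e(k) -- mean fraction of the segment each manual subsystem spends
  outside the *error* range (as printed: high s_e means good performance;
  very low s_e signals performance breakdown),
* SIT  s_t(k) -- the same for the *transition* zone,
* ASE  s_a(k) -- mean absolute deviation of the subsystem outputs from
  their set-points, normalized by the error-range length L.

These combine into the overall performance

    y(k) = 0.5 * min(s_e, s_t) + 0.5 * (1 - s_a_norm),

with s_a min-max normalized over the participant's concatenated sessions so
y stays in [0, 1].  Lower y means higher cognitive task-load.  y is
discretized into five load classes (very-low .. very-high) by thresholds at
1 - sigma_o and 1 - z_i * sigma_o where sigma_o is the s.d. of y and the
z coefficients are participant-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: participant-specific discretization coefficients (z1, z2, z3)
PARTICIPANT_Z: dict[str, tuple[float, float, float]] = {
    "A": (2.3, 2.7, 3.0),
    "B": (2.3, 2.6, 3.0),
    "C": (2.5, 2.7, 3.0),
    "D": (2.3, 2.7, 3.0),
    "E": (2.3, 2.5, 3.0),
    "F": (2.3, 2.7, 3.0),
    "G": (2.8, 3.1, 3.2),
}

CLASS_NAMES = ("very-low", "low", "normal", "high", "very-high")


def compute_sie(p: np.ndarray, n: int | None = None, T: float = 10.0) -> float:
    """Mean fraction of the segment spent out of the error range."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("at least one subsystem duration required")
    if n is not None and n != p.size:
        raise ValueError(f"n = {n} does not match {p.size} durations")
    if np.any((p < 0) | (p > T)):
        raise ValueError("durations must lie in [0, T]")
    return float(np.mean(p / T))


def compute_sit(q: np.ndarray, n: int | None = None, T: float = 10.0) -> float:
    """Mean fraction of the segment spent out of the transition zone."""
    return compute_sie(q, n, T)


def compute_ase(
    d: np.ndarray, c: np.ndarray, L: float | np.ndarray, n: int | None = None,
    T: float | None = None,
) -> float:
    """Mean set-point deviation |d_ij - c_i| / L over subsystems and seconds."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    c = np.asarray(c, dtype=float).reshape(-1, 1)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("error-range length L must be positive")
    if d.shape[0] != c.shape[0]:
        raise ValueError("one set-point per subsystem required")
    if n is not None and n != d.shape[0]:
        raise ValueError(f"n = {n} does not match {d.shape[0]} subsystems")
    if T is not None and T != d.shape[1]:
        raise ValueError(f"T = {T} does not match {d.shape[1]} samples")
    dev = np.abs(d - c) / (L.reshape(-1, 1) if L.ndim else L)
    return float(dev.mean())


def normalize_ase(s_a: np.ndarray) -> np.ndarray:
    """Min-max normalize ASE over the concatenated sessions, clipped to [0, 1]."""
    s_a = np.asarray(s_a, dtype=float)
    lo, hi = s_a.min(), s_a.max()
    if hi == lo:
        return np.zeros_like(s_a)
    return np.clip((s_a - lo) / (hi - lo), 0.0, 1.0)


def compute_performance(s_e, s_t, s_a_norm):
    """Overall performance y = 0.5*min(s_e, s_t) + 0.5*(1 - s_a_norm)."""
    s_e = np.asarray(s_e, dtype=float)
    s_t = np.asarray(s_t, dtype=float)
    s_a_norm = np.asarray(s_a_norm, dtype=float)
    y = 0.5 * np.minimum(s_e, s_t) + 0.5 * (1.0 - s_a_norm)
    return float(y) if y.ndim == 0 else y


def discretize_performance(
    y, sigma_o: float, z: tuple[float, float, float]
) -> np.ndarray | int:
    """Map performance to load class 1..5 (half-open intervals, 5 = otherwise).

    class 1: 1 - sigma_o <= y <= 1
    class 2: 1 - z1*sigma_o <= y < 1 - sigma_o
    class 3: 1 - z2*sigma_o <= y < 1 - z1*sigma_o
    class 4: 1 - z3*sigma_o <= y < 1 - z2*sigma_o
    class 5: otherwise
    """
    if sigma_o <= 0:
        raise ValueError("sigma_o must be positive")
    z1, z2, z3 = z
    if not z1 < z2 < z3:
        raise ValueError("discretization coefficients must satisfy z1 < z2 < z3")
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    c = np.full(y_arr.shape, 5, dtype=int)
    c[(y_arr >= 1 - z3 * sigma_o) & (y_arr < 1 - z2 * sigma_o)] = 4
    c[(y_arr >= 1 - z2 * sigma_o) & (y_arr < 1 - z1 * sigma_o)] = 3
    c[(y_arr >= 1 - z1 * sigma_o) & (y_arr < 1 - sigma_o)] = 2
    c[(y_arr >= 1 - sigma_o) & (y_arr <= 1)] = 1
    return int(c[0]) if np.isscalar(y) or np.ndim(y) == 0 else c


def select_z_by_occupancy(
    y: np.ndarray, sigma_o: float, occupancy: tuple[float, ...]
) -> tuple[float, float, float]:
    """Choose (z1, z2, z3) so class occupancies approximate a target profile.

    ``occupancy`` gives target fractions for classes 1..5 (summing to 1).
    The class-1 boundary is fixed at 1 - sigma_o by construction; z1..z3 are
    placed at the empirical quantiles that match the cumulative profile of
    classes 5, 5+4 and 5+4+3, then nudged to keep z1 < z2 < z3.
    """
    y = np.asarray(y, dtype=float)
    p1, p2, p3, p4, p5 = occupancy
    zs = []
    for cum in (p5 + p4 + p3, p5 + p4, p5):
        q = float(np.quantile(y, cum))
        zs.append(max((1.0 - q) / sigma_o, 1.0 + 1e-6))
    z1, z2, z3 = zs
    z2 = max(z2, z1 + 1e-6)
    z3 = max(z3, z2 + 1e-6)
    return (z1, z2, z3)


@dataclass
class PerformanceSeries:
    """Per-epoch performance indices, overall measure and load labels."""

    s_e: np.ndarray
    s_t: np.ndarray
    s_a: np.ndarray
    s_a_norm: np.ndarray
    y: np.ndarray
    sigma_o: float
    z: tuple[float, float, float]
    C: np.ndarray

    @classmethod
    def from_indices(
        cls,
        s_e: np.ndarray,
        s_t: np.ndarray,
        s_a: np.ndarray,
        z: tuple[float, float, float] = PARTICIPANT_Z["A"],
        sigma_o: float | None = None,
    ) -> "PerformanceSeries":
        s_e = np.asarray(s_e, float)
        s_t = np.asarray(s_t, float)
        s_a = np.asarray(s_a, float)
        s_a_norm = normalize_ase(s_a)
        y = compute_performance(s_e, s_t, s_a_norm)
        if sigma_o is None:
            sigma_o = float(np.std(y))
        C = discretize_performance(y, sigma_o, z)
        return cls(s_e, s_t, s_a, s_a_norm, y, sigma_o, z, C)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "s_e": self.s_e,
                "s_t": self.s_t,
                "s_a": self.s_a,
                "y": self.y,
                "C": self.C,
            }
        )
        df.index.name = "epoch"
        return df
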