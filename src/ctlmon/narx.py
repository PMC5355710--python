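"""Dynamic 5-class load classification with NARX LSSVM models.

The classifier is a regression-then-discretize design: a nonlinear
autoregressive model with exogenous inputs (NARX) predicts the continuous
operator performance y(k) from the current and past salient physiological
features x'(k) and from lagged performance, and the prediction is mapped to
a load class through the same five-interval discretization used for the
target labels.

Two variants are provided, differing in what feeds the autoregressive side:

* **LSSVM1** combines an RBF-kernel LSSVM on the exogenous lag block
  [x'(k) .. x'(k-d1+1)] with a linear-kernel LSSVM on its *own* fed-back
  predictions [y~(k-1) .. y~(k-d2)], with fixed convex weights
  m1 = 0.1, m2 = 0.9.
* **LSSVM2** adds a third, local linear regressor refit at every step on a
  sliding window of only four past samples (j = k-5 .. k-2) whose inputs
  are lagged *measured* performance; weights w1 = 0.02, w2 = 0.18,
  w3 = 0.8.  This variant requires measured performance up to k-1 and is
  the more accurate of the two.

Model orders (d1, d2) are selected on the training session by minimizing

    J(d1, d2) = tau1 * r_e(d1, d2) + tau2 * n_theta / n_theta_max

over the integer grid [1, 15] x [1, 15], where r_e is the teacher-forced
training RMSE and n_theta = p*d1 + 2*d2 counts regressor inputs
(p = exogenous feature dimension).

Usage follows the fitted-model idiom::

    model = CtlNarx(y_train, x_train, variant="lssvm2", orders=(3, 5))
    res = model.fit()
    y_hat = res.predict(x_test, endog=y_test)
    report = res.evaluate(x_test, y_test, sigma_o=sig, z=(2.3, 2.7, 3.0))
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ClassifierEvaluation
from .lssvm import LssvmComponent, train_lssvm
from .performance import discretize_performance

VARIANT_WEIGHTS = {
    "lssvm1": (0.1, 0.9),
    "lssvm2": (0.02, 0.18, 0.8),
}

#: four-sample sliding window of the LSSVM2 local regressor, k-5 .. k-2
LOCAL_WINDOW_OFFSETS = (-5, -4, -3, -2)


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def build_narx_regressors(
    x: np.ndarray, y: np.ndarray, d1: int, d2: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Supervised NARX pairs with teacher forcing.

    Returns (exog_block, ar_block, targets, t0) where t0 is the 0-based
    index of the first usable step (1-based k = max(d1, d2+1)); the
    exogenous block stacks x(k)..x(k-d1+1) (p*d1 wide) and the AR block the
    d2 lagged measured performances.
    """
    x = _as_2d(x)
    y = np.asarray(y, float).ravel()
    K, p = x.shape
    if K != y.size:
        raise ValueError("x and y must have equal length")
    t0 = max(d1, d2 + 1) - 1
    if K <= t0:
        raise ValueError(f"series of length {K} too short for orders ({d1}, {d2})")
    rows = np.arange(t0, K)
    exog = np.concatenate([x[rows - lag] for lag in range(d1)], axis=1)
    ar = np.column_stack([y[rows - lag] for lag in range(1, d2 + 1)])
    return exog, ar, y[rows], t0


def n_theta(d1: int, d2: int, p: int) -> int:
    """Regressor-input count used as the complexity measure in J."""
    return p * d1 + 2 * d2


@dataclass
class StructureSearchResult:
    """Objective surface and selected orders of the grid search."""

    J: np.ndarray
    r_e: np.ndarray
    d1_values: np.ndarray
    d2_values: np.ndarray
    tau: tuple[float, float]
    selected: tuple[int, int]

    @property
    def n_candidates(self) -> int:
        return self.J.size


class CtlNarx:
    """NARX LSSVM performance-prediction model (unfitted specification).

    Parameters
    ----------
    endog : measured performance series y(k) of the training session.
    exog : salient features x'(k), shape (K,) or (K, p).
    variant : "lssvm1" or "lssvm2".
    orders : (d1, d2); if None, `fit` runs the grid search.
    weights : override of the fixed convex combination weights.
    """

    def __init__(
        self,
        endog,
        exog,
        variant: str = "lssvm2",
        orders: tuple[int, int] | None = None,
        weights: tuple[float, ...] | None = None,
        gamma_reg: float = 100.0,
        sigma2: float = 500.0,
    ):
        if variant not in VARIANT_WEIGHTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.endog = np.asarray(endog, float).ravel()
        self.exog = _as_2d(exog)
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog must have equal length")
        self.variant = variant
        self.orders = orders
        self.weights = tuple(weights) if weights is not None else VARIANT_WEIGHTS[variant]
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("combination weights must sum to 1")
        self.gamma_reg = gamma_reg
        self.sigma2 = sigma2

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, perf_col: str = "y", feature_cols=None, **kwargs
    ) -> "CtlNarx":
        if feature_cols is None:
            feature_cols = [c for c in df.columns if c not in (perf_col, "C")]
        return cls(df[perf_col].to_numpy(), df[feature_cols].to_numpy(), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        grid: tuple[int, int] = (1, 15),
        tau: tuple[float, float] = (0.8, 0.2),
    ) -> "CtlNarxResults":
        """Train the component LSSVMs (after selecting orders if needed)."""
        structure = None
        if self.orders is None:
            structure = self.select_structure(grid=grid, tau=tau)
            self.orders = structure.selected
        d1, d2 = self.orders
        comps, r_e, fitted = self._train_at(d1, d2)
        return CtlNarxResults(self, comps, (d1, d2), structure, r_e, fitted)

    def _train_at(self, d1: int, d2: int):
        exog, ar, targets, t0 = build_narx_regressors(self.exog, self.endog, d1, d2)
        comp_exog = train_lssvm(exog, targets, "rbf", self.gamma_reg, self.sigma2)
        comp_ar = train_lssvm(ar, targets, "linear", self.gamma_reg, self.sigma2)
        comps = {"exog": comp_exog, "ar": comp_ar}
        fitted = self._teacher_forced(comps, exog, ar, t0, d2)
        r_e = float(np.sqrt(np.mean((targets - fitted) ** 2)))
        return comps, r_e, fitted

    def _teacher_forced(
        self, comps, exog_block, ar_block, t0, d2, y_series=None
    ) -> np.ndarray:
        """One-step-ahead predictions with measured lags everywhere."""
        f1 = comps["exog"].predict(exog_block)
        f2 = comps["ar"].predict(ar_block)
        if self.variant == "lssvm1":
            m1, m2 = self.weights
            return m1 * f1 + m2 * f2
        w1, w2, w3 = self.weights
        y = self.endog if y_series is None else np.asarray(y_series, float).ravel()
        out = np.empty_like(f1)
        for i, t in enumerate(range(t0, y.size)):
            f3 = self._local_prediction(y, t, d2)
            if f3 is None:
                s = w1 + w2
                out[i] = (w1 * f1[i] + w2 * f2[i]) / s
            else:
                out[i] = w1 * f1[i] + w2 * f2[i] + w3 * f3
        return out

    def _local_prediction(self, y_hist: np.ndarray, t: int, d2: int) -> float | None:
        """LSSVM2 third term: linear LSSVM refit on the 4-sample window.

        Window samples are steps t-5..t-2 (0-based), each with input
        [y(j-1) .. y(j-d2)] of measured performance and target y(j).
        Returns None when any required lag precedes the series start.
        """
        lo = t + LOCAL_WINDOW_OFFSETS[0]
        if lo - d2 < 0 or t - d2 < 0:
            return None
        Xw = np.array(
            [[y_hist[t + off - lag] for lag in range(1, d2 + 1)]
             for off in LOCAL_WINDOW_OFFSETS]
        )
        yw = np.array([y_hist[t + off] for off in LOCAL_WINDOW_OFFSETS])
        comp = train_lssvm(Xw, yw, "linear", self.gamma_reg, self.sigma2)
        query = np.array([[y_hist[t - lag] for lag in range(1, d2 + 1)]])
        return float(comp.predict(query)[0])

    # -- structure identification -----------------------------------------

    def select_structure(
        self,
        grid: tuple[int, int] = (1, 15),
        tau: tuple[float, float] = (0.8, 0.2),
    ) -> StructureSearchResult:
        """Grid-search (d1, d2) minimizing J; ties broken by smaller d1+d2,
        then smaller d1."""
        lo, hi = grid
        d_values = np.arange(lo, hi + 1)
        p = self.exog.shape[1]
        ntheta_max = n_theta(hi, hi, p)
        J = np.full((d_values.size, d_values.size), np.nan)
        RE = np.full_like(J, np.nan)
        tau1, tau2 = tau
        best = None
        for i, d1 in enumerate(d_values):
            for j, d2 in enumerate(d_values):
                _, r_e, _ = self._train_at(int(d1), int(d2))
                RE[i, j] = r_e
                J[i, j] = tau1 * r_e + tau2 * n_theta(d1, d2, p) / ntheta_max
                key = (J[i, j], d1 + d2, d1)
                if best is None or key < best[0]:
                    best = (key, (int(d1), int(d2)))
        return StructureSearchResult(J, RE, d_values, d_values, tau, best[1])


class CtlNarxResults:
    """Fitted NARX LSSVM model: estimates, diagnostics and prediction."""

    def __init__(
        self,
        model: CtlNarx,
        components: dict[str, LssvmComponent],
        orders: tuple[int, int],
        structure: StructureSearchResult | None,
        train_rmse: float,
        fittedvalues: np.ndarray,
    ):
        self.model = model
        self.components = components
        self.orders = orders
        self.structure = structure
        self.train_rmse = train_rmse
        self.fittedvalues = fittedvalues

    # -- prediction --------------------------------------------------------

    def predict(self, exog, endog=None) -> np.ndarray:
        """Free-running prediction y~(k) over a feature stream.

        ``endog`` is the measured performance series of the same stream; it
        seeds the warm-up (the first d2 autoregressive lags) and, for
        LSSVM2, drives the per-step local regressor.  Without it the model
        free-runs from a neutral initial performance and LSSVM2 degrades to
        its first two terms (renormalized).
        """
        exog = _as_2d(exog)
        K = exog.shape[0]
        d1, d2 = self.orders
        y_meas = None if endog is None else np.asarray(endog, float).ravel()
        predictor = OnlinePredictor(self)
        out = np.empty(K)
        for t in range(K):
            measured_prev = None
            if y_meas is not None and t > 0:
                measured_prev = y_meas[t - 1]
            out[t] = predictor.step(exog[t], measured_prev)
        return out

    def predict_one_step(self, exog, endog) -> tuple[np.ndarray, int]:
        """One-step-ahead (series-parallel) prediction on a measured stream.

        All autoregressive slots read the *measured* performance ``endog``;
        returns ``(predictions, t0)`` where predictions cover steps
        t0..K-1 (earlier steps lack the required lags).
        """
        d1, d2 = self.orders
        exog_block, ar_block, _, t0 = build_narx_regressors(
            exog, endog, d1, d2
        )
        pred = self.model._teacher_forced(
            self.components, exog_block, ar_block, t0, d2, y_series=endog
        )
        return pred, t0

    def classify(self, y_hat, sigma_o: float, z: tuple[float, float, float]):
        """Discretize predicted performance into load classes 1..5."""
        return discretize_performance(y_hat, sigma_o, z)

    def evaluate(
        self, exog, y_true, sigma_o: float, z: tuple[float, float, float]
    ) -> ClassifierEvaluation:
        """Predict over a test stream and score 5-class agreement."""
        y_true = np.asarray(y_true, float).ravel()
        y_hat = self.predict(exog, endog=y_true)
        pred = self.classify(y_hat, sigma_o, z)
        target = discretize_performance(y_true, sigma_o, z)
        return ClassifierEvaluation.from_labels(pred, target)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        d1, d2 = self.orders
        lines = [
            "               NARX LSSVM load classifier",
            "=" * 58,
            f"variant:            {m.variant.upper()}",
            f"orders (d1, d2):    ({d1}, {d2})",
            f"combination weights:{tuple(round(w, 4) for w in m.weights)}",
            f"kernel:             RBF(sigma2={m.sigma2:g}) + linear, gamma={m.gamma_reg:g}",
            f"training samples:   {self.components['exog'].X.shape[0]}"
            f" (series length {m.endog.size})",
            f"exogenous dim:      {m.exog.shape[1]} (regressors {m.exog.shape[1] * d1 + 2 * d2})",
            f"training RMSE r_e:  {self.train_rmse:.4f}",
        ]
        if self.structure is not None:
            lines.append(
                f"structure search:   J* = {self.structure.J.min():.4f} over "
                f"{self.structure.n_candidates} candidates"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_prediction(self, y_true, y_hat, ax=None):
        """Overlay measured and predicted performance (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(np.asarray(y_true, float), label="measured y", lw=1)
        ax.plot(np.asarray(y_hat, float), label="predicted y~", lw=1)
        ax.set_xlabel("epoch (10 s)")
        ax.set_ylabel("performance")
        ax.legend(loc="lower left", fontsize=8)
        return ax

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        def comp_dict(c: LssvmComponent) -> dict:
            return {
                "X": c.X.tolist(),
                "alpha": c.alpha.tolist(),
                "bias": c.bias,
                "kernel": c.kernel,
                "sigma2": c.sigma2,
                "gamma_reg": c.gamma_reg,
            }

        payload = {
            "variant": self.model.variant,
            "orders": list(self.orders),
            "weights": list(self.model.weights),
            "gamma_reg": self.model.gamma_reg,
            "sigma2": self.model.sigma2,
            "train_rmse": self.train_rmse,
            "endog": self.model.endog.tolist(),
            "exog": self.model.exog.tolist(),
            "components": {k: comp_dict(c) for k, c in self.components.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "CtlNarxResults":
        with open(path) as fh:
            d = json.load(fh)
        model = CtlNarx(
            d["endog"],
            d["exog"],
            variant=d["variant"],
            orders=tuple(d["orders"]),
            weights=tuple(d["weights"]),
            gamma_reg=d["gamma_reg"],
            sigma2=d["sigma2"],
        )
        comps = {
            k: LssvmComponent(
                np.asarray(c["X"], float),
                np.asarray(c["alpha"], float),
                c["bias"],
                c["kernel"],
                c["sigma2"],
                c["gamma_reg"],
            )
            for k, c in d["components"].items()
        }
        exog, ar, targets, t0 = build_narx_regressors(
            model.exog, model.endog, *model.orders
        )
        fitted = model._teacher_forced(comps, exog, ar, t0, model.orders[1])
        return cls(model, comps, tuple(d["orders"]), None, d["train_rmse"], fitted)


class OnlinePredictor:
    """Stepwise NARX predictor maintaining its own lag histories.

    Feed one feature vector per step (plus the previous step's measured
    performance when available); used both by batch `predict` and by the
    closed-loop simulation where features arrive one epoch at a time.
    """

    def __init__(self, results: CtlNarxResults):
        self.res = results
        self.model = results.model
        self.d1, self.d2 = results.orders
        self.x_hist: list[np.ndarray] = []
        self.fb_hist: list[float] = []  # autoregressive feedback values
        self.y_meas_hist: list[float] = []  # measured performance (lagged by 1)
        self.t = 0

    def _lagged_x(self) -> np.ndarray:
        rows = []
        for lag in range(self.d1):
            idx = self.t - lag
            idx = max(idx, 0)
            rows.append(self.x_hist[idx])
        return np.concatenate(rows)

    def _fb_value(self, s: int) -> float:
        """Autoregressive lag value at step index s.

        Warm-up (the first d2 steps) reads the measured performance when it
        has been supplied; later steps read the model's own predictions
        (free run).  Indices before the series start fall back to the
        earliest known value, or the neutral mid-scale 0.5.
        """
        if s < 0:
            if self.y_meas_hist:
                return self.y_meas_hist[0]
            return self.fb_hist[0] if self.fb_hist else 0.5
        if s < self.d2 and s < len(self.y_meas_hist):
            return self.y_meas_hist[s]
        return self.fb_hist[s]

    def _lagged_fb(self) -> np.ndarray:
        return np.array([self._fb_value(self.t - lag) for lag in range(1, self.d2 + 1)])

    def step(self, x_t: np.ndarray, measured_prev: float | None = None) -> float:
        """Predict y~(t) given x'(t) and, optionally, measured y(t-1)."""
        if measured_prev is not None:
            self.y_meas_hist.append(float(measured_prev))
        self.x_hist.append(np.asarray(x_t, float).ravel())
        f1 = float(self.res.components["exog"].predict(self._lagged_x()[None, :])[0])
        f2 = float(self.res.components["ar"].predict(self._lagged_fb()[None, :])[0])
        weights = self.model.weights
        if self.model.variant == "lssvm1":
            m1, m2 = weights
            y_hat = m1 * f1 + m2 * f2
        else:
            w1, w2, w3 = weights
            f3 = self._local_term()
            if f3 is None:
                s = w1 + w2
                y_hat = (w1 * f1 + w2 * f2) / s
            else:
                y_hat = w1 * f1 + w2 * f2 + w3 * f3
        self.fb_hist.append(float(y_hat))
        self.t += 1
        return float(y_hat)

    def _local_term(self) -> float | None:
        """Four-sample local linear regressor on measured performance lags."""
        y = np.asarray(self.y_meas_hist, float)  # y[0..t-1] measured
        t = self.t
        d2 = self.d2
        lo = t + LOCAL_WINDOW_OFFSETS[0]
        if y.size < t or lo - d2 < 0 or t - d2 < 0:
            return None
        return self.model._local_prediction(y, t, d2)


def select_structure(x, y, variant: str = "lssvm1", **kwargs) -> StructureSearchResult:
    """Functional wrapper around :meth:`CtlNarx.select_structure`."""
    return CtlNarx(y, x, variant=variant).select_structure(**kwargs)
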