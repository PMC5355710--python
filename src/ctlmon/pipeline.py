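"""End-to-end orchestration: preprocess -> reduce -> label -> train -> evaluate -> simulate.

`run_pipeline` chains the stages on a two-session dataset (train on
session 1, test on session 2) and emits a single JSON-serializable report
with all metrics and provenance (config echo, seed, package version).  A
stage failure is recorded with its cause and downstream stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np

from . import __version__
from .automation import SessionPool, run_simulation
from .config import PipelineConfig
from .evaluation import ClassifierEvaluation
from .features import FeatureReducer, AesParams
from .narx import CtlNarx
from .performance import discretize_performance
from .preprocess import RawRecording, extract_features
from .synthetic import LoadSchedule


def _session_features(session: dict, config: PipelineConfig, report: dict) -> Any:
    """Resolve a session dict to a reduced feature matrix source."""
    if "reduced" in session:
        return ("reduced", session["reduced"])
    if "features" in session:
        return ("features", session["features"])
    if "raw" in session:
        rec: RawRecording = session["raw"]
        feats = extract_features(
            rec,
            epoch_len=config.epoch_len,
            cutoff=config.filter_cutoff,
            filter_order=config.filter_order,
            rls_order=config.rls_order,
            rls_lambda=config.rls_lambda,
            bands={k: tuple(v) for k, v in config.bands.items()},
        )
        return ("features", feats)
    raise ValueError("session must provide 'reduced', 'features' or 'raw'")


def run_pipeline(config: PipelineConfig, session1: dict, session2: dict) -> dict:
    """Execute the full chain; each session dict holds 'y' plus one of
    'reduced' (12-col), 'features' (56-col) or 'raw' (RawRecording)."""
    report: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            if any(s["status"] == "failed" for s in report["stages"].values()):
                report["stages"][name] = {"status": "skipped"}
                return None
            try:
                out = fn()
                report["stages"][name] = {"status": "ok"}
                return out
            except Exception as exc:  # noqa: BLE001 - report and halt downstream
                report["stages"][name] = {"status": "failed", "cause": repr(exc)}
                return None
        return deco

    y1 = np.asarray(session1["y"], float)
    y2 = np.asarray(session2["y"], float)

    @stage("preprocess")
    def sources():
        return _session_features(session1, config, report), _session_features(
            session2, config, report
        )

    @stage("reduce")
    def reduced():
        (kind1, f1), (kind2, f2) = sources
        if kind1 == "reduced":
            return f1, f2
        g1, g2, g3 = config.aes_gains
        reducer = FeatureReducer(
            AesParams(config.aes_a, config.aes_b, g1, g2, g3),
            n_neighbors=config.lpp_neighbors,
        )
        r1 = reducer.fit_transform(f1, y1)
        return r1, reducer.transform(f2)

    @stage("label")
    def labels():
        # sigma_o over the participant's concatenated sessions
        sigma_o = float(np.std(np.concatenate([y1, y2])))
        z = tuple(config.z)
        c1 = discretize_performance(y1, sigma_o, z)
        c2 = discretize_performance(y2, sigma_o, z)
        report["labels"] = {
            "sigma_o": sigma_o,
            "z": list(z),
            "train_class_counts": np.bincount(c1, minlength=6)[1:].tolist(),
            "test_class_counts": np.bincount(c2, minlength=6)[1:].tolist(),
        }
        return sigma_o, z, c1, c2

    @stage("train")
    def fitted():
        r1, _ = reduced
        model = CtlNarx(
            y1,
            r1.to_numpy() if hasattr(r1, "to_numpy") else r1,
            variant=config.variant,
            orders=tuple(config.orders) if config.orders else None,
            gamma_reg=config.gamma_reg,
            sigma2=config.sigma2,
        )
        res = model.fit(grid=tuple(config.grid), tau=tuple(config.tau))
        report["model"] = {
            "variant": config.variant,
            "orders": list(res.orders),
            "train_rmse": res.train_rmse,
        }
        return res

    @stage("evaluate")
    def evaluation() -> ClassifierEvaluation:
        _, r2 = reduced
        sigma_o, z, _, _ = labels
        ev = fitted.evaluate(
            r2.to_numpy() if hasattr(r2, "to_numpy") else r2, y2, sigma_o, z
        )
        report["evaluation"] = ev.to_dict()
        return ev

    @stage("simulate")
    def simulation():
        _, r2 = reduced
        sigma_o, z, _, _ = labels
        schedule = LoadSchedule(tuple(config.schedule_counts), config.schedule_block_len)
        pool = SessionPool.from_session(
            r2.to_numpy() if hasattr(r2, "to_numpy") else r2, y2, schedule
        )
        sim_schedule = LoadSchedule(
            tuple(config.schedule_counts),
            max(1, config.sim_steps // len(config.schedule_counts)),
        )
        common = dict(
            pool=pool,
            results=fitted,
            sigma_o=sigma_o,
            z=z,
            steps=config.sim_steps,
            runs=config.sim_runs,
            schedule=sim_schedule,
            gain=config.controller_gain,
            thresholds=tuple(config.controller_thresholds),
        )
        without = run_simulation(controller=None, seed=config.seed, **common)
        with_aa = run_simulation(
            controller=config.controller, seed=config.seed + 1000, **common
        )
        report["simulation"] = {
            "controller": config.controller,
            "without_aa": without.summaries(),
            "with_aa": with_aa.summaries(),
        }
        return without, with_aa

    del sources, simulation, evaluation  # names kept for readability only
    report["report_hash"] = hashlib.sha256(
        json.dumps(report, sort_keys=True, default=str).encode()
    ).hexdigest()
    return report
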