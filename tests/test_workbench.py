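"""I/O schemas, configuration round-trips, pipeline report and CLI."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from ctlmon import (
    PipelineConfig,
    RawRecording,
    SchemaError,
    generate_raw_recording,
    generate_session_features,
    run_pipeline,
)
from ctlmon import io as ctio
from ctlmon.cli import main as cli_main
from ctlmon.performance import PARTICIPANT_Z
from ctlmon.preprocess import CANONICAL_CHANNELS, FEATURE_COLUMNS
from ctlmon.synthetic import LoadSchedule


class TestConfig:
    def test_defaults_match_method_constants(self):
        cfg = PipelineConfig()
        expected = {
            "epoch_len": 10.0,
            "filter_cutoff": 40.0,
            "filter_order": 3,
            "rls_order": 3,
            "rls_lambda": 0.99,
            "aes_a": 1.0,
            "aes_b": 2.2,
            "aes_gains": (0.2, 0.1, 0.3),
            "gamma_reg": 100.0,
            "sigma2": 500.0,
            "lssvm1_weights": (0.1, 0.9),
            "lssvm2_weights": (0.02, 0.18, 0.8),
            "grid": (1, 15),
            "tau": (0.8, 0.2),
            "z": tuple(PARTICIPANT_Z["A"]),
            "controller_thresholds": (0.2, 0.8),
            "controller_gain": 1.0,
            "set_point": 1.0,
            "hold_steps": 2,
            "sim_steps": 90,
            "sim_runs": 10,
            "schedule_counts": (1, 3, 4, 4, 3, 1),
        }
        for key, value in expected.items():
            assert getattr(cfg, key) == value, key
        assert cfg.bands == {
            "delta": [1.0, 4.0], "theta": [5.0, 8.0], "alpha": [9.0, 12.0],
            "beta": [13.0, 32.0], "gamma": [33.0, 40.0],
        }

    def test_yaml_roundtrip_lossless(self, tmp_path):
        cfg = PipelineConfig(orders=(3, 5), participant="B", seed=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        again = PipelineConfig.from_yaml(path)
        assert again == cfg
        # and the file is plain YAML
        assert yaml.safe_load(path.read_text())["seed"] == 7


class TestRawIo:
    def test_raw_csv_roundtrip(self, tmp_path):
        rec = generate_raw_recording(
            schedule=LoadSchedule(counts=(1,), block_len=1), seed=0
        )
        path = tmp_path / "raw.csv"
        ctio.write_raw_csv(rec, path)
        back = ctio.read_session(path)
        assert back.labels == CANONICAL_CHANNELS
        assert back.fs == pytest.approx(rec.fs)
        assert np.allclose(back.samples, rec.samples)

    def test_scrambled_channel_order_restored(self):
        rng = np.random.default_rng(0)
        perm = rng.permutation(13)
        labels = tuple(CANONICAL_CHANNELS[i] for i in perm)
        samples = rng.standard_normal((13, 100))
        rec = RawRecording(samples, 500.0, labels).reorder_canonical()
        assert rec.labels == CANONICAL_CHANNELS
        for i, lb in enumerate(labels):
            assert np.array_equal(rec.channel(lb), samples[i])

    def test_unknown_channel_label_rejected(self):
        with pytest.raises(SchemaError, match="Fp1"):
            RawRecording(np.zeros((1, 10)), 500.0, ("Fp1",)).reorder_canonical()


class TestFeatureIo:
    def test_feature_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.standard_normal((8, 56)), columns=list(FEATURE_COLUMNS)
        )
        df.index.name = "epoch"
        path = tmp_path / "features.csv"
        ctio.write_features_csv(df, path)
        back = ctio.read_features_csv(path)
        assert np.allclose(back.to_numpy(), df.to_numpy())

    def test_missing_hr_column_named_in_error(self, tmp_path):
        df = pd.DataFrame(np.zeros((3, 55)), columns=list(FEATURE_COLUMNS[:-1]))
        path = tmp_path / "bad.csv"
        df.to_csv(path, index_label="epoch")
        with pytest.raises(SchemaError, match="HR"):
            ctio.read_features_csv(path)


@pytest.fixture(scope="module")
def sessions():
    f1, y1, _ = generate_session_features(seed=0)
    f2, y2, _ = generate_session_features(seed=1)
    return {"reduced": f1, "y": y1}, {"reduced": f2, "y": y2}


class TestPipeline:
    def test_report_conservation_and_determinism(self, sessions):
        cfg = PipelineConfig(orders=(3, 5))
        rep = run_pipeline(cfg, *sessions)
        assert all(s["status"] == "ok" for s in rep["stages"].values())
        total = np.sum(rep["evaluation"]["confusion_matrix"])
        assert total == len(sessions[1]["y"])
        rep2 = run_pipeline(cfg, *sessions)
        assert rep["report_hash"] == rep2["report_hash"]

    def test_variant_comparison_favors_measured_feedback(self, sessions):
        acc = {}
        for variant in ("lssvm1", "lssvm2"):
            cfg = PipelineConfig(orders=(3, 5), variant=variant)
            acc[variant] = run_pipeline(cfg, *sessions)["evaluation"]["accuracy"]
        assert acc["lssvm2"] > acc["lssvm1"]

    def test_stage_failure_skips_downstream(self, sessions):
        cfg = PipelineConfig(orders=(3, 5), z=(2.3, 2.7, 3.0))
        bad_session2 = {"reduced": sessions[1]["reduced"], "y": sessions[1]["y"][:10]}
        rep = run_pipeline(cfg, sessions[0], bad_session2)
        statuses = [s["status"] for s in rep["stages"].values()]
        assert "failed" in statuses
        i = statuses.index("failed")
        assert all(s == "skipped" for s in statuses[i + 1 :])


class TestCli:
    def test_synth_train_evaluate_simulate_chain(self, tmp_path):
        runner = CliRunner()
        out = tmp_path
        cfg = PipelineConfig(orders=(3, 5))
        cfg_path = out / "cfg.yaml"
        cfg.to_yaml(cfg_path)

        r = runner.invoke(
            cli_main, ["synth", "--sessions", "2", "--seed", "0",
                       "--out-dir", str(out)],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            ["train", "--reduced", str(out / "session1_reduced.csv"),
             "--labels", str(out / "session1_labels.csv"),
             "--variant", "lssvm2", "--config", str(cfg_path),
             "--out", str(out / "model.json")],
        )
        assert r.exit_code == 0, r.output
        assert "LSSVM2" in r.output
        r = runner.invoke(
            cli_main,
            ["evaluate", "--model", str(out / "model.json"),
             "--reduced", str(out / "session2_reduced.csv"),
             "--labels", str(out / "session2_labels.csv"),
             "--config", str(cfg_path),
             "--report", str(out / "report.json")],
        )
        assert r.exit_code == 0, r.output
        import json

        report = json.loads((out / "report.json").read_text())
        assert np.sum(report["confusion_matrix"]) == 540
        assert report["accuracy"] > 0.5
        r = runner.invoke(
            cli_main,
            ["simulate", "--model", str(out / "model.json"),
             "--pool", str(out / "session2_reduced.csv"),
             "--pool-labels", str(out / "session2_labels.csv"),
             "--controller", "rule", "--runs", "3", "--seed", "1",
             "--config", str(cfg_path), "--out", str(out / "sim.json")],
        )
        assert r.exit_code == 0, r.output
        sim = json.loads((out / "sim.json").read_text())
        assert sim["with_aa"]["y_mean"] > sim["without_aa"]["y_mean"]

    def test_run_all_reports_accuracy(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main, ["run-all", "--seed", "0", "--out", str(tmp_path / "rep.json")]
        )
        assert r.exit_code == 0, r.output
        assert "test accuracy" in r.output
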