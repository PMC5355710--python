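"""Reading and writing recordings, feature matrices and label tables.

Raw recordings come either as EDF files (channel labels F3..O2, ECG, EOG;
read through :mod:`mne` when installed) or as long-form CSV with columns
``time_s, channel, value_uV``.  Feature matrices are CSVs with an
``epoch`` column plus the 56 canonical feature columns (or the 12 reduced
ones); label tables carry ``epoch, s_e, s_t, s_a, y, C``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import (
    CANONICAL_CHANNELS,
    FEATURE_COLUMNS,
    RawRecording,
    SchemaError,
)
from .features import REDUCED_COLUMNS


def read_raw_csv(path) -> RawRecording:
    """Long-form CSV (time_s, channel, value_uV) -> canonical RawRecording."""
    df = pd.read_csv(path)
    required = {"time_s", "channel", "value_uV"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"raw CSV missing columns: {sorted(missing)}")
    unknown = sorted(set(df["channel"]) - set(CANONICAL_CHANNELS))
    if unknown:
        raise SchemaError(f"unknown channel labels: {unknown}")
    wide = df.pivot(index="time_s", columns="channel", values="value_uV").sort_index()
    missing_ch = [c for c in CANONICAL_CHANNELS if c not in wide.columns]
    if missing_ch:
        raise SchemaError(f"missing channels: {missing_ch}")
    t = wide.index.to_numpy(float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise SchemaError("time_s must be a uniform grid")
    fs = 1.0 / dt[0]
    samples = wide[list(CANONICAL_CHANNELS)].to_numpy(float).T
    return RawRecording(samples, float(round(fs, 6)), CANONICAL_CHANNELS)


def write_raw_csv(rec: RawRecording, path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    frames = [
        pd.DataFrame({"time_s": t, "channel": lb, "value_uV": rec.samples[i]})
        for i, lb in enumerate(rec.labels)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_raw_edf(path) -> RawRecording:
    """EDF recording -> canonical RawRecording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    unknown = [lb for lb in labels if lb not in CANONICAL_CHANNELS]
    if unknown:
        raise SchemaError(f"unknown channel labels: {unknown}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    rec = RawRecording(data, float(raw.info["sfreq"]), labels)
    return rec.reorder_canonical()


def read_session(path, fmt: str | None = None) -> RawRecording:
    """Dispatch on format ('edf' | 'csv', inferred from the suffix by default)."""
    fmt = fmt or str(path).rsplit(".", 1)[-1].lower()
    if fmt == "edf":
        return read_raw_edf(path)
    if fmt == "csv":
        return read_raw_csv(path)
    raise ValueError(f"unknown raw format {fmt!r}")


def _read_matrix(path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"feature CSV missing columns: {missing}")
    out = df.set_index("epoch")[list(columns)] if "epoch" in df.columns else df[list(columns)]
    out.index.name = "epoch"
    return out


def read_features_csv(path) -> pd.DataFrame:
    """Full 56-column feature matrix."""
    return _read_matrix(path, FEATURE_COLUMNS)


def read_reduced_csv(path) -> pd.DataFrame:
    """Reduced 12-column salient feature matrix."""
    return _read_matrix(path, REDUCED_COLUMNS)


def write_features_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="epoch")


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("y", "C") if c not in df.columns]
    if missing:
        raise SchemaError(f"label CSV missing columns: {missing}")
    return df


def write_labels_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="epoch")
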