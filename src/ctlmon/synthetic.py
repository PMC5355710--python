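"""Synthetic operator sessions with the statistical structure the method assumes.

The study's human recordings are not public, so every pipeline stage is
exercised on simulated sessions that emulate their key statistics:

* a six-block task-load schedule n(k) = 1, 3, 4, 4, 3, 1 (15 min, i.e.
  90 ten-second epochs, per block; 540 epochs per session),
* per-channel salient features whose correlation with performance matches
  the participant-average pattern of the real study (|r| around 0.74 for
  the best frontal/parietal channels, around 0.32 for heart rate), with
  AR(1) temporal noise,
* performance y(k) declining with load, clipped to [0, 1], with AR(1)
  noise, discretized into five load classes,
* raw multichannel recordings (band-limited EEG carriers with
  load-modulated amplitudes, a blink-driven EOG with frontal leakage, an
  impulse-train ECG with load-dependent rate) for testing the signal
  conditioning chain end to end,
* a linear NARX process with known orders, the oracle for structure
  identification and predictor tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .features import REDUCED_COLUMNS
from .performance import PARTICIPANT_Z, discretize_performance
from .preprocess import CANONICAL_CHANNELS, DEFAULT_BANDS, EEG_CHANNELS, RawRecording

#: participant-average feature-performance |r| of the real study, used as
#: calibration targets for the default profile (channels F3..O2 then HR)
DEFAULT_CORR_TARGETS: dict[str, float] = {
    "F3": 0.7356, "F4": 0.6852, "Fz": 0.7381, "C3": 0.7422, "C4": 0.6940,
    "Cz": 0.7623, "P3": 0.7609, "P4": 0.7422, "Pz": 0.7867, "O1": 0.7481,
    "O2": 0.7177, "HR": 0.3161,
}


@dataclass
class LoadSchedule:
    """Block task-count schedule; counts are drawn from {1, 3, 4}."""

    counts: tuple[int, ...] = (1, 3, 4, 4, 3, 1)
    block_len: int = 90  # epochs per block (90 x 10 s = 15 min)

    def __post_init__(self) -> None:
        if any(c not in (1, 3, 4) for c in self.counts):
            raise ValueError("task counts must lie in {1, 3, 4}")
        if self.block_len < 1:
            raise ValueError("block length must be positive")

    @property
    def total_epochs(self) -> int:
        return len(self.counts) * self.block_len

    def expand(self) -> np.ndarray:
        """Per-epoch task count n(k)."""
        return np.repeat(self.counts, self.block_len)


@dataclass
class ParticipantProfile:
    """Statistical profile of one simulated operator.

    ``corr_targets`` sets the intended absolute feature-performance
    correlation per channel; the generator converts each target into a
    noise level analytically (the larger the target, the less channel
    noise).  Performance follows base - slope*n(k) plus AR(1) noise.
    """

    corr_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORR_TARGETS)
    )
    perf_base: float = 1.05
    perf_slope: float = 0.135
    perf_noise_sd: float = 0.05
    ar_phi: float = 0.6
    z: tuple[float, float, float] = PARTICIPANT_Z["A"]
    hr_baseline: float = 65.0  # beats/min at the lowest load
    hr_load_gain: float = 8.0  # beats/min per extra manual task
    blink_rate: float = 12.0  # events/min
    blink_leakage: dict[str, float] = field(
        default_factory=lambda: {"F3": 0.45, "F4": 0.45, "Fz": 0.5,
                                 "C3": 0.12, "C4": 0.12, "Cz": 0.15}
    )
    #: raw-signal band carrier amplitudes (uV r.m.s.) and their relative
    #: modulation per extra manual task
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"delta": 6.0, "theta": 5.0, "alpha": 8.0,
                                 "beta": 3.0, "gamma": 1.5}
    )
    band_load_modulation: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.0, "theta": 0.15, "alpha": -0.18,
                                 "beta": 0.05, "gamma": 0.0}
    )


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal s.d. ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = rng.normal(0.0, innov_sd, size=n)
    out = np.empty(n)
    prev = rng.normal(0.0, sd)
    for k in range(n):
        prev = phi * prev + e[k]
        out[k] = prev
    return out


def generate_session_features(
    profile: ParticipantProfile | None = None,
    schedule: LoadSchedule | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate one session at the salient-feature level.

    Returns ``(features, y, C)``: a K x 12 DataFrame (11 channel scalars +
    HR, already on the reduced scale), the performance series and the
    5-class labels (discretized with the profile's z coefficients and the
    session s.d. of y).
    """
    if profile is None:
        profile = ParticipantProfile()
    if schedule is None:
        schedule = LoadSchedule()
    rng = np.random.default_rng(seed)
    load = schedule.expand().astype(float)
    K = load.size
    load_c = load - load.mean()

    y = np.clip(
        profile.perf_base
        - profile.perf_slope * load
        + _ar1(K, profile.ar_phi, profile.perf_noise_sd, rng),
        0.0,
        1.0,
    )

    # analytic noise calibration: feature = -load_c + AR(1) noise; the
    # achievable |corr(feature, y)| is bounded by |corr(load, y)|, so the
    # noise s.d. is chosen from the target attenuation factor.
    r_ly = abs(float(np.corrcoef(load, y)[0, 1]))
    var_l = float(load_c.var())
    cols = {}
    for ch, target in profile.corr_targets.items():
        atten = min(target / r_ly, 0.999)
        noise_var = var_l * (1.0 / atten**2 - 1.0)
        cols[ch] = -load_c + _ar1(K, profile.ar_phi, float(np.sqrt(noise_var)), rng)
    features = pd.DataFrame(cols, columns=list(REDUCED_COLUMNS))
    features.index.name = "epoch"

    sigma_o = float(np.std(y))
    C = discretize_performance(y, sigma_o, profile.z)
    return features, y, C


def generate_raw_recording(
    profile: ParticipantProfile | None = None,
    schedule: LoadSchedule | None = None,
    fs: float = 500.0,
    seed: int = 0,
    epoch_len: float = 10.0,
) -> RawRecording:
    """Simulate the raw 13-channel recording for the conditioning chain.

    EEG channels are sums of band-limited noise carriers whose band
    amplitudes are modulated by the task load; the EOG is a blink pulse
    train that leaks (scaled) into the frontal channels; the ECG is an
    R-wave impulse train whose rate increases with load.
    """
    if profile is None:
        profile = ParticipantProfile()
    if schedule is None:
        schedule = LoadSchedule(block_len=6)  # 6 epochs/block keeps tests light
    rng = np.random.default_rng(seed)
    load = schedule.expand().astype(float)
    n_per = int(round(epoch_len * fs))
    n = load.size * n_per
    load_t = np.repeat(load, n_per)  # per-sample load

    # band-limited carriers with load-modulated amplitudes; by default theta
    # amplitude increases with load and alpha decreases
    base_amp = profile.band_amplitudes
    modulation = profile.band_load_modulation
    eeg = np.zeros((len(EEG_CHANNELS), n))
    for band, (lo, hi) in DEFAULT_BANDS.items():
        sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
        gain_t = base_amp[band] * (1.0 + modulation[band] * (load_t - 1.0))
        for c in range(len(EEG_CHANNELS)):
            carrier = sps.sosfilt(sos, rng.standard_normal(n))
            carrier /= carrier.std()
            eeg[c] += gain_t * carrier

    # blink pulse train on the EOG channel, leaking into frontal EEG
    eog = np.zeros(n)
    pulse_len = int(round(0.3 * fs))
    pulse = 150.0 * np.hanning(pulse_len)
    n_blinks = rng.poisson(profile.blink_rate * (n / fs) / 60.0)
    starts = rng.integers(0, max(1, n - pulse_len), size=n_blinks)
    for s in starts:
        eog[s : s + pulse_len] += pulse
    eog += 5.0 * rng.standard_normal(n)
    for ch, leak in profile.blink_leakage.items():
        eeg[EEG_CHANNELS.index(ch)] += leak * eog

    # ECG: R-wave spikes at a load-dependent rate
    ecg = np.zeros(n)
    wave_len = int(round(0.04 * fs))
    rwave = 800.0 * np.hanning(wave_len)
    t = 0.0
    while t < n / fs:
        k = min(int(t / epoch_len), load.size - 1)
        hr = profile.hr_baseline + profile.hr_load_gain * (load[k] - 1.0)
        idx = int(round(t * fs))
        ecg[idx : idx + wave_len] += rwave[: max(0, min(wave_len, n - idx))]
        t += 60.0 / hr
    ecg += 10.0 * rng.standard_normal(n)

    samples = np.vstack([eeg, ecg[None, :], eog[None, :]])
    return RawRecording(samples, fs, CANONICAL_CHANNELS)


def generate_narx_process(
    d1_true: int = 2,
    d2_true: int = 4,
    exog_coeffs: tuple[float, ...] = (0.5, 0.4),
    ar_coeffs: tuple[float, ...] = (0.3, 0.1, 0.05, 0.35),
    noise_sd: float = 0.05,
    length: int = 300,
    seed: int = 0,
    exog_phi: float = 0.5,
    offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear NARX process with known true orders (oracle for model tests).

    y(k) = offset + sum_i a_i x(k-i+1) + sum_j c_j y(k-j) + N(0, noise_sd^2),
    with x an AR(1) exogenous driver of coefficient ``exog_phi``.  Raises
    for unstable AR coefficients (roots of the AR characteristic polynomial
    on or outside the unit circle).
    """
    if len(exog_coeffs) != d1_true or len(ar_coeffs) != d2_true:
        raise ValueError("coefficient vectors must match the true orders")
    poly = np.concatenate([[1.0], -np.asarray(ar_coeffs, float)])
    if d2_true > 0 and np.any(np.abs(np.roots(poly)) >= 1.0 - 1e-12):
        raise ValueError("unstable autoregressive coefficients")
    rng = np.random.default_rng(seed)
    x = _ar1(length, exog_phi, 1.0, rng)
    y = np.zeros(length)
    noise = rng.normal(0.0, noise_sd, size=length)
    for k in range(length):
        acc = offset + noise[k]
        for i, a in enumerate(exog_coeffs):
            if k - i >= 0:
                acc += a * x[k - i]
        for j, c in enumerate(ar_coeffs, start=1):
            if k - j >= 0:
                acc += c * y[k - j]
        y[k] = acc
    return x, y
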