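"""Signal conditioning: filtering, RLS ocular removal, epoching, spectra, HR."""

import numpy as np
import pytest
from scipy import signal as sps

from ctlmon import (
    RawRecording,
    RlsFilterState,
    PowerSpectrum,
    assemble_and_normalize,
    band_powers,
    compute_hr,
    epoch_psd,
    epoch_signal,
    lowpass_filter,
    remove_eog_rls,
)
from ctlmon.preprocess import DEFAULT_BANDS, FEATURE_COLUMNS, normalize_features

FS = 500.0


def _rec(channels, fs=FS, labels=None):
    channels = np.atleast_2d(np.asarray(channels, float))
    if labels is None:
        labels = tuple(f"F{i}" for i in range(3, 3 + channels.shape[0]))
        labels = ("F3",) if channels.shape[0] == 1 else labels
    return RawRecording(channels, fs, labels)


class TestLowpass:
    def test_dc_and_zero_pass_unchanged(self):
        dc = np.full(2000, 7.5)
        zero = np.zeros(2000)
        out = lowpass_filter(_rec(np.vstack([dc, zero]), labels=("F3", "F4")))
        assert np.allclose(out.samples[0][500:], 7.5, rtol=1e-6)
        assert np.allclose(out.samples[1], 0.0)

    def test_stopband_sinusoid_matches_analytic_magnitude(self):
        # 3rd-order Butterworth: |H| = 1/sqrt(1 + (W/Wc)^6) with the
        # bilinear-transform frequency warping W = tan(pi f / fs)
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 100.0 * t)
        out = lowpass_filter(_rec(x)).samples[0]
        steady = out[int(2 * FS):]
        ratio = np.tan(np.pi * 100.0 / FS) / np.tan(np.pi * 40.0 / FS)
        expected = 1.0 / np.sqrt(1.0 + ratio**6)
        measured = np.sqrt(2.0) * steady.std()
        assert measured == pytest.approx(expected, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(_rec(np.zeros(100), fs=60.0), cutoff=40.0)


class TestRlsOcularFilter:
    def test_zero_reference_is_identity(self):
        rng = np.random.default_rng(0)
        eeg = rng.standard_normal(2000)
        out = remove_eog_rls(eeg, np.zeros(2000))
        assert np.array_equal(out, eeg)

    def test_pure_leakage_converges_to_coupling(self):
        rng = np.random.default_rng(1)
        eog = rng.standard_normal(5000)
        contaminated = 0.5 * eog
        state = RlsFilterState(order=1)
        cleaned = remove_eog_rls(contaminated, eog, state)
        assert state.h[0] == pytest.approx(0.5, abs=1e-3)
        tail = slice(2500, None)
        assert (
            np.mean(cleaned[tail] ** 2) / np.mean(contaminated[tail] ** 2) < 1e-4
        )

    def test_unit_forgetting_matches_batch_least_squares(self):
        # lambda = 1: recursion solves the same normal equations as batch OLS
        rng = np.random.default_rng(2)
        M = 3
        eog = rng.standard_normal(4000)
        h_true = np.array([0.6, -0.3, 0.1])
        leak = sps.lfilter(h_true, [1.0], eog)
        eeg = rng.standard_normal(4000) * 0.1 + leak
        state = RlsFilterState(order=M, lam=1.0)
        remove_eog_rls(eeg, eog, state)
        U = np.column_stack(
            [np.concatenate([np.zeros(m), eog[: eog.size - m]]) for m in range(M)]
        )
        h_ols, *_ = np.linalg.lstsq(U, eeg, rcond=None)
        assert np.allclose(state.h, h_ols, atol=1e-6)

    def test_injected_blink_attenuated_tenfold(self):
        rng = np.random.default_rng(3)
        n = int(60 * FS)
        sos = sps.butter(4, (1, 30), btype="bandpass", fs=FS, output="sos")
        eeg_truth = sps.sosfilt(sos, rng.standard_normal(n)) * 10
        eog = np.zeros(n)
        pulse = 150.0 * np.hanning(int(0.3 * FS))
        for s in rng.integers(0, n - pulse.size, size=12):
            eog[s : s + pulse.size] += pulse
        contaminated = eeg_truth + 0.5 * eog
        cleaned = remove_eog_rls(contaminated, eog)
        before = np.mean((contaminated - eeg_truth) ** 2)
        after = np.mean((cleaned - eeg_truth) ** 2)
        assert before / after >= 10.0


class TestEpoching:
    def test_session_epoch_count(self):
        rec = _rec(np.zeros(int(90 * 60 * FS)))
        assert len(epoch_signal(rec)) == 540

    @pytest.mark.parametrize("seconds,expected", [(10, 1), (25, 2)])
    def test_partial_tail_discarded(self, seconds, expected):
        rec = _rec(np.arange(int(seconds * FS), dtype=float))
        assert len(epoch_signal(rec)) == expected

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            epoch_signal(_rec(np.zeros(100)))

    def test_concatenated_epochs_reproduce_record_minus_tail(self):
        x = np.arange(int(25 * FS), dtype=float)
        eps = epoch_signal(_rec(x))
        rebuilt = np.concatenate([e.samples[0] for e in eps])
        assert np.array_equal(rebuilt, x[: rebuilt.size])


class TestSpectra:
    def test_bin_aligned_tone_concentrates_power(self):
        t = np.arange(int(10 * FS)) / FS
        spec = epoch_psd(np.sin(2 * np.pi * 10.0 * t), FS)
        assert spec.freqs.size == 400
        i = int(np.argmin(np.abs(spec.freqs - 10.0)))
        assert spec.power[i] / spec.power.sum() >= 0.99

    def test_zero_epoch_gives_zero_spectrum(self):
        spec = epoch_psd(np.zeros(int(10 * FS)), FS)
        assert np.all(spec.power == 0)

    def test_white_noise_satisfies_parseval(self):
        # full-band periodogram integrates to the time-domain mean square
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(10 * FS))
        f, pxx = sps.periodogram(x, FS, window="boxcar", detrend=False)
        assert np.sum(pxx) * (f[1] - f[0]) == pytest.approx(np.mean(x**2), rel=0.01)
        spec = epoch_psd(x, FS)
        lo = int(round(1.0 / (f[1] - f[0])))
        assert np.allclose(spec.power, pxx[lo : lo + 400])

    def test_wrong_epoch_length_rejected(self):
        with pytest.raises(ValueError):
            epoch_psd(np.zeros(123), FS)


class TestBandPowers:
    def test_uniform_spectrum_gives_equal_bands(self):
        freqs = np.round(np.arange(1.0, 41.0, 0.1), 1)
        bp = band_powers(PowerSpectrum(freqs, np.full(400, 3.5)))
        assert np.allclose(bp, 3.5)

    def test_alpha_tone_only_hits_alpha(self):
        freqs = np.round(np.arange(1.0, 41.0, 0.1), 1)
        power = np.zeros(400)
        power[np.argmin(np.abs(freqs - 10.0))] = 5.0
        bp = band_powers(PowerSpectrum(freqs, power))
        assert bp[2] > 0
        assert np.all(bp[[0, 1, 3, 4]] == 0)

    def test_delta_average_matches_bin_enumeration(self):
        freqs = np.round(np.arange(1.0, 41.0, 0.1), 1)
        power = np.zeros(400)
        power[np.argmin(np.abs(freqs - 2.0))] = 4.0
        power[np.argmin(np.abs(freqs - 3.0))] = 2.0
        lo, hi = DEFAULT_BANDS["delta"]
        expected = np.mean([power[i] for i in range(400) if lo <= freqs[i] <= hi])
        bp = band_powers(PowerSpectrum(freqs, power))
        assert bp[0] == pytest.approx(expected)

    def test_nonnegative_spectrum_gives_nonnegative_bands(self):
        rng = np.random.default_rng(5)
        freqs = np.round(np.arange(1.0, 41.0, 0.1), 1)
        bp = band_powers(PowerSpectrum(freqs, rng.uniform(0, 1, 400)))
        assert np.all(bp >= 0)


class TestHeartRate:
    @staticmethod
    def _ecg_with_peaks(times, duration=10.0):
        n = int(duration * FS)
        ecg = np.zeros(n)
        wave = 800.0 * np.hanning(int(0.04 * FS))
        for t0 in times:
            i = int(t0 * FS)
            ecg[i : i + wave.size] += wave[: n - i]
        return ecg

    @pytest.mark.parametrize(
        "rr,expected", [(1.0, 60.0), (0.5, 120.0)]
    )
    def test_constant_rr(self, rr, expected):
        times = np.arange(0.5, 9.5, rr)
        hr = compute_hr(self._ecg_with_peaks(times), FS)
        assert hr == pytest.approx(expected, rel=0.02)

    def test_mixed_rr_averages_instantaneous_rates(self):
        # RR 0.8 s and 1.0 s -> (75 + 60) / 2 = 67.5 beats/min
        hr = compute_hr(self._ecg_with_peaks([4.0, 4.8, 5.8]), FS)
        assert hr == pytest.approx(67.5, rel=0.02)

    def test_missing_peaks_marked_nan(self):
        assert np.isnan(compute_hr(np.zeros(int(10 * FS)), FS))


class TestAssembly:
    def test_shape_and_normalization(self):
        rng = np.random.default_rng(6)
        df = assemble_and_normalize(rng.uniform(1, 5, (20, 55)), rng.uniform(55, 95, 20))
        assert list(df.columns) == list(FEATURE_COLUMNS)
        assert df.shape == (20, 56)
        assert np.all(np.abs(df.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(df.std(axis=0, ddof=0) - 1) < 1e-9)

    def test_constant_column_zeroed_with_warning(self):
        rng = np.random.default_rng(7)
        with pytest.warns(UserWarning, match="zero-variance"):
            df = assemble_and_normalize(
                rng.uniform(1, 5, (15, 55)), np.full(15, 70.0)
            )
        assert np.all(df["HR"] == 0)

    def test_hr_gaps_forward_filled(self):
        rng = np.random.default_rng(8)
        hr = np.array([60.0, np.nan, 80.0, np.nan])
        df = assemble_and_normalize(
            rng.uniform(1, 5, (4, 55)), hr, normalize=False
        )
        assert np.array_equal(df["HR"].to_numpy(), [60.0, 60.0, 80.0, 80.0])

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(9)
        once = normalize_features(rng.uniform(0, 3, (30, 8)))
        twice = normalize_features(once)
        assert np.max(np.abs(twice - once)) < 1e-12
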