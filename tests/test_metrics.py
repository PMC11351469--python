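"""HR, HRV, spectral SNR, error metrics and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsediff.metrics import (
    BeatSeries,
    avnn,
    bland_altman,
    detect_beats,
    error_metrics,
    heart_rate,
    relative_improvement,
    sdnn,
    spectral_snr,
)
from pulsediff.signal_core import Waveform

from conftest import tone

FS = 30.0


def beats_from_ibis(ibis_s, fs=FS):
    times = np.concatenate([[0.0], np.cumsum(ibis_s)])
    return BeatSeries(np.round(times * fs * 100).astype(int), fs * 100)


class TestDetectBeats:
    def test_pure_tone_beat_count_and_ibis(self):
        w = Waveform(tone(1.0, FS, duration=10.0, phase=np.pi / 2), FS)
        b = detect_beats(w)
        assert 9 <= b.peak_indices.size <= 11
        np.testing.assert_allclose(b.ibis, 1.0, atol=1.0 / FS)

    def test_noise_robust_peak_count(self):
        """10 dB additive noise does not change the detected beat count."""
        clean = tone(1.0, FS, duration=10.0, phase=np.pi / 2)
        n_clean = detect_beats(Waveform(clean, FS)).peak_indices.size
        amp = np.std(clean) * 10 ** (-10 / 20)
        ok = 0
        for seed in range(20):
            noisy = clean + amp * np.random.default_rng(seed).standard_normal(clean.size)
            if detect_beats(Waveform(noisy, FS)).peak_indices.size == n_clean:
                ok += 1
        assert ok >= 18

    def test_constant_signal_empty(self):
        b = detect_beats(Waveform(np.ones(300), FS))
        assert b.peak_indices.size == 0
        assert np.isnan(heart_rate(b))


class TestHRAndHRV:
    @pytest.mark.parametrize(
        "ibis,expected_hr",
        [([1.0, 1.0, 1.0], 60.0), ([0.5, 0.5], 120.0), ([0.8, 1.0, 1.2], 60.0)],
    )
    def test_heart_rate(self, ibis, expected_hr):
        assert heart_rate(beats_from_ibis(ibis)) == pytest.approx(expected_hr, rel=1e-3)

    @pytest.mark.parametrize(
        "rr_ms,exp_avnn,exp_sdnn",
        [
            ([1000, 1000], 1000.0, 0.0),
            ([900, 1100], 1000.0, 141.42),
            ([800, 1000, 1200], 1000.0, 200.0),
        ],
    )
    def test_avnn_sdnn(self, rr_ms, exp_avnn, exp_sdnn):
        b = beats_from_ibis(np.asarray(rr_ms) / 1000.0)
        assert avnn(b) == pytest.approx(exp_avnn, rel=1e-3)
        assert sdnn(b) == pytest.approx(exp_sdnn, abs=0.5)

    def test_hr_avnn_identity(self, rng):
        ibis = rng.uniform(0.6, 1.2, size=10)
        b = beats_from_ibis(ibis)
        assert heart_rate(b) == pytest.approx(60000.0 / avnn(b))

    def test_insufficient_intervals(self):
        one_peak = BeatSeries(np.array([5]), FS)
        assert np.isnan(heart_rate(one_peak))
        assert np.isnan(avnn(one_peak))
        assert np.isnan(sdnn(beats_from_ibis([1.0])))


class TestSpectralSNR:
    def test_pure_tone_clamps_high(self):
        w = Waveform(tone(1.5, FS, duration=30.0), FS)
        assert spectral_snr(w, 1.5) == 60.0

    @given(k=st.floats(0.01, 100.0), seed=st.integers(0, 50))
    def test_amplitude_invariance(self, k, seed):
        rng = np.random.default_rng(seed)
        x = tone(1.2, FS, duration=20.0) + 0.5 * rng.standard_normal(600)
        a = spectral_snr(Waveform(x, FS), 1.2)
        b = spectral_snr(Waveform(k * x, FS), 1.2)
        assert a == pytest.approx(b, abs=1e-9)

    def test_matches_analytic_noise_partition_oracle(self):
        """Mean over 50 noise seeds within 1.5 dB of the closed-form value.

        For a unit tone at f0 plus white noise of known variance, the expected
        partition is P_sig = A^2/2 + PSD * w_sig and P_noise = PSD * w_noise,
        with PSD = var / (fs/2) and w_sig, w_noise the signal-window and
        remaining widths of the [0.5, 6] Hz analysis band.
        """
        f0, dur, sigma = 1.5, 30.0, 0.3
        n = int(dur * FS)
        clean = tone(f0, FS, duration=dur)
        vals = [
            spectral_snr(
                Waveform(clean + sigma * np.random.default_rng(s).standard_normal(n), FS),
                f0,
            )
            for s in range(50)
        ]
        psd = sigma**2 / (FS / 2)
        w_sig = 0.2 + 0.4  # f0 +- 0.1 and 2 f0 +- 0.2 windows
        w_noise = (6.0 - 0.5) - w_sig
        oracle = 20 * np.log10((0.5 + psd * w_sig) / (psd * w_noise))
        assert np.mean(vals) == pytest.approx(oracle, abs=1.5)

    def test_monotone_in_noise_level(self):
        clean = tone(1.2, FS, duration=20.0)
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(clean.size)
        snrs = [
            spectral_snr(Waveform(clean + a * noise, FS), 1.2) for a in (0.1, 0.3, 1.0)
        ]
        assert snrs[0] > snrs[1] > snrs[2]

    def test_log_base_switch(self):
        rng = np.random.default_rng(1)
        x = tone(1.0, FS, duration=20.0) + 0.5 * rng.standard_normal(600)
        w = Waveform(x, FS)
        assert spectral_snr(w, 1.0, log_base_20=True) == pytest.approx(
            2.0 * spectral_snr(w, 1.0, log_base_20=False)
        )

    def test_f0_out_of_band_rejected(self):
        with pytest.raises(ValueError):
            spectral_snr(Waveform(np.zeros(300), FS), 0.5)


class TestErrorMetrics:
    def test_identical_lists(self):
        mae, rmse, mape, pearson = error_metrics([59, 60, 61], [59, 60, 61])
        assert (mae, rmse, mape) == (0.0, 0.0, 0.0)
        assert pearson == pytest.approx(1.0)

    def test_constant_offset(self):
        mae, rmse, mape, pearson = error_metrics([60, 61, 62], [59, 60, 61])
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(1.0)
        assert pearson == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        mae, rmse, mape, _ = error_metrics([62, 58], [60, 60])
        assert mae == pytest.approx(2.0)
        assert rmse == pytest.approx(2.0)
        assert mape == pytest.approx(10.0 / 3.0, rel=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            error_metrics([1, 2], [1, 2, 3])


class TestRelativeImprovement:
    @pytest.mark.parametrize(
        "base,enh,higher,expected",
        [
            (4.85, 1.46, False, 69.90),
            (0.72, 0.90, True, 25.00),
            (3.0, 3.0, False, 0.0),
            (3.0, 3.0, True, 0.0),
        ],
    )
    def test_values(self, base, enh, higher, expected):
        assert relative_improvement(base, enh, higher) == pytest.approx(expected, abs=0.005)

    def test_zero_baseline_missing(self):
        assert np.isnan(relative_improvement(0.0, 1.0))


class TestBlandAltman:
    def test_identical(self):
        assert bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        m, lo, hi = bland_altman([1.0, -1.0], [0.0, 0.0])
        assert m == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-3)
        assert lo == pytest.approx(-hi)

    def test_constant_shift_moves_mean_not_width(self, rng):
        ref = rng.standard_normal(20)
        pred = ref + rng.standard_normal(20) * 0.1
        m1, lo1, hi1 = bland_altman(pred, ref)
        m2, lo2, hi2 = bland_altman(pred + 5.0, ref)
        assert m2 == pytest.approx(m1 + 5.0)
        assert (hi2 - lo2) == pytest.approx(hi1 - lo1)
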