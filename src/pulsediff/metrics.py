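"""Heart rate, heart-rate variability, spectral SNR and agreement metrics.

HR is the reciprocal of the mean inter-beat interval (in bpm).  AVNN and SDNN
are the mean and sample standard deviation of the normal-to-normal (NN/RR)
intervals in milliseconds.  The spectral SNR of a pulse waveform is the log
ratio of the power concentrated around the pulse fundamental and its first
harmonic to the remaining power in the analysis band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .signal_core import Waveform

#: Analysis band for spectral SNR, Hz.
SNR_BAND = (0.5, 6.0)

#: Half-widths of the fundamental and harmonic windows, Hz.
SNR_F0_HALFWIDTH = 0.1
SNR_F1_HALFWIDTH = 0.2

#: Clamp range for reported SNR, dB.
SNR_CLAMP = (-40.0, 60.0)


@dataclass(frozen=True)
class BeatSeries:
    """Detected systolic peaks and the inter-beat intervals between them."""

    peak_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.peak_indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("peak_indices must be 1D")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("peak_indices must be strictly increasing")
        object.__setattr__(self, "peak_indices", idx)

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals in seconds."""
        return np.diff(self.peak_indices) / self.fs

    @property
    def n_intervals(self) -> int:
        return max(self.peak_indices.size - 1, 0)


def detect_beats(
    w: Waveform,
    min_interval_s: float = 0.33,
    prominence_frac: float = 0.5,
    smooth_hz: float = 4.0,
) -> BeatSeries:
    """Detect systolic peaks in a band-limited pulse waveform.

    The signal is first smoothed with a zero-phase second-order low-pass at
    ``smooth_hz`` (above the 3 Hz pulse ceiling, so beat timing is preserved
    while broadband measurement noise is suppressed), then local maxima are
    taken with a minimum inter-peak distance (default 0.33 s, a 3 Hz ceiling)
    and a prominence threshold of ``prominence_frac`` times the smoothed
    signal's standard deviation.  A constant signal yields an empty series.
    """
    x = w.samples
    if smooth_hz < w.fs / 2:
        sos = sps.butter(2, smooth_hz, btype="low", fs=w.fs, output="sos")
        padlen = 3 * (2 * sos.shape[0] + 1)
        if x.size > padlen:
            x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    if sd == 0.0:
        return BeatSeries(np.array([], dtype=int), w.fs)
    distance = max(1, int(round(min_interval_s * w.fs)))
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence_frac * sd)
    return BeatSeries(peaks, w.fs)


def heart_rate(b: BeatSeries) -> float:
    """HR in bpm: 60 / mean inter-beat interval.  NaN when no interval exists."""
    if b.n_intervals < 1:
        return float("nan")
    return 60.0 / float(np.mean(b.ibis))


def avnn(b: BeatSeries) -> float:
    """Mean NN interval in milliseconds.  NaN when no interval exists."""
    if b.n_intervals < 1:
        return float("nan")
    return float(np.mean(b.ibis)) * 1000.0


def sdnn(b: BeatSeries) -> float:
    """Sample standard deviation (ddof=1) of NN intervals in ms; NaN if N < 2."""
    if b.n_intervals < 2:
        return float("nan")
    return float(np.std(b.ibis, ddof=1)) * 1000.0


def spectral_snr(
    w: Waveform,
    f0: float,
    band: tuple[float, float] = SNR_BAND,
    log_base_20: bool = True,
) -> float:
    """Spectral SNR in dB of a pulse waveform with fundamental ``f0``.

    Power is integrated over a periodogram of the analysis band: the signal
    power is everything within ``f0 ± 0.1`` Hz and ``2·f0 ± 0.2`` Hz, the
    noise power is the remainder of the band, and the reported value is
    ``20·log10(P_signal / P_noise)`` (the convention followed throughout this
    package; set ``log_base_20=False`` for the 10·log10 power-ratio variant).
    The result is clamped to [-40, +60] dB; a zero noise floor clamps high.
    Scale-invariant: multiplying the waveform by any positive constant leaves
    the value unchanged.
    """
    if not (0.7 <= f0 <= 3.0):
        raise ValueError(f"f0={f0} outside the pulse band [0.7, 3] Hz")
    x = w.samples
    # Zero-pad to a 0.05 Hz grid so the +-0.1 Hz windows resolve on short segments.
    nfft = max(x.size, int(round(w.fs / 0.05)))
    freqs, pxx = sps.periodogram(x, fs=w.fs, nfft=nfft)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    sig_mask = (np.abs(freqs - f0) <= SNR_F0_HALFWIDTH) | (
        np.abs(freqs - 2.0 * f0) <= SNR_F1_HALFWIDTH
    )
    p_sig = pxx[in_band & sig_mask].sum()
    p_noise = pxx[in_band & ~sig_mask].sum()
    if p_noise <= 0.0 or p_sig <= 0.0:
        return SNR_CLAMP[1] if p_sig > 0 else SNR_CLAMP[0]
    factor = 20.0 if log_base_20 else 10.0
    return float(np.clip(factor * np.log10(p_sig / p_noise), *SNR_CLAMP))


def error_metrics(pred, ref) -> tuple[float, float, float, float]:
    """MAE, RMSE, MAPE (%) and Pearson correlation between two lists."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("pred and ref must be equal-length non-empty 1D arrays")
    err = pred - ref
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err * err)))
    if np.any(ref == 0):
        raise ValueError("MAPE undefined: reference contains zeros")
    mape = float(np.mean(np.abs(err / ref))) * 100.0
    if pred.size < 2 or pred.std() == 0 or ref.std() == 0:
        pearson = float("nan")
    else:
        pearson = float(stats.pearsonr(pred, ref).statistic)
    return mae, rmse, mape, pearson


def relative_improvement(
    baseline: float, enhanced: float, higher_is_better: bool = False
) -> float:
    """Percent improvement of ``enhanced`` over ``baseline``.

    Lower-is-better metrics (errors): ``100 * (baseline - enhanced) / baseline``.
    Higher-is-better metrics (correlation, SNR): ``100 * (enhanced - baseline)
    / baseline``.  NaN when the baseline is zero.
    """
    if baseline == 0:
        return float("nan")
    if higher_is_better:
        return 100.0 * (enhanced - baseline) / baseline
    return 100.0 * (baseline - enhanced) / baseline


def bland_altman(pred, ref) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean ± 1.96 · sample sd)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 2:
        raise ValueError("need equal-length arrays with at least 2 entries")
    d = pred - ref
    m = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return m, m - half, m + half


@dataclass
class VitalsReport:
    """Per-segment vitals plus dataset-level agreement statistics."""

    hr_bpm: list = field(default_factory=list)
    avnn_ms: list = field(default_factory=list)
    sdnn_ms: list = field(default_factory=list)
    snr_db: list = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {"segment": i, "hr_bpm": h, "avnn_ms": a, "sdnn_ms": s, "snr_db": r}
            for i, (h, a, s, r) in enumerate(
                zip(self.hr_bpm, self.avnn_ms, self.sdnn_ms, self.snr_db)
            )
        ]


def segment_vitals(w: Waveform, f0: float | None = None) -> dict:
    """HR/AVNN/SDNN (and SNR when ``f0`` is known) for one segment."""
    beats = detect_beats(w)
    out = {
        "hr_bpm": heart_rate(beats),
        "avnn_ms": avnn(beats),
        "sdnn_ms": sdnn(beats),
        "n_beats": int(beats.peak_indices.size),
    }
    if f0 is not None:
        out["snr_db"] = spectral_snr(w, f0)
    return out
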