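"""Core waveform types, filtering, segmentation and resampling augmentation.

The pulse band used throughout the package is 0.7-3 Hz (42-180 bpm), the
physiological range of resting-to-exercise heart rates.  Rough rPPG traces and
reference PPG traces are band-passed to this range, cut into fixed-length
segments and (optionally) frequency-augmented by resampling before they enter
the diffusion model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Default pulse band in Hz.
PULSE_BAND = (0.7, 3.0)

#: Default segment length in samples (10 s at 30 Hz).
SEGMENT_LENGTH = 300

#: Default resampling-augmentation frequency ratios.
AUGMENT_RATIOS = (0.4, 0.6, 0.8, 1.2, 1.4, 1.6, 1.8, 2.0)


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled 1D physiological signal.

    Parameters
    ----------
    samples : array-like
        Signal values, arbitrary units.  Must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text description (e.g. ``"ppg"``, ``"rough_rppg"``).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("waveform must be a non-empty 1D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class SegmentPair:
    """An aligned (conditioner, reference) segment pair.

    ``y`` is the rough rPPG conditioner and ``x0`` the reference PPG target,
    both of length ``L`` at sampling rate ``fs``.  ``f0`` is the ground-truth
    pulse fundamental in Hz when known (synthetic data or annotation).
    """

    y: np.ndarray
    x0: np.ndarray
    fs: float
    f0: float | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        x0 = np.asarray(self.x0, dtype=float)
        if y.shape != x0.shape or y.ndim != 1:
            raise ValueError("y and x0 must be 1D arrays of equal length")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x0", x0)

    @property
    def length(self) -> int:
        return self.y.size


class InvalidBandError(ValueError):
    """Requested filter band is incompatible with the sampling rate."""


class TooShortError(ValueError):
    """Signal shorter than the filter warm-up length."""


def bandpass(
    w: Waveform,
    low_hz: float = PULSE_BAND[0],
    high_hz: float = PULSE_BAND[1],
    order: int = 3,
) -> Waveform:
    """Zero-phase Butterworth band-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``) so that peak
    timing — on which the inter-beat-interval metrics depend — is not delayed.
    The effective magnitude response is the squared Butterworth response.

    Raises
    ------
    InvalidBandError
        If the band does not satisfy ``0 < low < high < fs/2``.
    TooShortError
        If the signal is shorter than the filter warm-up (padding) length.
    """
    if not (0.0 < low_hz < high_hz < w.fs / 2.0):
        raise InvalidBandError(
            f"band ({low_hz}, {high_hz}) Hz invalid for fs={w.fs} Hz"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=w.fs, output="sos")
    # sosfiltfilt pads by 3 * (max(len(a), len(b)) - 1) per second-order section
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(w) <= padlen:
        raise TooShortError(
            f"signal of {len(w)} samples shorter than filter warm-up ({padlen})"
        )
    out = sps.sosfiltfilt(sos, w.samples)
    return Waveform(out, w.fs, label=w.label)


def segment(w: Waveform | np.ndarray, L: int, stride: int) -> list[np.ndarray]:
    """Cut a waveform into overlapping windows of length ``L``.

    Window ``k`` covers samples ``[k*stride, k*stride + L)`` (0-based,
    half-open); ``floor((n - L)/stride) + 1`` windows are produced.  A signal
    shorter than ``L`` yields an empty list with a warning so that batch
    pipelines can skip short records instead of crashing.
    """
    x = w.samples if isinstance(w, Waveform) else np.asarray(w, dtype=float)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if L < 1:
        raise ValueError("L must be >= 1")
    n = x.size
    if L > n:
        logger.warning("segment: signal of %d samples shorter than L=%d; skipped", n, L)
        return []
    n_seg = (n - L) // stride + 1
    return [x[k * stride : k * stride + L].copy() for k in range(n_seg)]


def znormalize(seg: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization; constant input maps to zeros.

    Applied to both diffusion targets and conditioners so the signal scale
    matches the unit-variance Gaussian noise of the forward process.
    """
    x = np.asarray(seg, dtype=float)
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def dominant_frequency(
    x: np.ndarray, fs: float, band: tuple[float, float] = PULSE_BAND
) -> float:
    """Location (Hz) of the periodogram peak inside ``band``.

    Zero-pads to a 0.02 Hz grid so short segments still localize the peak.
    """
    x = np.asarray(x, dtype=float)
    nfft = max(x.size, int(round(fs / 0.02)))
    freqs, pxx = sps.periodogram(x, fs=fs, nfft=nfft)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(freqs[mask][np.argmax(pxx[mask])])


def _rescale_to_length(x: np.ndarray, n_new: int, L: int) -> np.ndarray:
    """Fourier-resample ``x`` to ``n_new`` samples, then center-crop or edge-pad to ``L``."""
    y = sps.resample(x, n_new)
    if n_new >= L:
        start = (n_new - L) // 2
        return y[start : start + L]
    pad = L - n_new
    left = pad // 2
    return np.pad(y, (left, pad - left), mode="edge")


def resample_augment(
    p: SegmentPair,
    ratios: Sequence[float] = AUGMENT_RATIOS,
    band: tuple[float, float] = PULSE_BAND,
) -> list[SegmentPair]:
    """Frequency augmentation by time-rescaling a segment pair.

    For each ratio ``r`` the pair is resampled so the pulse fundamental becomes
    ``r * f0`` and re-cut (or edge-padded) to the original length.  Pairs whose
    target fundamental falls outside ``band`` are omitted; the unmodified pair
    (``r = 1``) is always included first.  Requires ``p.f0``; without it the
    augmentation is skipped with a warning and only the original pair returned.
    """
    if p.f0 is None:
        logger.warning("resample_augment: pair has no f0; augmentation skipped")
        return [p]
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    L = p.length
    out = [p]
    for r in ratios:
        if r == 1.0:
            continue
        f_target = r * p.f0
        if not (band[0] <= f_target <= band[1]):
            continue
        n_new = int(round(L / r))
        out.append(
            SegmentPair(
                y=_rescale_to_length(p.y, n_new, L),
                x0=_rescale_to_length(p.x0, n_new, L),
                fs=p.fs,
                f0=f_target,
            )
        )
    return out
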