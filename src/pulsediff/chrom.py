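"""Chrominance-based (CHROM) rPPG extraction from ROI-averaged RGB traces.

CHROM projects mean-normalized RGB channels onto two chrominance axes chosen
to cancel specular/illumination variation, then combines them with a per-window
gain ratio so residual motion components cancel.  It is the conventional
baseline that produces the "rough" rPPG waveform the diffusion model enhances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_core import Waveform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RGBTrace:
    """ROI-averaged red/green/blue time series at sampling rate ``fs``."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.g, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if not (r.shape == g.shape == b.shape) or r.ndim != 1:
            raise ValueError("r, g, b must be 1D arrays of equal length")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        for name, c in (("r", r), ("g", g), ("b", b)):
            if c.mean() <= 0:
                raise ValueError(f"channel {name} must have positive mean")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "b", b)

    def __len__(self) -> int:
        return self.r.size


def _chrom_window(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """CHROM pulse estimate for one analysis window."""
    # Mean-normalize per window: Cn = C / mean(C) - 1 (unitless, gain-free).
    rn = r / r.mean() - 1.0
    gn = g / g.mean() - 1.0
    bn = b / b.mean() - 1.0
    xs = 3.0 * rn - 2.0 * gn
    ys = 1.5 * rn + gn - 1.5 * bn
    sy = ys.std(ddof=1)
    if sy == 0.0:
        logger.warning("chrom: zero-variance Ys window; using alpha=0")
        return xs
    alpha = xs.std(ddof=1) / sy
    return xs - alpha * ys


def chrom_signal(
    trace: RGBTrace, window_s: float = 1.6, overlap: float = 0.5
) -> Waveform:
    """Extract a rough rPPG waveform from an RGB trace with CHROM.

    Processes the trace in windows of ``window_s`` seconds with fractional
    ``overlap``, combining windows by Hann-tapered overlap-add (normalized by
    the accumulated taper so output amplitude is window-position independent).
    Output length equals input length.  Global illumination gain cancels
    exactly: scaling all channels by a common constant leaves the output
    unchanged.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    n = len(trace)
    win = int(round(window_s * trace.fs))
    if win < trace.fs:
        raise ValueError("window must cover at least 1 s")
    win = min(win, n)
    hop = max(1, int(round(win * (1.0 - overlap))))

    out = np.zeros(n)
    weight = np.zeros(n)
    taper = np.hanning(win)
    if taper.sum() == 0:  # win == 1 degenerate case
        taper = np.ones(win)
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if starts[-1] + win < n:  # cover the tail
        starts.append(n - win)
    for s in starts:
        sl = slice(s, s + win)
        out[sl] += taper * _chrom_window(trace.r[sl], trace.g[sl], trace.b[sl])
        weight[sl] += taper
    nz = weight > 1e-12
    out[nz] /= weight[nz]
    return Waveform(out, trace.fs, label="rough_rppg")
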