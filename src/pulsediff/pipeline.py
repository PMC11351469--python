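"""Whole-record enhancement: segment, run the reverse process, stitch.

A long rough rPPG waveform is cut into 50%-overlapping windows of the model's
segment length, each window is z-normalized and enhanced by the conditional
reverse process, and the enhanced windows are recombined by overlap-averaging
(each output sample is the mean of every window value covering it).
"""

from __future__ import annotations

import numpy as np

from .denoiser import Denoiser
from .diffusion import FastSchedule, NoiseSchedule, run_reverse
from .signal_core import Waveform, segment, znormalize


def enhance_waveform(
    denoiser: Denoiser,
    w: Waveform,
    sched: NoiseSchedule,
    L: int,
    rng: np.random.Generator,
    refined: bool = True,
    fast: FastSchedule | None = None,
) -> Waveform:
    """Enhance a rough rPPG waveform of arbitrary length.

    Windows of ``L`` samples at stride ``L // 2`` are enhanced in one batched
    reverse pass; a final window anchored at the end covers any remainder.
    Deterministic given the state of ``rng``.
    """
    n = len(w)
    if n < L:
        raise ValueError(f"waveform of {n} samples shorter than segment length {L}")
    stride = max(L // 2, 1)
    starts = [k * stride for k in range((n - L) // stride + 1)]
    if starts[-1] + L < n:
        starts.append(n - L)

    windows = np.stack([znormalize(w.samples[s : s + L]) for s in starts])
    enhanced = run_reverse(denoiser, windows, sched, rng, refined=refined, fast=fast)

    out = np.zeros(n)
    weight = np.zeros(n)
    for row, s in zip(enhanced, starts):
        out[s : s + L] += row
        weight[s : s + L] += 1.0
    out /= weight
    return Waveform(out, w.fs, label="enhanced_rppg")


def enhance_pairs(
    denoiser: Denoiser,
    ys: np.ndarray,
    sched: NoiseSchedule,
    rng: np.random.Generator,
    refined: bool = True,
    fast: FastSchedule | None = None,
    batch: int = 64,
) -> np.ndarray:
    """Enhance a stack of conditioner segments ``(N, L)`` in batches."""
    ys = np.asarray(ys, dtype=float)
    outs = [
        run_reverse(denoiser, ys[i : i + batch], sched, rng, refined=refined, fast=fast)
        for i in range(0, ys.shape[0], batch)
    ]
    return np.concatenate(outs, axis=0)
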