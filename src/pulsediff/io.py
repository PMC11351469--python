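"""Columnar-text I/O for waveforms and RGB traces.

Waveforms travel as CSV with header ``t,value``; RGB traces as ``t,r,g,b``.
The sampling rate is stored in a JSON sidecar (``<name>.json``) when writing
and, when the sidecar is absent on read, inferred from the median spacing of
the time column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chrom import RGBTrace
from .signal_core import Waveform


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _infer_fs(t: np.ndarray) -> float:
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValueError("time column must be increasing")
    return 1.0 / float(dt)


def write_waveform(path: str | Path, w: Waveform) -> None:
    path = Path(path)
    pd.DataFrame({"t": w.times, "value": w.samples}).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"fs": w.fs, "label": w.label}))


def read_waveform(path: str | Path) -> Waveform:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"t", "value"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns t,value")
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
        fs, label = float(meta["fs"]), meta.get("label", "")
    else:
        fs, label = _infer_fs(df["t"].to_numpy()), ""
    return Waveform(df["value"].to_numpy(), fs, label=label)


def write_rgb(path: str | Path, trace: RGBTrace) -> None:
    path = Path(path)
    t = np.arange(len(trace)) / trace.fs
    pd.DataFrame({"t": t, "r": trace.r, "g": trace.g, "b": trace.b}).to_csv(
        path, index=False
    )
    _sidecar(path).write_text(json.dumps({"fs": trace.fs}))


def read_rgb(path: str | Path) -> RGBTrace:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"t", "r", "g", "b"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns t,r,g,b")
    if _sidecar(path).exists():
        fs = float(json.loads(_sidecar(path).read_text())["fs"])
    else:
        fs = _infer_fs(df["t"].to_numpy())
    return RGBTrace(
        r=df["r"].to_numpy(), g=df["g"].to_numpy(), b=df["b"].to_numpy(), fs=fs
    )
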