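"""Compute HR, HRV and spectral SNR from a pulse waveform.

Generates a clean 60 s synthetic pulse at 72 bpm with 3% beat-interval
jitter, detects beats and prints the vitals next to the generating values.
"""

import numpy as np

from pulsediff import (
    SynthConfig,
    avnn,
    detect_beats,
    gen_ppg,
    heart_rate,
    sdnn,
    spectral_snr,
)

cfg = SynthConfig(hr_hz=1.2, hrv_jitter=0.03, duration_s=60.0, seed=11)
ppg, beat_times = gen_ppg(cfg)

beats = detect_beats(ppg)
true_ibis = np.diff(beat_times)

print(f"true HR      : {60 * cfg.hr_hz:6.1f} bpm")
print(f"measured HR  : {heart_rate(beats):6.1f} bpm")
print(f"true AVNN    : {1000 * true_ibis.mean():6.1f} ms")
print(f"measured AVNN: {avnn(beats):6.1f} ms")
print(f"true SDNN    : {1000 * true_ibis.std(ddof=1):6.1f} ms")
print(f"measured SDNN: {sdnn(beats):6.1f} ms")
print(f"spectral SNR : {spectral_snr(ppg, cfg.hr_hz):6.1f} dB (clean signal, high)")
print("HR is 60 / mean inter-beat interval; AVNN/SDNN are the mean and")
print("sample standard deviation of the same intervals in milliseconds.")
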