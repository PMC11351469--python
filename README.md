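# pulsediff

Conditional-diffusion enhancement of remote-photoplethysmography (rPPG) pulse
waveforms, with the surrounding tooling to extract, degrade, enhance and
evaluate them.

## The problem

rPPG recovers the blood-volume pulse from the tiny skin-color oscillations in
facial video. Conventional extractors such as the chrominance (CHROM) method
produce a waveform whose periodicity is usually good enough for heart-rate
estimation, but whose signal-to-noise ratio (SNR) is too low for heart-rate
*variability* (HRV) measures, which are exquisitely sensitive to beat-timing
noise. `pulsediff` treats enhancement as conditional generation: a denoising
diffusion model is trained on clean PPG segments, and at inference the rough
rPPG segment conditions the reverse process so the model regenerates a clean
waveform anchored to the observed one.

## The model

A denoising diffusion probabilistic model (DDPM) over segments
`x0 ∈ R^L` (L = 300 samples at 30 Hz by default). The forward process
corrupts with a linear variance schedule `β_t ∈ [1e-4, 5e-2]`, `t = 1..T`
(T = 50):

    x_t = √ᾱ_t · x0 + √(1 − ᾱ_t) · ε,   ᾱ_t = Π_{i≤t} (1 − β_i),  ε ~ N(0, I)

A gated dilated-convolution network `ε_θ(x_t, t, y)` (DiffWave-style residual
blocks, dilation cycle [1, 2, 4, 8], tanh ⊙ σ gating, summed skip connections)
is trained to predict the noise, with the rough rPPG segment `y` injected into
every block. The vanilla reverse update is

    x_{t−1} = (x_t − β_t/√(1 − ᾱ_t) · ε_θ) / √α_t + σ_t z,

and the *refined* reverse process additionally interpolates each intermediate
toward the conditioner,

    x_{t−1} ← γ_{t−1} · x_{t−1} + (1 − γ_{t−1}) · y,   γ_{t−1} = ᾱ_{t−1},

so the search space stays anchored to the observed waveform early (γ small at
large t) and hands over to the learned pulse prior as t → 0 (γ → 1). A 6-step
inference schedule `[1e-4, 1e-3, 1e-2, 0.05, 0.2, 0.5]`, aligned to the
training schedule by matching √ᾱ, provides fast sampling.

Vitals are measured per segment: HR = 60 / mean inter-beat interval; AVNN and
SDNN are the mean and sample standard deviation of the beat intervals (ms);
spectral SNR is `20·log10` of the power within ±0.1 Hz of the pulse
fundamental and ±0.2 Hz of its first harmonic against the remaining
[0.5, 6] Hz band power.

## Worked example

`examples/` contains one short script per capability. For instance:

```sh
$ python examples/chrom_extraction.py
embedded pulse frequency : 1.50 Hz (90 bpm)
CHROM dominant frequency : 1.52 Hz (91 bpm)

$ python examples/vitals_from_waveform.py
true HR      :   72.0 bpm
measured HR  :   72.1 bpm
true AVNN    :  832.7 ms
measured AVNN:  832.4 ms
true SDNN    :   21.2 ms
measured SDNN:   24.1 ms
spectral SNR :   38.2 dB (clean signal, high)

$ python examples/diffusion_basics.py
alpha_bar_T = 0.2062 (fraction of signal left at t=T)
corrupted correlation with x0: +0.119
reconstruction error after reverse chain: 1.11e-16
```

The first shows the chrominance extractor recovering a 90 bpm pulse embedded
at 1% modulation depth in synthetic RGB traces; the second shows beat
detection and HRV metrics agreeing with the generating ground truth; the
third shows the reverse update exactly inverting the forward corruption when
given the true noise. `examples/train_and_enhance.py` runs a miniature
train-then-enhance loop end to end.

There is also a thin CLI over the same library calls:

```sh
pulsediff synth   --n-pairs 100 --out-dir data/
pulsediff train   --data-dir data/ --checkpoint runs/model
pulsediff enhance --checkpoint runs/model --input rough.csv --output enhanced.csv
pulsediff evaluate --pred enhanced.csv --ref reference.csv --baseline rough.csv
```

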