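# Methods

## Signal model and preprocessing

All waveforms are uniformly sampled 1D signals with an explicit sampling rate
(30 Hz throughout the defaults, the common video frame rate). The pulse band
is 0.7–3 Hz (42–180 bpm). Preprocessing applies a third-order Butterworth
band-pass over that band, run forward–backward (`sosfiltfilt`) so the filter
is zero-phase: HRV metrics depend on beat timing, and a causal filter would
delay peaks by a frequency-dependent amount. Filtered records are cut into
segments of `L` samples (default 300, i.e. 10 s) with a configurable stride,
0-based and half-open. Segments are z-normalized (mean 0, variance 1) before
entering the diffusion model so that signal scale matches the unit-variance
Gaussian noise of the forward process; a constant segment maps to zeros. The
frequency-uniformity augmentation resamples a segment pair so the pulse
fundamental moves to `r·f0` for ratios r in {0.4, 0.6, 0.8, 1.2, 1.4, 1.6,
1.8, 2.0} (Fourier resampling, then center-crop or edge-pad back to `L`);
pairs whose target fundamental leaves the pulse band are dropped, and the
unmodified pair is always kept.

## CHROM extraction

The chrominance method projects per-window mean-normalized RGB channels
(`Cn = C/mean(C) − 1`) onto `Xs = 3Rn − 2Gn` and `Ys = 1.5Rn + Gn − 1.5Bn`
and combines them as `S = Xs − (σ(Xs)/σ(Ys))·Ys`. Windows are 1.6 s with 50%
overlap, recombined by Hann-weighted overlap-add normalized by the
accumulated taper. The construction is invariant to a global illumination
gain by design; a zero-variance `Ys` window falls back to `S = Xs` with a
warning. Window length and overlap follow the original chrominance method's
convention.

## Diffusion process

The noise schedule is linear, `β_t` from 1e-4 to 5e-2 over `T = 50` steps,
with `ᾱ_0 := 1` so the refinement weight `γ_0 = 1` and the first posterior
standard deviation are well defined. The forward marginal, the
noise-prediction loss (mean squared error over samples and batch), and the
reverse update use the standard DDPM forms; the reverse update's leading
coefficient is `1/√α_t` (the posterior-mean coefficient — with the cumulative
product in that position the latent scale diverges as `t` grows, and the
single-step algebraic inversion test fails). Sampling draws `z ~ N(0, I)`
fresh each step with `z = 0` at the final step.

The refined reverse process interpolates each intermediate toward the clean
conditioner with weight `1 − γ_{t−1}`, `γ_{t−1} = ᾱ_{t−1}`; the conditioner is
never forward-noised. Fast sampling builds a 6-step inference schedule
(β = 1e-4 … 0.5) with its own cumulative products and maps each inference
step to a continuous training-step index by linear interpolation of `√ᾱ`
between adjacent training steps (clamped at the ends with a warning); the
reverse iteration then uses the inference-schedule coefficients with the
aligned fractional step embedding, and `γ` is the inference-schedule `ᾱ`.

## Denoiser network and training

`ε_θ(x_t, t, y)` is a cascade of gated residual blocks: a non-causal
(symmetric zero-padded) dilated convolution (kernel 3, dilation cycle
[1, 2, 4, 8] repeated) produces 2C channels split into tanh/σ halves and
multiplied; the step embedding (128-dim sinusoidal with a descending
four-decade frequency ladder, refined by a two-layer swish MLP, evaluated at
real-valued `t` so fractional fast-sampling steps embed smoothly) is added to
each block's input through a per-block dense layer; the conditioner enters
every block through a dilated convolution added to the gate input, and
additionally as a second channel of the input projection. Residual and skip
channel widths default to 64/64; skips are summed into a conv1×1 → ReLU →
conv1×1 head. Default receptive field: 1 + 2·(1+2+4+8)·3 = 91 samples (3 s at
30 Hz), enough to cover one full pulse period at the lowest in-band rate.

The network, its gradients and the Adam optimizer are implemented in NumPy on
a small reverse-mode autodiff engine shipped with the package; gradients are
validated against central finite differences in the test suite. Parameters
use Kaiming initialization everywhere, including the output head, so that
gradient flows to every parameter from the first step (a zero-initialized
head would silence upstream gradients on the first batch). Training samples a
segment pair, a step `t ~ Uniform{1..T}` and `ε ~ N(0, I)` per iteration and
minimizes the noise-prediction MSE. Full-scale defaults follow the published
configuration (learning rate 2e-4, batch 64); these are tied to a very long
schedule. The scaled-down study instead uses 1e-3 with cosine annealing to
zero and an EMA (decay 0.999) of the parameters for inference — standard
short-schedule practice. Training aborts on a non-finite loss and restores
the last checkpointed parameters.

## Vitals metrics

Beat detection smooths the waveform with a zero-phase second-order low-pass
at 4 Hz (above the pulse ceiling, so timing is preserved) and takes local
maxima with a minimum spacing of 0.33 s and prominence at least 0.5 of the
smoothed signal's standard deviation. HR is 60 over the mean inter-beat
interval; AVNN and SDNN are the mean and sample standard deviation (ddof 1)
of the intervals in milliseconds. Spectral SNR integrates a zero-padded
periodogram (0.05 Hz grid) over [0.5, 6] Hz: signal power within ±0.1 Hz of
`f0` plus ±0.2 Hz of `2·f0`, noise power the remainder, reported as
`20·log10(P_sig/P_noise)` and clamped to [−40, +60] dB. The `20·log10` form
follows the published definition even though power ratios conventionally take
`10·log10`; a switch selects the factor-10 variant. `f0` is taken from the
reference signal (its periodogram peak, or the generating rate for synthetic
data), not from the signal under test. Bland–Altman agreement reports the
mean difference and mean ± 1.96 sample standard deviations.

## Synthetic data

The generator emulates the structure the enhancement task depends on, with
controllable ground truth. Clean pulses are built from a beat-aligned phase
ramp: beat intervals are `(1/f0)·(1 + jitter·N(0,1))` (default jitter 0.03,
floored at 40% of the nominal interval), and the waveform is
`cos(2πφ) + 0.4·cos(4πφ)`, so systolic peaks coincide with the known beat
times and the spectrum has the fundamental-plus-harmonic shape the SNR metric
assumes. Conditioners add pulse-band-limited Gaussian noise whose amplitude
is calibrated iteratively (40 dB-per-decade updates) until the measured
spectral SNR of the finished conditioner is within ±1 dB of the target
(default 3 dB), plus sub-0.5 Hz baseline wander and Poisson-timed
Gaussian-windowed motion transients (default 2/min), then band-pass to
0.7–3 Hz. RGB traces embed the normalized pulse as a ~1% reflectance
modulation with channel strengths (0.33, 1.0, 0.5) — strongest in green —
under a shared multiplicative illumination drift and independent sensor
noise. Datasets sample the pulse rate uniformly over 0.7–3 Hz with
per-pair child seeds, so different master seeds give disjoint datasets.

What the generator does *not* emulate: real PPG morphology (dicrotic notch,
asymmetric systolic upstroke), skin-tone and motion-dependent noise
statistics, sensor quantization, or correlation between noise level and heart
rate. Tests passing on these fixtures show the machinery is correct and that
enhancement works when the data match the model's assumptions; they do not
quantify performance on real video-derived signals.

## The scaled-down enhancement study

`pulsediff.experiments.run_enhancement_study` trains a 4-block, 32-channel
denoiser for 2000 steps (batch 16) on 500 pairs of 128 samples at ≈3 dB
conditioner SNR and evaluates 50 held-out pairs — sizes chosen so the whole
study runs in a few minutes on one CPU. Results at these sizes (study seed 0):
the refined reverse process raises mean spectral SNR by ≈1.3 dB over the
conditioner and beats the vanilla reverse process by ≈6.7 dB, HR MAE does not
degrade, and 6-step fast sampling lands within ≈2.4 dB of full 50-step
sampling. Stochastic quantities move by a few tenths of a dB (and ~1 bpm)
across seeds.

Two quantitative margins of the full-scale method are **not** reached at this
scale, and the corresponding assertions are left failing rather than
loosened: a +3 dB mean-SNR gain over the conditioner, and < 2 dB fast-sampling
degradation. The limitation is structural, not a defect of the machinery: the
sampler is verified exact (an oracle noise predictor inverts the chain to
machine precision, and an oracle corrupted by *unbiased* noise of RMS 0.5 —
a worse mean squared error than the trained model's — still reaches the clean
ceiling of ≈7.2 dB), and the trained model's implied clean-signal estimate
correlates 0.90–1.00 with the truth at every step on training-consistent
states. But the refined process interpolates the clean conditioner into every
step, and the noise-prediction objective only ever shows the model states
corrupted by *white* noise, whose in-pulse-band power (≤ 0.1 at these β) is
far below the conditioner's structured in-band noise power (≈ 0.33). A
2000-step model therefore preserves, rather than removes, conditioner noise
it inherits through the interpolation — a linear decomposition of the output
gives ≈ 0.76·(clean) + 0.78·(conditioner noise) + white residual, where a
weight of ≤ 0.62 would meet the margin. Closing this gap is a matter of
training scale (the full-scale configuration trains a 12-block, 64-channel
model for 2×10⁶ steps), at which point prior enforcement on off-distribution
states strengthens; no toy-scale optimizer or architecture variant we
evaluated (learning rate, annealing, EMA, receptive field, conditioner
pathway, resampling-augmented data) moved the gain beyond ≈1.3 dB.

## Numerical choices and degenerate inputs

Diffusion arithmetic is float64 end to end. `T = 1` follows the single-point
linspace convention (β = β_min). Segmentation of a record shorter than `L`
returns an empty list with a warning so batch pipelines skip short records.
Constant segments z-normalize to zeros; a constant waveform yields an empty
beat series and missing (NaN) vitals rather than an exception; MAPE refuses
zero references; Pearson correlation is NaN for constant lists. SNR clamps to
[−40, +60] dB and returns the upper clamp when the noise partition is empty.
Checkpoints store parameters (npz) beside a JSON of the architecture and
schedule, and refuse to load when either mismatches.
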