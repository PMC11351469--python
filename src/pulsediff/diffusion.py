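"""Denoising-diffusion machinery for 1D pulse waveforms.

Implements the linear noise schedule, the closed-form forward corruption,
the noise-prediction training loss, the vanilla reverse sampler, the refined
reverse sampler (per-step convex interpolation between the model output and
the conditioner), and the short aligned inference schedule for fast sampling.

Conventions
-----------
Steps are 1-based: ``t = 1..T``.  ``alpha_bar`` carries a leading entry
``alpha_bar[0] = 1`` so that the mixing weight gamma_0 = 1 and the posterior
standard deviation sigma_1 are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

logger = logging.getLogger(__name__)

#: Default number of training diffusion steps.
DEFAULT_T = 50

#: Default linear beta range.
DEFAULT_BETA_RANGE = (1e-4, 5e-2)

#: Default 6-step fast-sampling inference schedule.
FAST_BETAS = (0.0001, 0.001, 0.01, 0.05, 0.2, 0.5)


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step corruption variances and derived quantities.

    Attributes
    ----------
    beta : (T,) array
        Variance schedule beta_1..beta_T, each in (0, 1).
    alpha : (T,) array
        ``1 - beta``.
    alpha_bar : (T+1,) array
        Cumulative products with ``alpha_bar[0] = 1``; ``alpha_bar[t]``
        is the product of ``alpha_1..alpha_t``.
    sigma : (T,) array
        Posterior standard deviations; ``sigma[t-1]`` is
        ``sqrt((1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) * beta_t)``.
    """

    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    sigma: np.ndarray

    @property
    def T(self) -> int:
        return self.beta.size

    def gamma(self, t: int | np.ndarray) -> np.ndarray:
        """Refinement mixing weight gamma_{t-1} = alpha_bar_{t-1} for step t."""
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"step t out of range [1, {self.T}]")
        return self.alpha_bar[t - 1]

    def to_dict(self) -> dict:
        """JSON-serializable echo of the schedule for run reproducibility."""
        return {
            "T": int(self.T),
            "beta": self.beta.tolist(),
        }


def make_schedule(
    T: int = DEFAULT_T,
    beta_min: float = DEFAULT_BETA_RANGE[0],
    beta_max: float = DEFAULT_BETA_RANGE[1],
) -> NoiseSchedule:
    """Linearly spaced beta schedule with derived alpha, alpha_bar, sigma.

    ``T = 1`` follows the single-point linspace convention: the lone beta is
    ``beta_min``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta_min <= beta_max < 1.0):
        raise ValueError(f"require 0 < beta_min <= beta_max < 1, got [{beta_min}, {beta_max}]")
    beta = np.linspace(beta_min, beta_max, T) if T > 1 else np.array([beta_min])
    return schedule_from_betas(beta)


def schedule_from_betas(beta: np.ndarray) -> NoiseSchedule:
    """Build a :class:`NoiseSchedule` from an explicit beta sequence."""
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 1 or beta.size < 1:
        raise ValueError("beta must be a non-empty 1D array")
    if np.any(beta <= 0) or np.any(beta >= 1):
        raise ValueError("each beta must lie in (0, 1)")
    alpha = 1.0 - beta
    alpha_bar = np.concatenate([[1.0], np.cumprod(alpha)])
    sigma = np.sqrt((1.0 - alpha_bar[:-1]) / (1.0 - alpha_bar[1:]) * beta)
    return NoiseSchedule(beta=beta, alpha=alpha, alpha_bar=alpha_bar, sigma=sigma)


def _check_t(t: int | np.ndarray, T: int, allow_zero: bool = False) -> np.ndarray:
    t = np.asarray(t)
    lo = 0 if allow_zero else 1
    if np.any(t < lo) or np.any(t > T):
        raise ValueError(f"step t={t} out of range [{lo}, {T}]")
    return t


def forward_sample(
    x0: np.ndarray, t: int | np.ndarray, eps: np.ndarray, sched: NoiseSchedule
) -> np.ndarray:
    """Closed-form marginal draw of the forward chain.

    ``x_t = sqrt(alpha_bar_t) * x0 + sqrt(1 - alpha_bar_t) * eps``.

    ``t`` may be a scalar or a per-row array matching a batched ``x0`` of
    shape ``(B, L)``.  ``t = 0`` returns ``x0`` (identity convention).
    """
    x0 = np.asarray(x0, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if eps.shape != x0.shape:
        raise ValueError("eps must have the same shape as x0")
    t = _check_t(t, sched.T, allow_zero=True)
    ab = sched.alpha_bar[t]
    if ab.ndim == 1 and x0.ndim == 2:  # per-row t for a batch
        ab = ab[:, None]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def training_loss(eps: np.ndarray, eps_hat: np.ndarray) -> float:
    """Mean squared error between true and predicted noise (mean reduction)."""
    eps = np.asarray(eps, dtype=float)
    eps_hat = np.asarray(eps_hat, dtype=float)
    if eps.shape != eps_hat.shape:
        raise ValueError("eps and eps_hat must have the same shape")
    d = eps_hat - eps
    return float(np.mean(d * d))


def reverse_step(
    x_t: np.ndarray,
    t: int,
    eps_hat: np.ndarray,
    sched: NoiseSchedule,
    z: np.ndarray | float = 0.0,
) -> np.ndarray:
    """One vanilla reverse-process step.

    ``x_{t-1} = (x_t - beta_t / sqrt(1 - alpha_bar_t) * eps_hat) / sqrt(alpha_t)
    + sigma_t * z``.  Pass ``z = 0`` at the final step ``t = 1``.
    """
    _check_t(t, sched.T)
    x_t = np.asarray(x_t, dtype=float)
    eps_hat = np.asarray(eps_hat, dtype=float)
    if eps_hat.shape != x_t.shape:
        raise ValueError("eps_hat must match x_t in shape")
    i = t - 1
    mean = (x_t - sched.beta[i] / np.sqrt(1.0 - sched.alpha_bar[t]) * eps_hat) / np.sqrt(
        sched.alpha[i]
    )
    return mean + sched.sigma[i] * np.asarray(z)


def refined_reverse_step(
    x_t: np.ndarray,
    t: int,
    eps_hat: np.ndarray,
    y: np.ndarray,
    sched: NoiseSchedule,
    z: np.ndarray | float = 0.0,
    gamma: float | None = None,
) -> np.ndarray:
    """One refined reverse step: interpolate toward the conditioner.

    Computes the vanilla step ``x~_{t-1}`` and returns
    ``gamma_{t-1} * x~_{t-1} + (1 - gamma_{t-1}) * y`` with
    ``gamma_{t-1} = alpha_bar_{t-1}`` (overridable for analysis).  The clean
    conditioner is mixed in directly; it is never forward-noised.
    """
    y = np.asarray(y, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    if y.shape != x_t.shape:
        raise ValueError("conditioner y must match x_t in shape")
    x_prev = reverse_step(x_t, t, eps_hat, sched, z)
    g = float(sched.gamma(t)) if gamma is None else float(gamma)
    return g * x_prev + (1.0 - g) * y


@dataclass(frozen=True)
class FastSchedule:
    """Short inference schedule aligned to a training schedule.

    ``t_align[s-1]`` is the (possibly fractional) training-step index whose
    cumulative sqrt(alpha_bar) matches inference step ``s``; the step
    embedding is evaluated there while the reverse-update coefficients come
    from the inference schedule itself.
    """

    infer: NoiseSchedule
    t_align: np.ndarray

    @property
    def S(self) -> int:
        return self.infer.T


def fast_schedule(sched_train: NoiseSchedule, betas_infer=FAST_BETAS) -> FastSchedule:
    """Build the aligned fast-sampling schedule.

    For each inference step the continuous training-step index is found by
    linear interpolation of ``sqrt(alpha_bar)`` between adjacent training
    steps; values outside the training range are clamped to the nearest
    endpoint with a warning.
    """
    betas_infer = np.asarray(betas_infer, dtype=float)
    if np.any(np.diff(betas_infer) <= 0):
        raise ValueError("betas_infer must be strictly increasing")
    infer = schedule_from_betas(betas_infer)

    # sqrt(alpha_bar) at training steps 1..T (decreasing in t).
    st = np.sqrt(sched_train.alpha_bar[1:])
    T = sched_train.T
    t_align = np.empty(infer.T)
    for s in range(1, infer.T + 1):
        g = np.sqrt(infer.alpha_bar[s])
        if g > st[0]:
            logger.warning("fast_schedule: step %d above training range; clamped", s)
            t_align[s - 1] = 1.0
        elif g < st[-1]:
            logger.warning("fast_schedule: step %d below training range; clamped", s)
            t_align[s - 1] = float(T)
        else:
            # largest t with st[t-1] >= g >= st[t]
            idx = int(np.searchsorted(-st, -g, side="right")) - 1  # 0-based upper bin
            idx = min(idx, T - 2)
            hi, lo = st[idx], st[idx + 1]
            frac = 0.0 if hi == lo else (hi - g) / (hi - lo)
            t_align[s - 1] = (idx + 1) + frac
    return FastSchedule(infer=infer, t_align=t_align)


class NoisePredictor(Protocol):
    """Anything exposing ``predict_noise(x_t, t, y) -> eps_hat``."""

    def predict_noise(self, x_t: np.ndarray, t, y: np.ndarray) -> np.ndarray: ...


def run_reverse(
    denoiser: NoisePredictor | Callable,
    y: np.ndarray,
    sched: NoiseSchedule,
    rng: np.random.Generator,
    refined: bool = True,
    fast: FastSchedule | None = None,
) -> np.ndarray:
    """Run the full reverse process conditioned on ``y``.

    Starts from ``x_T ~ N(0, I)`` and iterates ``t = T..1`` (or the aligned
    fast schedule), feeding the conditioner to the denoiser at every step and,
    when ``refined``, interpolating each intermediate toward ``y`` with weight
    ``1 - gamma_{t-1}``.  Deterministic given the state of ``rng``.

    ``y`` may be ``(L,)`` or a batch ``(B, L)``; the output matches.
    """
    predict = denoiser.predict_noise if hasattr(denoiser, "predict_noise") else denoiser
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    yb = y[None, :] if squeeze else y

    if fast is None:
        steps = list(range(sched.T, 0, -1))
        embed_t = steps
        coeff = sched
    else:
        steps = list(range(fast.S, 0, -1))
        embed_t = [fast.t_align[s - 1] for s in steps]
        coeff = fast.infer

    x = rng.standard_normal(yb.shape)
    for s, te in zip(steps, embed_t):
        eps_hat = np.asarray(predict(x, te, yb), dtype=float)
        if eps_hat.shape != x.shape:
            raise ValueError("denoiser output shape mismatch")
        z = rng.standard_normal(yb.shape) if s > 1 else 0.0
        if refined:
            x = refined_reverse_step(x, s, eps_hat, yb, coeff, z)
        else:
            x = reverse_step(x, s, eps_hat, coeff, z)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite latent at reverse step t={s}")
    return x[0] if squeeze else x
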