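"""Trial-level generative models for the two rival observers.

The Vector Sum observer perceives deterministically (the same stimulus always
yields bit-identical percepts); all trial-to-trial variability comes from
memory noise with s.d. ``sigma_M`` applied to the first-interval percept of a
two-interval forced choice. The MLE observer redraws noisy per-cue estimates
on every presentation and combines them by inverse-variance weighting.

Closed-form choice probabilities implied by these generative rules:

* Vector Sum: ``P(choose comparison) = Phi((K_c z_c - K_s z_s) / sigma_M)``
* MLE:        ``P(choose comparison) = Phi((z_c - z_s) / sqrt(sigma_Cs^2 + sigma_Cc^2))``
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core import (
    MLEParams,
    Stimulus,
    VecSumParams,
    mle_combine,
    mle_sigma_c,
    vector_sum_depth,
)

__all__ = [
    "ObserverKind",
    "PerceptSample",
    "perceive_vecsum",
    "perceive_mle",
    "trial_2afc",
    "simulate_2afc_block",
    "choice_probability",
]


class ObserverKind(str, enum.Enum):
    """The two observer models every simulator dispatches on."""

    MLE = "mle"
    VECSUM = "vecsum"


@dataclass(frozen=True)
class PerceptSample:
    """A single percept: its value and whether the mapping was deterministic."""

    value: float
    deterministic: bool


def perceive_vecsum(stimulus: Stimulus, params: VecSumParams) -> PerceptSample:
    """Deterministic Vector Sum percept; consumes no randomness."""
    return PerceptSample(value=vector_sum_depth(stimulus), deterministic=True)


def perceive_mle(
    stimulus: Stimulus, params: MLEParams, rng: np.random.Generator
) -> PerceptSample:
    """One noisy MLE percept: per-cue draws ``N(z, sigma_i^2)`` combined by
    inverse-variance weighting; marginally ``N(z, sigma_C^2)``."""
    active = stimulus.strengths.active_labels
    if not active:
        raise ValueError("stimulus has all-zero cue strengths: no depth signal")
    missing = [lab for lab in active if lab not in params.sigmas]
    if missing:
        raise ValueError(f"no noise s.d. provided for presented cue(s) {missing}")
    estimates = {
        lab: float(rng.normal(stimulus.z, params[lab])) for lab in sorted(active)
    }
    sub = MLEParams({lab: params[lab] for lab in active})
    return PerceptSample(value=mle_combine(estimates, sub).mean, deterministic=False)


def choice_probability(
    standard: Stimulus,
    comparison: Stimulus,
    observer: ObserverKind,
    params: VecSumParams | MLEParams,
) -> float:
    """Closed-form P(comparison judged deeper) implied by the generative model."""
    from scipy.stats import norm

    if observer is ObserverKind.VECSUM:
        assert isinstance(params, VecSumParams)
        d = vector_sum_depth(comparison) - vector_sum_depth(standard)
        return float(norm.cdf(d / params.sigma_M))
    assert isinstance(params, MLEParams)
    pooled = np.hypot(mle_sigma_c(standard, params), mle_sigma_c(comparison, params))
    return float(norm.cdf((comparison.z - standard.z) / pooled))


def trial_2afc(
    standard: Stimulus,
    comparison: Stimulus,
    observer: ObserverKind,
    params: VecSumParams | MLEParams,
    rng: np.random.Generator,
) -> tuple[bool, str]:
    """Simulate one two-interval forced-choice trial.

    The interval order is randomized 50/50. For the Vector Sum observer both
    percepts are deterministic and a single ``N(0, sigma_M^2)`` memory draw
    perturbs the first-interval percept (the observer must hold it in memory
    across the inter-stimulus interval). For the MLE observer both percepts
    are fresh noisy draws.

    Returns
    -------
    (resp_cmp_deeper, first_interval)
        ``resp_cmp_deeper`` is True when the comparison is judged deeper;
        ``first_interval`` is ``"standard"`` or ``"comparison"``.
    """
    first = "standard" if rng.random() < 0.5 else "comparison"
    if observer is ObserverKind.VECSUM:
        assert isinstance(params, VecSumParams)
        p_std = vector_sum_depth(standard)
        p_cmp = vector_sum_depth(comparison)
        noise = rng.normal(0.0, params.sigma_M)
        if first == "standard":
            p_std = p_std + noise
        else:
            p_cmp = p_cmp + noise
        return bool(p_cmp > p_std), first
    assert isinstance(params, MLEParams)
    if first == "standard":
        p_std = perceive_mle(standard, params, rng).value
        p_cmp = perceive_mle(comparison, params, rng).value
    else:
        p_cmp = perceive_mle(comparison, params, rng).value
        p_std = perceive_mle(standard, params, rng).value
    return bool(p_cmp > p_std), first


def simulate_2afc_block(
    standard: Stimulus,
    comparison_strengths,
    comparison_depths: np.ndarray,
    observer: ObserverKind,
    params: VecSumParams | MLEParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 2AFC trials: one comparison depth per trial.

    Implements exactly the generative rules of :func:`trial_2afc` with array
    draws (the difference of percepts has the same law whichever interval
    carries the memory noise). Returns ``(resp_cmp_deeper, first_is_standard)``
    boolean arrays aligned with ``comparison_depths``.
    """
    zc = np.asarray(comparison_depths, dtype=float)
    n = zc.size
    first_is_standard = rng.random(n) < 0.5
    if observer is ObserverKind.VECSUM:
        assert isinstance(params, VecSumParams)
        K_s = standard.strengths.norm()
        K_c = comparison_strengths.norm()
        if K_s == 0 or K_c == 0:
            raise ValueError("all-zero cue strengths: no depth signal")
        noise = rng.normal(0.0, params.sigma_M, size=n)
        # memory noise lands on whichever percept came first; the comparison
        # percept gains +noise when the standard was first, -noise otherwise
        diff = K_c * zc - K_s * standard.z + np.where(first_is_standard, -noise, noise)
        return diff > 0, first_is_standard
    assert isinstance(params, MLEParams)
    sig_s = mle_sigma_c(standard, params)
    sig_c = mle_sigma_c(comparison_strengths, params)
    e_std = rng.normal(standard.z, sig_s, size=n)
    e_cmp = rng.normal(zc, sig_c, size=n)
    return e_cmp > e_std, first_is_standard
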