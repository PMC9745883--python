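"""Domain types and closed-form equations of the two depth-cue combination models.

Two rival observer models of 3D depth-cue integration are expressed here in
closed form:

* the **Vector Sum** model of Intrinsic Constraint (IC) theory: each cue module
  maps distal depth ``z`` linearly and deterministically to an internal
  estimate ``k_i * z`` (``k_i`` is the *cue strength*); the combined percept is
  the Euclidean norm of the single-cue estimates, ``z * sqrt(sum k_i**2)``.
  Perceptual variability in a task comes only from task-related (memory) noise
  ``sigma_M``, so the JND for a stimulus of strength ``K`` is ``sigma_M / K``.

* the **MLE** (inverse-variance weighted average) model: each cue yields an
  unbiased but noisy estimate with s.d. ``sigma_i``; cues are averaged with
  weights proportional to ``1 / sigma_i**2``, and the combined noise satisfies
  ``1 / sigma_C**2 = sum 1 / sigma_i**2``.

Only strength-to-noise *ratios* are identifiable from forced-choice data, so
inference elsewhere in the package fixes the gauge ``sigma_M = 1``; perceived
depth is expressed in arbitrary internal units while distal depth is in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "CueStrengths",
    "Stimulus",
    "VecSumParams",
    "MLEParams",
    "CombinedEstimate",
    "vector_sum_depth",
    "combined_strength",
    "mle_combine",
    "mle_sigma_c",
    "jnd_from_strength",
    "combined_jnd_from_single",
    "jitter_strengths",
]


@dataclass(frozen=True)
class CueStrengths:
    """Mapping from cue label to cue strength ``k_i``.

    Cue strength is the slope of the (assumed linear) mapping from distal
    depth in cm to a module's internal depth estimate; it is dimensionless
    in perceived-depth-units per cm. Strengths are non-negative; iteration
    is always in sorted label order so downstream results are deterministic.
    """

    _items: tuple[tuple[str, float], ...] = field(default=())

    def __init__(self, strengths: Mapping[str, float]):
        items = tuple(sorted((str(lab), float(k)) for lab, k in strengths.items()))
        if not items:
            raise ValueError("CueStrengths requires at least one cue label")
        for lab, k in items:
            if not math.isfinite(k) or k < 0:
                raise ValueError(f"cue strength must be finite and >= 0, got {lab}={k}")
        object.__setattr__(self, "_items", items)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self._items)

    @property
    def values(self) -> np.ndarray:
        return np.array([k for _, k in self._items], dtype=float)

    @property
    def active_labels(self) -> tuple[str, ...]:
        """Labels of cues with strictly positive strength."""
        return tuple(lab for lab, k in self._items if k > 0)

    def __getitem__(self, label: str) -> float:
        for lab, k in self._items:
            if lab == label:
                return k
        raise KeyError(label)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def as_dict(self) -> dict[str, float]:
        return dict(self._items)

    def norm(self) -> float:
        """Euclidean norm of the strength vector (the combined strength K)."""
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class Stimulus:
    """A presented stimulus: distal depth (cm) plus per-cue strengths.

    ``z`` must be positive; each cue module's estimate of this stimulus is
    ``k_i * z`` under the linear deterministic mapping.
    """

    z: float
    strengths: CueStrengths

    def __post_init__(self) -> None:
        if not (math.isfinite(self.z) and self.z > 0):
            raise ValueError(f"distal depth z must be finite and > 0, got {self.z}")

    def cue_estimates(self) -> dict[str, float]:
        """Deterministic per-cue estimates ``k_i * z`` (all cues, zeros kept)."""
        return {lab: k * self.z for lab, k in self.strengths}


@dataclass(frozen=True)
class VecSumParams:
    """Vector Sum observer parameters.

    ``sigma_M`` is the s.d. of the task-related memory noise perturbing the
    first-interval percept in a 2AFC trial (perceived-depth units, > 0); it is
    the sole stochastic element of this observer. ``strengths`` optionally
    stores strength vectors keyed by condition label, for observers whose cue
    strengths differ across stimulus classes.
    """

    sigma_M: float = 1.0
    strengths: Mapping[str, CueStrengths] | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma_M) and self.sigma_M > 0):
            raise ValueError(f"sigma_M must be finite and > 0, got {self.sigma_M}")


@dataclass(frozen=True)
class MLEParams:
    """MLE observer parameters: per-cue estimation-noise s.d. ``sigma_i`` (cm)."""

    sigmas: Mapping[str, float]

    def __post_init__(self) -> None:
        sig = dict(self.sigmas)
        if not sig:
            raise ValueError("MLEParams requires at least one cue")
        for lab, s in sig.items():
            if not (math.isfinite(s) and s > 0):
                raise ValueError(f"noise s.d. must be finite and > 0, got {lab}={s}")
        object.__setattr__(self, "sigmas", sig)

    def __getitem__(self, label: str) -> float:
        return self.sigmas[label]


@dataclass(frozen=True)
class CombinedEstimate:
    """A combined depth estimate: mean, spread (s.d.) and optional cue weights."""

    mean: float
    spread: float
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if self.weights is not None:
            w = np.array(list(self.weights.values()), dtype=float)
            if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be non-negative and sum to 1")


def vector_sum_depth(stimulus: Stimulus) -> float:
    """Combined perceived depth under the Vector Sum rule.

    Single-cue estimates ``k_i * z`` are the components of a vector whose
    Euclidean norm is the percept: ``z * sqrt(sum k_i**2)``. With a single
    active cue this reduces to ``k_i * z``; with several it always exceeds
    every single-cue estimate (combined-cue overestimation).

    Raises
    ------
    ValueError
        If every cue strength is zero (no perceivable depth signal; almost
        always a configuration bug, so it is rejected rather than mapped to 0).
    """
    K = stimulus.strengths.norm()
    if K == 0.0:
        raise ValueError("stimulus has all-zero cue strengths: no depth signal")
    return stimulus.z * K


def combined_strength(strengths: CueStrengths) -> float:
    """Combined cue strength ``K = sqrt(sum k_i**2)``.

    The combined stimulus inherits a linear depth mapping whose slope is the
    Euclidean norm of the single-cue slopes; hence ``K >= max_i k_i`` with
    equality only when a single cue is active.
    """
    return strengths.norm()


def mle_combine(estimates: Mapping[str, float], params: MLEParams) -> CombinedEstimate:
    """Inverse-variance weighted combination of single-cue estimates.

    Weights are ``w_i = (1/sigma_i^2) / sum_j (1/sigma_j^2)``; the combined
    mean is ``sum w_i * zhat_i`` and the combined s.d. satisfies
    ``1/sigma_C^2 = sum 1/sigma_i^2``, so ``sigma_C <= min_i sigma_i``.
    """
    est = dict(estimates)
    if not est:
        raise ValueError("no estimates to combine")
    if set(est) != set(params.sigmas):
        raise ValueError(
            f"cue labels differ between estimates {sorted(est)} and "
            f"params {sorted(params.sigmas)}"
        )
    labels = sorted(est)
    z = np.array([est[lab] for lab in labels], dtype=float)
    prec = np.array([1.0 / params[lab] ** 2 for lab in labels])
    w = prec / prec.sum()
    return CombinedEstimate(
        mean=float(w @ z),
        spread=float(1.0 / math.sqrt(prec.sum())),
        weights=dict(zip(labels, w.tolist())),
    )


def mle_sigma_c(stimulus_or_strengths: Stimulus | CueStrengths, params: MLEParams) -> float:
    """Combined-estimate noise s.d. for the cues active in a stimulus.

    For a single-cue stimulus this is that cue's ``sigma_i``; for a combined
    stimulus it is the inverse-variance pooled s.d. with no extra free
    parameter.
    """
    strengths = (
        stimulus_or_strengths.strengths
        if isinstance(stimulus_or_strengths, Stimulus)
        else stimulus_or_strengths
    )
    active = strengths.active_labels
    if not active:
        raise ValueError("stimulus has all-zero cue strengths: no depth signal")
    missing = [lab for lab in active if lab not in params.sigmas]
    if missing:
        raise ValueError(f"no noise s.d. provided for presented cue(s) {missing}")
    prec = sum(1.0 / params[lab] ** 2 for lab in active)
    return 1.0 / math.sqrt(prec)


def jnd_from_strength(K: float, sigma_M: float) -> float:
    """JND implied by the Vector Sum model: ``sigma_M / K``.

    Discrimination succeeds when the perceived-depth difference overcomes the
    task noise, so the distal depth increment required is inversely
    proportional to the stimulus strength.
    """
    if not (math.isfinite(K) and K > 0):
        raise ValueError(f"strength K must be > 0, got {K}")
    if not (math.isfinite(sigma_M) and sigma_M > 0):
        raise ValueError(f"sigma_M must be > 0, got {sigma_M}")
    return sigma_M / K


def combined_jnd_from_single(jnds: "list[float] | np.ndarray") -> float:
    """Combined-stimulus JND from single-cue JNDs: ``1/JND_C^2 = sum 1/JND_i^2``.

    This inverse-squares rule is formally identical to the MLE prediction for
    pooled noise, even though under the Vector Sum model it arises purely from
    strength summation (``JND_i = sigma_M/k_i`` and ``K_C = sqrt(sum k_i^2)``).
    """
    arr = np.asarray(jnds, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one JND")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("all JNDs must be finite and > 0")
    return float(1.0 / math.sqrt(np.sum(1.0 / arr**2)))


def jitter_strengths(
    strengths: CueStrengths, rel_sd: float, rng: np.random.Generator
) -> CueStrengths:
    """Nuisance-parameter jitter: multiply each strength by an independent
    lognormal-ish factor ``max(1 + N(0, rel_sd^2), 0)``.

    Off by default everywhere; exists to demonstrate the norm's robustness —
    the combined strength moves proportionally less than the perturbed
    components do (material, illumination or distance changes alter cue
    strengths without altering distal depth).
    """
    if rel_sd < 0:
        raise ValueError("rel_sd must be >= 0")
    factors = np.maximum(1.0 + rng.normal(0.0, rel_sd, size=len(strengths)), 0.0)
    return CueStrengths(
        {lab: k * f for (lab, k), f in zip(strengths, factors)}
    )
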