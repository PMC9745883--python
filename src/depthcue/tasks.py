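"""Simulators for full psychophysical experiments.

Four task paradigms are covered, each a pure function of (design, observer
parameters, seed):

* method of constant stimuli, 2AFC depth discrimination;
* adaptive 1-up-2-down staircase, 2AFC;
* cross-cue depth matching (adjust comparison depth to a perceptual match);
* magnitude estimation (probe adjustment, one judged depth per presentation).

Trial tables are plain :class:`pandas.DataFrame` objects with the columns
``condition_id, z_std, std_cues, z_cmp, cmp_cues, first_interval,
resp_cmp_deeper`` so that the same psychometric fitter serves every 2AFC
paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CueStrengths, MLEParams, Stimulus, VecSumParams
from .observers import ObserverKind, simulate_2afc_block
from .rng import derive_rng

__all__ = [
    "TRIAL_COLUMNS",
    "ConstantStimuliDesign",
    "StaircaseResult",
    "MatchResult",
    "default_comparison_levels",
    "run_constant_stimuli",
    "run_staircase",
    "run_matching",
    "run_magnitude_estimation",
]

TRIAL_COLUMNS = [
    "condition_id",
    "z_std",
    "std_cues",
    "z_cmp",
    "cmp_cues",
    "first_interval",
    "resp_cmp_deeper",
]


@dataclass(frozen=True)
class ConstantStimuliDesign:
    """A constant-stimuli 2AFC condition.

    The standard stimulus is fixed throughout; the comparison takes each depth
    in ``levels`` (cm, ascending) ``trials_per_level`` times, in shuffled
    order. ``std_cues_id``/``cmp_cues_id`` are labels recorded in the trial
    table so multi-condition fits can group by stimulus class.
    """

    condition_id: str
    standard: Stimulus
    comparison_strengths: CueStrengths
    levels: tuple[float, ...]
    trials_per_level: int = 40
    seed: int = 0
    std_cues_id: str = "standard"
    cmp_cues_id: str = "comparison"

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        if len(set(levels)) < 2:
            raise ValueError("need at least 2 distinct comparison levels")
        if list(levels) != sorted(levels):
            raise ValueError("comparison levels must be sorted ascending")
        if any(v <= 0 for v in levels):
            raise ValueError("comparison depths must be > 0")
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")
        object.__setattr__(self, "levels", levels)


@dataclass(frozen=True)
class StaircaseResult:
    """Output of an adaptive staircase run.

    ``trials`` is fitter-compatible; ``converged`` is False when the
    max-trial cap was hit before the requested number of reversals.
    """

    trials: pd.DataFrame
    reversal_depths: tuple[float, ...]
    step_sizes: tuple[float, ...]
    converged: bool


@dataclass(frozen=True)
class MatchResult:
    """Result of a cross-cue matching run: standard depth, mean matched depth
    and the individual adjustment settlements."""

    z1: float
    z2: float
    adjustments: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.z2 <= 0:
            raise ValueError("matched depth must be > 0")


def default_comparison_levels(pse: float, jnd: float, *, n_levels: int = 7, max_span: float = 1.5) -> tuple[float, ...]:
    """Comparison depths at predicted PSE ± {0, 0.5, 1, 1.5} × predicted JND.

    Levels are clipped away from zero (depths must stay positive); the
    placement keeps psychometric fits well-conditioned for either observer.
    """
    offsets = np.linspace(-max_span, max_span, n_levels)
    levels = pse + offsets * jnd
    floor = 0.05 * pse
    return tuple(float(v) for v in np.maximum(levels, floor))


def run_constant_stimuli(
    design: ConstantStimuliDesign,
    observer: ObserverKind,
    params: VecSumParams | MLEParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one constant-stimuli condition; one row per trial.

    Deterministic given (design, params): the default stream is derived from
    ``design.seed`` and ``design.condition_id``.
    """
    if rng is None:
        rng = derive_rng(design.seed, "constant_stimuli", design.condition_id)
    depths = np.repeat(np.asarray(design.levels, dtype=float), design.trials_per_level)
    rng.shuffle(depths)
    resp, first_std = simulate_2afc_block(
        design.standard, design.comparison_strengths, depths, observer, params, rng
    )
    return pd.DataFrame(
        {
            "condition_id": design.condition_id,
            "z_std": design.standard.z,
            "std_cues": design.std_cues_id,
            "z_cmp": depths,
            "cmp_cues": design.cmp_cues_id,
            "first_interval": np.where(first_std, "standard", "comparison"),
            "resp_cmp_deeper": resp.astype(int),
        },
        columns=TRIAL_COLUMNS,
    )


def run_staircase(
    standard: Stimulus,
    comparison_strengths: CueStrengths,
    observer: ObserverKind,
    params: VecSumParams | MLEParams,
    rng: np.random.Generator,
    *,
    rule: str = "1up2down",
    start: float | None = None,
    initial_step: float | None = None,
    n_reversals: int = 12,
    max_trials: int = 400,
    condition_id: str = "staircase",
    std_cues_id: str = "standard",
    cmp_cues_id: str = "comparison",
) -> StaircaseResult:
    """Transformed 1-up-2-down staircase (converges on the 70.7% point).

    Two consecutive "comparison deeper" responses lower the comparison depth
    by the current step; any "not deeper" raises it. The step halves after
    each of the first three reversals. Stops at ``n_reversals`` reversals or
    ``max_trials`` trials, whichever first; hitting the cap is flagged via
    ``converged=False`` rather than raised.
    """
    if rule != "1up2down":
        raise ValueError(f"unsupported staircase rule {rule!r}; only '1up2down'")
    K_s = standard.strengths.norm()
    K_c = comparison_strengths.norm()
    if K_c == 0:
        raise ValueError("comparison strengths are all zero")
    if start is None:
        # begin well above the expected convergence point
        start = (K_s / K_c) * standard.z * 1.5
    if initial_step is None:
        initial_step = 0.1 * start

    z = float(start)
    step = float(initial_step)
    floor = 1e-3 * standard.z
    rows: list[tuple] = []
    reversals: list[float] = []
    steps: list[float] = []
    down_count = 0
    last_dir = 0  # +1 up, -1 down
    while len(reversals) < n_reversals and len(rows) < max_trials:
        resp, first_std = simulate_2afc_block(
            standard, comparison_strengths, np.array([z]), observer, params, rng
        )
        deeper = bool(resp[0])
        rows.append(
            (
                condition_id,
                standard.z,
                std_cues_id,
                z,
                cmp_cues_id,
                "standard" if first_std[0] else "comparison",
                int(deeper),
            )
        )
        if deeper:
            down_count += 1
            move = -1 if down_count == 2 else 0
        else:
            down_count = 0
            move = +1
        if move:
            if down_count == 2:
                down_count = 0
            if last_dir and move != last_dir:
                reversals.append(z)
                steps.append(step)
                if len(reversals) <= 3:
                    step /= 2.0
            last_dir = move
            z = max(z + move * step, floor)
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return StaircaseResult(
        trials=trials,
        reversal_depths=tuple(reversals),
        step_sizes=tuple(steps),
        converged=len(reversals) >= n_reversals,
    )


def run_matching(
    standard: Stimulus,
    comparison_strengths: CueStrengths,
    observer: ObserverKind,
    params: VecSumParams | MLEParams,
    n_adjustments: int,
    rng: np.random.Generator,
    *,
    adjustment_noise_sd: float | None = None,
) -> MatchResult:
    """Cross-cue depth matching: vary comparison depth z2 to a perceptual match.

    Vector Sum: percepts are deterministic, so each adjustment settles where
    ``K2 z2 = K1 z1`` (i.e. at ``z2 = (K1/K2) z1``) plus motor/adjustment
    noise in distal units (default s.d. 0.05·z1; 0 gives exact settlements).
    MLE: the observer equates two noisy estimates, so each settlement is
    ``z1 + e1 − e2`` with ``e_i ~ N(0, sigma_Ci^2)`` — unbiased around z1.
    """
    if n_adjustments < 1:
        raise ValueError("n_adjustments must be >= 1")
    K_c = comparison_strengths.norm()
    if K_c == 0:
        raise ValueError("comparison strength is zero: match undefined")
    z1 = standard.z
    if adjustment_noise_sd is None:
        adjustment_noise_sd = 0.05 * z1
    if observer is ObserverKind.VECSUM:
        assert isinstance(params, VecSumParams)
        K_s = standard.strengths.norm()
        target = (K_s / K_c) * z1
        settle = target + (
            rng.normal(0.0, adjustment_noise_sd, size=n_adjustments)
            if adjustment_noise_sd > 0
            else np.zeros(n_adjustments)
        )
    else:
        assert isinstance(params, MLEParams)
        from .core import mle_sigma_c

        sig1 = mle_sigma_c(standard, params)
        sig2 = mle_sigma_c(comparison_strengths, params)
        settle = (
            z1
            + rng.normal(0.0, sig1, size=n_adjustments)
            - rng.normal(0.0, sig2, size=n_adjustments)
        )
        if adjustment_noise_sd > 0:
            settle = settle + rng.normal(0.0, adjustment_noise_sd, size=n_adjustments)
    settle = np.maximum(settle, 1e-6 * z1)
    return MatchResult(
        z1=z1, z2=float(settle.mean()), adjustments=tuple(float(v) for v in settle)
    )


def run_magnitude_estimation(
    stimuli: Sequence[Stimulus],
    observer: ObserverKind,
    params: VecSumParams | MLEParams,
    response_noise: float,
    rng: np.random.Generator,
    *,
    trials_per_stimulus: int = 1,
    condition_id: str = "magnitude",
) -> pd.DataFrame:
    """Magnitude estimation: judged depth per presentation.

    Vector Sum judgments are ``K·z`` plus additive Gaussian response noise,
    so a linear regression of judgments on distal depth recovers the combined
    strength K. MLE judgments are unbiased noisy estimates ``N(z, sigma_C^2)``
    plus the same response noise.
    """
    if response_noise < 0:
        raise ValueError("response noise must be >= 0")
    if trials_per_stimulus < 1:
        raise ValueError("trials_per_stimulus must be >= 1")
    zs, judged = [], []
    for stim in stimuli:
        if observer is ObserverKind.VECSUM:
            assert isinstance(params, VecSumParams)
            base = stim.strengths.norm() * stim.z
            if stim.strengths.norm() == 0:
                raise ValueError("stimulus has all-zero cue strengths")
            vals = np.full(trials_per_stimulus, base)
        else:
            assert isinstance(params, MLEParams)
            from .core import mle_sigma_c

            sig = mle_sigma_c(stim, params)
            vals = rng.normal(stim.z, sig, size=trials_per_stimulus)
        if response_noise > 0:
            vals = vals + rng.normal(0.0, response_noise, size=trials_per_stimulus)
        zs.extend([stim.z] * trials_per_stimulus)
        judged.extend(vals.tolist())
    return pd.DataFrame(
        {"condition_id": condition_id, "z": zs, "judged_depth": judged}
    )
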