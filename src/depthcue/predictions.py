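"""Closed-form predictions and model-based inference.

This module turns the two observer models into testable predictions for
crossed standard/comparison discrimination designs, cross-cue matching and
cue-combination magnitude estimation, and fits either model to multi-condition
trial tables by maximum likelihood for AIC-based model comparison.

Key closed forms, writing ``K_s``/``K_c`` for standard/comparison combined
strengths and ``sigma_Cs``/``sigma_Cc`` for the MLE pooled noise s.d.:

===========  =======================  ==============================
model        PSE                      JND (slope^-1 of the curve)
===========  =======================  ==============================
Vector Sum   (K_s / K_c) * z_s        sigma_M / K_c
MLE          z_s                      sqrt(sigma_Cs^2 + sigma_Cc^2)
===========  =======================  ==============================

The distinguishing signatures: under the Vector Sum model the JND depends
only on the comparison stimulus, and PSEs shift whenever strengths differ;
under MLE all PSEs are veridical and the JND pools both stimuli's noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .core import (
    CueStrengths,
    MLEParams,
    VecSumParams,
    combined_strength,
    mle_sigma_c,
)
from .observers import ObserverKind

__all__ = [
    "ConditionSpec",
    "ModelComparison",
    "ObserverFit",
    "predict_condition",
    "crossed_design_table",
    "predict_match_from_jnds",
    "strength_ratio_from_jnds",
    "predict_combined_line",
    "fit_observer_model",
    "compare_models",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One discrimination condition: which class is the fixed standard, which
    the variable comparison, and the standard's depth (cm)."""

    standard_id: str
    comparison_id: str
    z_s: float
    standard: CueStrengths
    comparison: CueStrengths

    def __post_init__(self) -> None:
        if self.z_s <= 0:
            raise ValueError("standard depth must be > 0")


@dataclass(frozen=True)
class ObserverFit:
    """Maximum-likelihood parameters of one observer model on a trial table.

    ``params`` maps stimulus-class id to the fitted strength K (Vector Sum,
    gauge sigma_M = 1) or noise s.d. sigma (MLE).
    """

    model: ObserverKind
    params: dict[str, float]
    loglik: float
    n_params: int
    n_trials: int


@dataclass(frozen=True)
class ModelComparison:
    """AIC adjudication between the two observer models."""

    fits: dict[str, ObserverFit]
    aic: dict[str, float]
    selected: str
    tie: bool
    low_power: bool = False


def predict_condition(
    model: ObserverKind,
    condition: ConditionSpec,
    params: VecSumParams | MLEParams,
) -> tuple[float, float]:
    """Closed-form (PSE, JND) for one condition under one model."""
    K_c = combined_strength(condition.comparison)
    if K_c == 0:
        raise ValueError("comparison stimulus has zero strength")
    if model is ObserverKind.VECSUM:
        assert isinstance(params, VecSumParams)
        K_s = combined_strength(condition.standard)
        return (K_s / K_c) * condition.z_s, params.sigma_M / K_c
    assert isinstance(params, MLEParams)
    sig_s = mle_sigma_c(condition.standard, params)
    sig_c = mle_sigma_c(condition.comparison, params)
    return condition.z_s, math.hypot(sig_s, sig_c)


def crossed_design_table(
    model: ObserverKind,
    classes: Mapping[str, CueStrengths],
    params: VecSumParams | MLEParams,
    z_s: float,
) -> pd.DataFrame:
    """Predictions for the full 2x2 crossing of two stimulus classes.

    Each class serves once as the fixed standard and once as the variable
    comparison (4 conditions). Under the Vector Sum model the two rows sharing
    a comparison class have exactly equal JNDs; under MLE all four rows share
    PSE = z_s.
    """
    ids = list(classes)
    if len(ids) != 2:
        raise ValueError(f"crossed design needs exactly 2 stimulus classes, got {len(ids)}")
    rows = []
    for sid in ids:
        for cid in ids:
            cond = ConditionSpec(sid, cid, z_s, classes[sid], classes[cid])
            pse, jnd = predict_condition(model, cond, params)
            rows.append(
                {
                    "model": model.value,
                    "standard": sid,
                    "comparison": cid,
                    "z_s": z_s,
                    "pse": pse,
                    "jnd": jnd,
                }
            )
    return pd.DataFrame(rows)


def predict_match_from_jnds(z1: float, jnd1: float, jnd2: float) -> float:
    """Vector Sum matching law: the comparison depth perceptually matching a
    standard at ``z1`` is ``z2 = (JND2 / JND1) * z1``.

    Strengths are inversely proportional to JNDs (``k = sigma_M / JND``), so
    the unobservable strength ratio ``k1/k2`` equals ``JND2/JND1`` and the
    match point ``z2 = (k1/k2) z1`` follows from discrimination data alone.
    """
    if z1 <= 0 or jnd1 <= 0 or jnd2 <= 0:
        raise ValueError("z1 and both JNDs must be > 0")
    return (jnd2 / jnd1) * z1


def strength_ratio_from_jnds(jnd_i: float, jnd_j: float) -> float:
    """Cue-strength ratio ``k_i / k_j = JND_j / JND_i``."""
    if jnd_i <= 0 or jnd_j <= 0:
        raise ValueError("JNDs must be > 0")
    return jnd_j / jnd_i


def predict_combined_line(
    slopes: Sequence[float],
    slope_ses: Sequence[float] | None,
    n_boot: int,
    rng: np.random.Generator,
    *,
    level: float = 0.95,
) -> dict:
    """Combined-cue slope predicted from single-cue slopes, with a CI band.

    The point prediction is the Euclidean norm ``sqrt(sum slope_i^2)`` (never
    below the largest single slope). Uncertainty is propagated by parametric
    bootstrap: each draw samples every slope from ``N(slope_i, se_i^2)``,
    clips negative draws at 0 (counted; a clipping rate above 5% sets a
    warning flag) and records the norm; the band is the percentile interval.
    """
    s = np.asarray(slopes, dtype=float)
    if s.size < 2:
        raise ValueError("need >= 2 single-cue slopes")
    point = float(np.linalg.norm(s))
    out = {"combined_slope": point, "n_boot": 0, "clip_rate": 0.0, "clip_warning": False}
    if slope_ses is None or n_boot < 1:
        return out
    se = np.asarray(slope_ses, dtype=float)
    draws = rng.normal(s, se, size=(n_boot, s.size))
    n_clipped = int((draws < 0).sum())
    draws = np.clip(draws, 0.0, None)
    norms = np.linalg.norm(draws, axis=1)
    alpha = (1 - level) / 2
    clip_rate = n_clipped / draws.size
    out.update(
        n_boot=n_boot,
        low=float(np.quantile(norms, alpha)),
        high=float(np.quantile(norms, 1 - alpha)),
        clip_rate=clip_rate,
        clip_warning=clip_rate > 0.05,
    )
    return out


def _cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a trial table into (std class, z_std, cmp class, z_cmp) cells."""
    required = {"std_cues", "z_std", "cmp_cues", "z_cmp", "resp_cmp_deeper"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    g = (
        trials.groupby(["std_cues", "z_std", "cmp_cues", "z_cmp"])["resp_cmp_deeper"]
        .agg(["sum", "count"])
        .reset_index()
    )
    return g


def fit_observer_model(
    trials: pd.DataFrame,
    model: ObserverKind,
) -> ObserverFit:
    """Fit one observer model to a multi-condition trial table by maximum
    likelihood over per-trial choice probabilities.

    Vector Sum: one strength K per stimulus-class id, in the gauge
    ``sigma_M = 1`` (only K/sigma_M is identifiable from forced choice), so
    ``P = Phi(K_c z_c - K_s z_s)``. MLE: one noise s.d. per class id, with
    ``P = Phi((z_c - z_s) / sqrt(sigma_s^2 + sigma_c^2))``; a crossed design
    identifies every class sigma, so none is held fixed.

    Raises
    ------
    ValueError
        Empty table, or a single-condition design (the strength gauge leaves
        the model unidentifiable without conditions that share classes).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    cells = _cells(trials)
    conds = cells[["std_cues", "cmp_cues"]].drop_duplicates()
    if len(conds) < 2:
        raise ValueError(
            "need >= 2 standard/comparison conditions sharing stimulus classes; "
            "a single condition only identifies one strength-to-noise ratio"
        )
    class_ids = sorted(set(cells["std_cues"]) | set(cells["cmp_cues"]))
    idx = {cid: i for i, cid in enumerate(class_ids)}
    i_s = cells["std_cues"].map(idx).to_numpy()
    i_c = cells["cmp_cues"].map(idx).to_numpy()
    z_s = cells["z_std"].to_numpy(dtype=float)
    z_c = cells["z_cmp"].to_numpy(dtype=float)
    k = cells["sum"].to_numpy(dtype=float)
    n = cells["count"].to_numpy(dtype=float)

    def nll(log_theta: np.ndarray) -> float:
        theta = np.exp(log_theta)
        if model is ObserverKind.VECSUM:
            d = theta[i_c] * z_c - theta[i_s] * z_s
        else:
            d = (z_c - z_s) / np.sqrt(theta[i_s] ** 2 + theta[i_c] ** 2)
        p = np.clip(norm.cdf(d), 1e-12, 1 - 1e-12)
        return float(-(k * np.log(p) + (n - k) * np.log(1 - p)).sum())

    x0 = np.zeros(len(class_ids))
    best = None
    for scale in (1.0, 0.5, 2.0):
        res = minimize(nll, x0 + math.log(scale), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = np.exp(best.x)
    return ObserverFit(
        model=model,
        params={cid: float(theta[idx[cid]]) for cid in class_ids},
        loglik=-float(best.fun),
        n_params=len(class_ids),
        n_trials=int(n.sum()),
    )


def compare_models(trials: pd.DataFrame, *, low_power_n: int = 100) -> ModelComparison:
    """Fit both observer models and adjudicate by AIC.

    ``low_power`` is set when the table holds fewer than ``low_power_n``
    trials, where selection is unreliable; ties (identical AIC to 1e-6) are
    reported explicitly and resolved alphabetically.
    """
    fits = {
        kind.value: fit_observer_model(trials, kind)
        for kind in (ObserverKind.MLE, ObserverKind.VECSUM)
    }
    aic = {name: 2 * f.n_params - 2 * f.loglik for name, f in fits.items()}
    names = sorted(aic)
    tie = abs(aic[names[0]] - aic[names[1]]) < 1e-6
    selected = min(names, key=lambda nm: (aic[nm], nm))
    return ModelComparison(
        fits=fits,
        aic=aic,
        selected=selected,
        tie=tie,
        low_power=len(trials) < low_power_n,
    )
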