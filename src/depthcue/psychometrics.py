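"""Cumulative-Gaussian psychometric fitting: PSE, JND, bootstrap CIs.

The psychometric function relates comparison depth to the probability of
judging the comparison deeper than the standard; it is modelled as

    P(resp) = lapse/2 + (1 - lapse) * Phi((z_cmp - pse) / sigma)

fit by maximum Bernoulli likelihood. ``sigma`` doubles as the JND: one sigma
above the PSE the (lapse-free) model predicts Phi(1) ≈ 84.1% "deeper"
responses, the conventional 84% discrimination criterion. The lapse rate is
fixed at 0 by default; optionally a single shared lapse in [0, 0.06] is fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "BootstrapCI",
    "fit_psychometric",
    "jnd_from_fit",
    "predict_response_rate",
    "bootstrap_fit",
]

LAPSE_MAX = 0.06


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted psychometric parameters for one condition."""

    pse: float
    sigma: float
    lapse: float
    loglik: float
    n_trials: int
    converged: bool
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0.0 <= self.lapse <= LAPSE_MAX):
            raise ValueError(f"lapse must lie in [0, {LAPSE_MAX}]")
        if self.loglik > 1e-9:
            raise ValueError("log-likelihood of binary data cannot be positive")


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence interval for one parameter."""

    parameter: str
    low: float
    high: float
    n_boot: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must be <= high")

    def covers(self, value: float) -> bool:
        return self.low <= value <= self.high


def _aggregate(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    grp = trials.groupby("z_cmp")["resp_cmp_deeper"]
    agg = grp.agg(["sum", "count"]).reset_index().sort_values("z_cmp")
    return (
        agg["z_cmp"].to_numpy(dtype=float),
        agg["sum"].to_numpy(dtype=float),
        agg["count"].to_numpy(dtype=float),
    )


def _nll(theta: np.ndarray, z: np.ndarray, k: np.ndarray, n: np.ndarray, fit_lapse: bool) -> float:
    pse, log_sigma = theta[0], theta[1]
    lapse = theta[2] if fit_lapse else 0.0
    sigma = math.exp(log_sigma)
    p = lapse / 2.0 + (1.0 - lapse) * norm.cdf((z - pse) / sigma)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-(k * np.log(p) + (n - k) * np.log(1.0 - p)).sum())


def _probit_init(z: np.ndarray, k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Probit-regression starting values (pse, sigma)."""
    import warnings

    import statsmodels.api as sm

    span = z.max() - z.min()
    try:
        X = sm.add_constant(z)
        model = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial(sm.families.links.Probit()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=50)
        b0, b1 = res.params
        if b1 > 1e-9:
            return float(-b0 / b1), float(min(1.0 / b1, 100 * span))
    except Exception:
        pass
    return float(z.mean()), float(max(span / 2.0, 1e-6))


def fit_psychometric(
    trials: pd.DataFrame,
    *,
    fit_lapse: bool = False,
    n_starts: int = 5,
    start: tuple[float, float] | None = None,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit for one condition's trials.

    Uses bounded L-BFGS-B with multi-start (jittered around a probit-regression
    initializer); the best log-likelihood wins, ties broken by smaller sigma.
    Degenerate data are flagged rather than raised: perfectly separated
    responses push sigma to its lower bound (``converged=False``,
    ``"sigma_at_lower_bound"``), response rates flat in depth push sigma to its
    upper bound (``"sigma_at_upper_bound"``, ``"pse_unidentifiable"``).

    Raises
    ------
    ValueError
        Fewer than 2 distinct comparison levels, or only one response
        category present overall.
    """
    z, k, n = _aggregate(trials)
    if z.size < 2:
        raise ValueError("need >= 2 distinct comparison levels to fit")
    if k.sum() == 0 or k.sum() == n.sum():
        raise ValueError("both response categories must be present to fit")
    span = float(z.max() - z.min())
    sigma_lo, sigma_hi = 1e-4 * span, 50.0 * span
    bounds = [
        (z.min() - 2 * span, z.max() + 2 * span),
        (math.log(sigma_lo), math.log(sigma_hi)),
    ]
    if fit_lapse:
        bounds.append((0.0, LAPSE_MAX))

    if start is not None:
        starts = [start]
    else:
        pse0, sigma0 = _probit_init(z, k, n)
        sigma0 = float(np.clip(sigma0, sigma_lo * 2, sigma_hi / 2))
        pse0 = float(np.clip(pse0, bounds[0][0], bounds[0][1]))
        rng = np.random.default_rng(0)  # jitter pattern is part of the algorithm
        starts = [(pse0, sigma0)]
        for _ in range(n_starts - 1):
            starts.append(
                (
                    float(np.clip(pse0 + rng.normal(0, 0.2 * span), *bounds[0])),
                    float(np.clip(sigma0 * math.exp(rng.normal(0, 0.5)), sigma_lo * 2, sigma_hi / 2)),
                )
            )

    best = None
    for pse0, sigma0 in starts:
        theta0 = [pse0, math.log(sigma0)] + ([0.01] if fit_lapse else [])
        res = minimize(
            _nll,
            np.asarray(theta0),
            args=(z, k, n, fit_lapse),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None:
            best = res
        elif res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9 and res.x[1] < best.x[1]
        ):
            best = res
    assert best is not None

    pse = float(best.x[0])
    sigma = float(math.exp(best.x[1]))
    lapse = float(best.x[2]) if fit_lapse else 0.0
    flags: list[str] = []
    converged = bool(best.success)
    if sigma <= sigma_lo * 2.05 or -best.fun > -1e-6:
        # a perfect (zero-deviance) fit means the data are separated and
        # sigma is running to its lower bound
        flags.append("sigma_at_lower_bound")
        converged = False
    if sigma >= sigma_hi / 2.05:
        flags.append("sigma_at_upper_bound")
        flags.append("pse_unidentifiable")
        converged = False
    return PsychometricFit(
        pse=pse,
        sigma=sigma,
        lapse=lapse,
        loglik=-float(best.fun),
        n_trials=int(n.sum()),
        converged=converged,
        flags=tuple(flags),
    )


def jnd_from_fit(fit: PsychometricFit) -> float:
    """The JND is the fitted sigma: the depth increment above the PSE at which
    the (lapse-free) model predicts Phi(1) ≈ 84.1% "deeper" responses."""
    if not fit.converged:
        raise ValueError("cannot report a JND from an unconverged fit")
    return fit.sigma


def predict_response_rate(fit: PsychometricFit, z_cmp: float) -> float:
    """Model-predicted P(comparison judged deeper) at a comparison depth."""
    return float(
        fit.lapse / 2.0 + (1.0 - fit.lapse) * norm.cdf((z_cmp - fit.pse) / fit.sigma)
    )


def bootstrap_fit(
    trials: pd.DataFrame,
    n_boot: int,
    rng: np.random.Generator,
    *,
    parameters: tuple[str, ...] = ("pse", "sigma"),
    level: float = 0.95,
    fit_lapse: bool = False,
    max_failure_rate: float = 0.20,
) -> dict[str, BootstrapCI]:
    """Nonparametric bootstrap CIs: resample trials within each level, refit.

    Each replicate refits from the full-data estimate (single start). If more
    than ``max_failure_rate`` of replicates fail to fit, an error reporting
    the failure rate is raised rather than returning unreliable intervals.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    full = fit_psychometric(trials, fit_lapse=fit_lapse)
    z, k, n = _aggregate(trials)
    draws: dict[str, list[float]] = {p: [] for p in parameters}
    failures = 0
    for _ in range(n_boot):
        k_b = rng.binomial(n.astype(int), k / n)
        boot = pd.DataFrame(
            {
                "z_cmp": np.repeat(z, n.astype(int)),
                "resp_cmp_deeper": np.concatenate(
                    [
                        np.r_[np.ones(int(kb)), np.zeros(int(nn - kb))]
                        for kb, nn in zip(k_b, n)
                    ]
                ),
            }
        )
        try:
            f = fit_psychometric(
                boot, fit_lapse=fit_lapse, start=(full.pse, full.sigma), n_starts=1
            )
        except ValueError:
            failures += 1
            continue
        if not f.converged:
            failures += 1
            continue
        for p in parameters:
            draws[p].append(getattr(f, p))
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(
            f"bootstrap refit failure rate {failures / n_boot:.1%} exceeds "
            f"{max_failure_rate:.0%}"
        )
    alpha = (1.0 - level) / 2.0
    out = {}
    for p in parameters:
        arr = np.asarray(draws[p])
        out[p] = BootstrapCI(
            parameter=p,
            low=float(np.quantile(arr, alpha)),
            high=float(np.quantile(arr, 1 - alpha)),
            n_boot=n_boot,
            level=level,
        )
    return out
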