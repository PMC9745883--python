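"""Synthetic experiment bundles emulating the four study designs.

Each scenario generates, from a seed and an observer model, the complete set
of trial tables a real study of that design would produce, plus a config and
manifest, so every analysis stage in the package can be exercised without any
external data:

* ``crossed-single-cue`` — two single-cue texture classes of different
  strength, each serving as standard and comparison (2x2 discrimination).
* ``crossed-single-vs-combined`` — a single-cue class crossed with the
  combined-cue class (2x2 discrimination).
* ``matching-plus-discrimination`` — separate motion and disparity
  discrimination runs plus a cross-cue depth-matching run.
* ``magnitude-two-distances`` — magnitude estimation for texture, disparity
  and combined stimuli under two viewing-distance parameter sets (distance is
  a label on strength sets only, not geometry).

Default parameter values are invented placeholders chosen so each scenario's
qualitative signature is detectable at the default trial counts; the manifest
records them as such.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import CueStrengths, MLEParams, Stimulus, VecSumParams
from .observers import ObserverKind
from .predictions import ConditionSpec, predict_condition
from .rng import derive_rng
from .tasks import (
    ConstantStimuliDesign,
    default_comparison_levels,
    run_constant_stimuli,
    run_magnitude_estimation,
    run_matching,
)

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioSpec",
    "ScenarioBundle",
    "default_parameters",
    "generate_scenario",
]

SCENARIO_NAMES = (
    "crossed-single-cue",
    "crossed-single-vs-combined",
    "matching-plus-discrimination",
    "magnitude-two-distances",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named scenario plus its full parameter set and mandatory seed."""

    name: str
    parameters: dict
    seed: int

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
            )


@dataclass(frozen=True)
class ScenarioBundle:
    """Generated scenario data: named tables plus the resolved config."""

    spec: ScenarioSpec
    observer: ObserverKind
    tables: dict[str, pd.DataFrame]
    config: dict
    extras: dict = field(default_factory=dict)

    def checksums(self) -> dict[str, str]:
        """SHA-256 of each table's CSV serialization (what write() puts on disk)."""
        return {
            name: hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()
            for name, df in sorted(self.tables.items())
        }

    def write(self, outdir) -> dict:
        """Write trials_*.csv, config.json and manifest.json; returns manifest."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            df.to_csv(out / f"trials_{name}.csv", index=False)
        (out / "config.json").write_text(json.dumps(self.config, indent=2, sort_keys=True))
        manifest = {
            "scenario": self.spec.name,
            "observer": self.observer.value,
            "seed": self.spec.seed,
            "parameters": self.spec.parameters,
            "parameter_provenance": "invented placeholder defaults unless overridden",
            "checksums": self.checksums(),
            "extras": self.extras,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest


def default_parameters(name: str) -> dict:
    """Documented default parameter set for a scenario.

    Strengths k are dimensionless slopes, noise s.d.s sigma are in cm,
    sigma_M is in perceived-depth units (gauge 1), depths in cm.
    """
    if name == "crossed-single-cue":
        return {
            "classes": {"T1": {"texture_strong": 1.0}, "T2": {"texture_weak": 0.5}},
            "mle_sigmas": {"texture_strong": 1.0, "texture_weak": 2.0},
            "sigma_M": 1.0,
            "z_s": 10.0,
            "n_levels": 7,
            "trials_per_level": 40,
        }
    if name == "crossed-single-vs-combined":
        return {
            "classes": {
                "single": {"disparity": 0.8},
                "combined": {"texture": 0.6, "disparity": 0.8},
            },
            "mle_sigmas": {"texture": 1.0, "disparity": 1.0},
            "sigma_M": 1.0,
            "z_s": 10.0,
            "n_levels": 7,
            "trials_per_level": 40,
        }
    if name == "matching-plus-discrimination":
        return {
            "k_motion": 0.9,
            "k_disparity": 0.45,
            "mle_sigmas": {"motion": 1.0, "disparity": 2.0},
            "sigma_M": 1.0,
            "z1": 10.0,
            "n_levels": 7,
            "trials_per_level": 40,
            "n_adjustments": 50,
            "adjustment_noise_frac": 0.05,
        }
    if name == "magnitude-two-distances":
        return {
            "strength_sets": {
                "40cm": {"texture": 0.7, "disparity": 1.2},
                "80cm": {"texture": 0.95, "disparity": 1.0},
            },
            "mle_sigmas": {"texture": 1.0, "disparity": 1.0},
            "sigma_M": 1.0,
            "depth_levels": [1.0, 2.0, 3.0, 4.0, 5.0],
            "trials_per_level": 20,
            "response_noise": 0.3,
        }
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
    )


def _obs_params(observer: ObserverKind, p: dict) -> VecSumParams | MLEParams:
    if observer is ObserverKind.VECSUM:
        return VecSumParams(sigma_M=p.get("sigma_M", 1.0))
    return MLEParams(p["mle_sigmas"])


def _crossed(spec: ScenarioSpec, observer: ObserverKind) -> dict[str, pd.DataFrame]:
    p = spec.parameters
    classes = {cid: CueStrengths(ks) for cid, ks in p["classes"].items()}
    params = _obs_params(observer, p)
    tables = {}
    for sid, s_str in classes.items():
        for cid, c_str in classes.items():
            cond = ConditionSpec(sid, cid, p["z_s"], s_str, c_str)
            pse, jnd = predict_condition(observer, cond, params)
            design = ConstantStimuliDesign(
                condition_id=f"S{sid}_C{cid}",
                standard=Stimulus(p["z_s"], s_str),
                comparison_strengths=c_str,
                levels=default_comparison_levels(pse, jnd, n_levels=p["n_levels"]),
                trials_per_level=p["trials_per_level"],
                seed=spec.seed,
                std_cues_id=sid,
                cmp_cues_id=cid,
            )
            rng = derive_rng(spec.seed, spec.name, design.condition_id)
            tables[design.condition_id] = run_constant_stimuli(
                design, observer, params, rng
            )
    return tables


def _matching(spec: ScenarioSpec, observer: ObserverKind) -> tuple[dict, dict]:
    p = spec.parameters
    motion = CueStrengths({"motion": p["k_motion"]})
    disparity = CueStrengths({"disparity": p["k_disparity"]})
    params = _obs_params(observer, p)
    z1 = p["z1"]
    tables = {}
    for cue_id, strengths in (("motion", motion), ("disparity", disparity)):
        cond = ConditionSpec(cue_id, cue_id, z1, strengths, strengths)
        pse, jnd = predict_condition(observer, cond, params)
        design = ConstantStimuliDesign(
            condition_id=f"disc_{cue_id}",
            standard=Stimulus(z1, strengths),
            comparison_strengths=strengths,
            levels=default_comparison_levels(pse, jnd, n_levels=p["n_levels"]),
            trials_per_level=p["trials_per_level"],
            seed=spec.seed,
            std_cues_id=cue_id,
            cmp_cues_id=cue_id,
        )
        rng = derive_rng(spec.seed, spec.name, design.condition_id)
        tables[design.condition_id] = run_constant_stimuli(design, observer, params, rng)
    rng = derive_rng(spec.seed, spec.name, "matching")
    match = run_matching(
        Stimulus(z1, motion),
        disparity,
        observer,
        params,
        p["n_adjustments"],
        rng,
        adjustment_noise_sd=p["adjustment_noise_frac"] * z1,
    )
    tables["matching"] = pd.DataFrame(
        {
            "condition_id": "matching",
            "z1": match.z1,
            "adjustment": np.arange(1, len(match.adjustments) + 1),
            "z2_setting": match.adjustments,
        }
    )
    return tables, {"z2_mean": match.z2}


def _magnitude(spec: ScenarioSpec, observer: ObserverKind) -> dict[str, pd.DataFrame]:
    p = spec.parameters
    params = _obs_params(observer, p)
    tables = {}
    for dist_label, strengths in p["strength_sets"].items():
        conditions: dict[str, CueStrengths] = {
            cue: CueStrengths({cue: k}) for cue, k in strengths.items()
        }
        conditions["combined"] = CueStrengths(strengths)
        for cond_label, cs in conditions.items():
            cid = f"{dist_label}_{cond_label}"
            rng = derive_rng(spec.seed, spec.name, cid)
            stimuli = [Stimulus(z, cs) for z in p["depth_levels"]]
            tables[cid] = run_magnitude_estimation(
                stimuli,
                observer,
                params,
                p["response_noise"],
                rng,
                trials_per_stimulus=p["trials_per_level"],
                condition_id=cid,
            )
    return tables


_GENERATORS: dict[str, Callable] = {
    "crossed-single-cue": _crossed,
    "crossed-single-vs-combined": _crossed,
    "matching-plus-discrimination": _matching,
    "magnitude-two-distances": _magnitude,
}


def generate_scenario(spec: ScenarioSpec, observer: ObserverKind) -> ScenarioBundle:
    """Generate the full deterministic bundle for a scenario spec."""
    gen = _GENERATORS[spec.name]
    result = gen(spec, observer)
    extras: dict = {}
    if isinstance(result, tuple):
        tables, extras = result
    else:
        tables = result
    config = {
        "scenario": spec.name,
        "observer": observer.value,
        "seed": spec.seed,
        "parameters": spec.parameters,
    }
    return ScenarioBundle(
        spec=spec, observer=observer, tables=tables, config=config, extras=extras
    )
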