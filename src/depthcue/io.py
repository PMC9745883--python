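"""Trial-table and configuration file I/O.

CSV is the single trial-data interchange format (data volumes are tiny);
configurations are JSON or YAML. Readers validate column schemas and name
the offending column or row on failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .tasks import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "read_config", "write_config"]


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks column(s) {missing}")
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    resp = df["resp_cmp_deeper"]
    bad = df.index[~resp.isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"{path}: column 'resp_cmp_deeper' must be binary; first bad row {int(bad[0])}"
        )
    for col in ("z_std", "z_cmp"):
        nonpos = df.index[df[col] <= 0]
        if len(nonpos):
            raise ValueError(
                f"{path}: column {col!r} must be positive; first bad row {int(nonpos[0])}"
            )
    return df


def read_config(path) -> dict:
    """Load a JSON or YAML run configuration."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    p = Path(path)
    if p.suffix.lower() in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        p.write_text(json.dumps(cfg, indent=2, sort_keys=True))
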