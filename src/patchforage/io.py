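"""Trial-table serialization and run configuration.

Trial tables are UTF-8 tab-separated files with a header row, '.' decimal,
one row per trial, and a leading ``# patchforage-trials v1`` schema
comment.  Unknown columns survive a read/write round trip.  External
tables with different column names can be ingested through a column
mapping (a dict or YAML file of ``source_name: canonical_name`` pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from patchforage.task import TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "SCHEMA_VERSION",
    "records_to_frame",
    "write_trials",
    "read_trials",
    "RunConfig",
]

SCHEMA_VERSION = "patchforage-trials v1"

TRIAL_COLUMNS = [
    "trial",
    "cost",
    "mu_cur",
    "mu_alt",
    "val_cur",
    "val_alt",
    "side_cur",
    "patch_choice",
    "switch",
    "pla",
    "m_left",
    "m_right",
    "p_left",
    "p_right",
    "no_brainer",
    "flipped",
    "value_choice",
    "rew_left",
    "rew_right",
    "reward",
    "rt_patch",
    "rt_value",
]


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten simulator records into the canonical trial table."""
    rows = []
    for r in records:
        o = r.options
        rows.append(
            {
                "trial": r.trial_index,
                "cost": r.cost,
                "mu_cur": r.mu_current,
                "mu_alt": r.mu_alternative,
                "val_cur": r.value_current,
                "val_alt": r.value_alternative,
                "side_cur": r.side_current,
                "patch_choice": r.patch_choice,
                "switch": int(r.switch_trial),
                "pla": r.pla,
                "m_left": o.m_left,
                "m_right": o.m_right,
                "p_left": o.p_left,
                "p_right": o.p_right,
                "no_brainer": o.no_brainer if o.no_brainer else "none",
                "flipped": int(o.flipped),
                "value_choice": r.value_choice,
                "rew_left": int(r.rewarded_left),
                "rew_right": int(r.rewarded_right),
                "reward": r.reward_obtained,
                "rt_patch": r.rt_patch,
                "rt_value": r.rt_value,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        trials.to_csv(fh, sep="\t", index=False)


def read_trials(path, column_mapping=None) -> pd.DataFrame:
    """Read a trial table, optionally renaming external columns.

    ``column_mapping`` may be a dict of ``source: canonical`` names or a
    path to a YAML file holding one.  Missing required columns raise a
    ValueError naming them.
    """
    if column_mapping is not None and not isinstance(column_mapping, dict):
        with open(column_mapping, encoding="utf-8") as fh:
            column_mapping = yaml.safe_load(fh)
    df = pd.read_csv(
        path, sep="\t", comment="#", keep_default_na=False, na_values=["nan", ""]
    )
    if column_mapping:
        df = df.rename(columns=column_mapping)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table at {path} missing required columns: {missing}")
    return df


@dataclass
class RunConfig:
    """Full-pipeline configuration; serializable to/from YAML.

    The serialized config together with the seed reproduces every
    deterministic stage bit-for-bit.
    """

    seed: int = 0
    n_participants: int = 29
    n_trials: int = 320
    n_starts: int = 100
    omega_mult: float = 6.62
    gate_alpha: float = 0.05
    replicate_side_bias_bug: bool = True
    planted_effects: list = field(
        default_factory=lambda: [
            {"region": "dACC", "trait": "theta_leave", "r": 0.5},
            {"region": "vmPFC", "trait": "alpha", "r": -0.46},
        ]
    )
    task_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_participants": self.n_participants,
            "n_trials": self.n_trials,
            "n_starts": self.n_starts,
            "omega_mult": self.omega_mult,
            "gate_alpha": self.gate_alpha,
            "replicate_side_bias_bug": self.replicate_side_bias_bug,
            "planted_effects": self.planted_effects,
            "task_params": self.task_params,
        }
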