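"""Reading and writing the package's file formats.

Trial tables are long-format CSV/TSV (comma decimal point, UTF-8), one row
per participant x profile x trial.  Trait and trial indices are 1-based in
files and 0-based in memory.  Every output manifest records the seed and a
hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_TRIAL_COLUMNS = (
    "participant_id",
    "group",
    "profile_id",
    "profile_class",
    "trial_index",
    "trait_id",
    "prediction",
    "feedback",
    "valid",
)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


class TrialTableError(ValueError):
    """Raised for malformed trial files, naming the offending lines."""


def _parse_valid(col: pd.Series) -> pd.Series:
    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise TrialTableError(f"cannot parse valid flag {v!r}")

    return col.map(one)


def read_trials(path: str | Path, scale_min: int = 1, scale_max: int = 8) -> pd.DataFrame:
    """Load and validate a long-format trial table.

    Rejects missing columns, out-of-range ratings, and duplicate
    (participant, profile, trait) rows, reporting 1-based file line numbers
    (header is line 1).  trait_id is converted to the 0-based internal
    convention.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path.name}: missing column(s) {missing}")

    lines = df.index.to_numpy() + 2  # header occupies line 1
    for col in ("prediction", "feedback"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.isna() | (v < scale_min) | (v > scale_max)
        if bad.any():
            where = ", ".join(map(str, lines[bad.to_numpy()][:10]))
            raise TrialTableError(
                f"{path.name}: {col} outside [{scale_min}, {scale_max}] "
                f"on line(s) {where}"
            )
        df[col] = v

    dup = df.duplicated(["participant_id", "profile_id", "trait_id"], keep=False)
    if dup.any():
        where = ", ".join(map(str, lines[dup.to_numpy()][:10]))
        raise TrialTableError(
            f"{path.name}: duplicate (participant, profile, trait) on line(s) {where}"
        )

    df["valid"] = _parse_valid(df["valid"])
    df["trait_id"] = df["trait_id"].astype(int) - 1
    if (df["trait_id"] < 0).any():
        raise TrialTableError(f"{path.name}: trait_id must be >= 1 in files")
    df["trial_index"] = df["trial_index"].astype(int)
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table with the 1-based file conventions."""
    out = trials.copy()
    out["trait_id"] = out["trait_id"].astype(int) + 1
    out["valid"] = out["valid"].astype(bool)
    cols = [c for c in REQUIRED_TRIAL_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    out[cols].to_csv(path, index=False, sep=sep)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(path: str | Path, seed: int, config: dict, extra: dict | None = None) -> None:
    payload = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_reference_ratings(path: str | Path) -> pd.DataFrame:
    """Population reference rating table: rows = people, columns = traits."""
    return pd.read_csv(path)


def read_self_ratings(path: str | Path) -> pd.DataFrame:
    """Participant self-rating table: participant_id column + one column per
    trait (1-based trait ids or labels)."""
    return pd.read_csv(path)
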