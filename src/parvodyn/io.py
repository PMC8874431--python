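"""Tidy experiment-table CSV reading and writing.

One row per observation with columns
``experiment, host, strain, temperature_C, x, y, replicate``.
Semantics of x/y per experiment:

==================== ========================== =========================
experiment            x                          y
==================== ========================== =========================
decay                 zoospore age (h)           infection (%)
functional_response   zoospore:host ratio        infection (%)
growth                time (days)                cells mL^-1
yield                 sporocyte diameter (um)    zoospores released
==================== ========================== =========================
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import TIDY_COLUMNS

KNOWN_EXPERIMENTS = ("decay", "functional_response", "growth", "yield")


def read_experiment_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TIDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: experiment CSV missing columns {sorted(missing)}; "
            f"expected {TIDY_COLUMNS}"
        )
    unknown = set(df["experiment"].unique()) - set(KNOWN_EXPERIMENTS)
    if unknown:
        raise ValueError(f"{path}: unknown experiment kinds {sorted(unknown)}")
    return df[TIDY_COLUMNS + [c for c in df.columns if c not in TIDY_COLUMNS]]


def write_experiment_csv(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(TIDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"experiment table missing columns {sorted(missing)}")
    df.to_csv(path, index=False)
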