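"""Reading and validating wide decision CSVs, and run logging.

The single canonical CSV dialect: columns ``id``, ``country``, the twelve
decision columns named ``{game}_{action}`` with game in A..F and action in
{steal, nosteal}, holding 0, 1 or empty/NA, plus any number of covariate
columns. Validation is strict — no column guessing — and errors name the
offending row and column.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import DECISION_COLUMNS

__all__ = ["read_decisions", "write_decisions", "write_run_log"]

REQUIRED_COLUMNS = ["id", "country", *DECISION_COLUMNS]


class DecisionFileError(ValueError):
    """A decision CSV failed validation."""


def read_decisions(path) -> pd.DataFrame:
    """Read and validate a wide decision CSV.

    Decision values are coerced to float 0/1 with NaN for missing; any
    other value raises :class:`DecisionFileError` naming the CSV row
    (1-based, excluding the header) and column. Duplicate ids are
    rejected.
    """
    data = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise DecisionFileError(f"{path}: missing required column(s): {missing}")
    dup = data["id"][data["id"].duplicated()]
    if not dup.empty:
        raise DecisionFileError(
            f"{path}: duplicate participant id(s): {sorted(map(str, dup.unique()))}"
        )
    for col in DECISION_COLUMNS:
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = coerced.notna() & ~coerced.isin([0, 1])
        unparsed = coerced.isna() & data[col].notna() \
            & ~data[col].astype(str).str.strip().str.upper().isin(["", "NA", "NAN"])
        problems = bad | unparsed
        if problems.any():
            row = int(problems.idxmax()) + 1
            raise DecisionFileError(
                f"{path}: non-binary decision value {data[col][row - 1]!r} "
                f"in column {col!r}, row {row}"
            )
        data[col] = coerced.astype(float)
    return data


def write_decisions(data: pd.DataFrame, path) -> None:
    """Write a decision table in the canonical dialect (missing as empty)."""
    out = data.copy()
    for col in DECISION_COLUMNS:
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    out.to_csv(path, index=False)


def write_run_log(path, *, seed: int, command: str, **settings) -> None:
    """Append a YAML run record (seed, command, settings, versions)."""
    import punishstrat

    record = {
        "command": command,
        "seed": int(seed),
        "settings": {k: _plain(v) for k, v in settings.items()},
        "versions": {
            "punishstrat": punishstrat.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "a") as fh:
        yaml.safe_dump([record], fh, sort_keys=False)


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    return v
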