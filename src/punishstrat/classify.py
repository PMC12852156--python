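"""Model-free analysis of decision data: exact matching, counts, censuses.

The observed data are wide DataFrames with one row per participant: an
``id`` column, a ``country`` column, and the twelve decision columns named
``A_steal`` .. ``F_nosteal`` in canonical order, holding 0 (no punish),
1 (punish) or NaN (missing — e.g. a decision excluded for a failed
per-game comprehension check).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .strategies import PredictionMatrix, decision_labels

__all__ = [
    "DECISION_COLUMNS",
    "classify_exact",
    "classify_dataset",
    "strategy_counts",
    "pattern_census",
    "punish_rates",
]

DECISION_COLUMNS = decision_labels()

NA_LABEL = "NA"


def _decision_array(data: pd.DataFrame) -> np.ndarray:
    missing = [c for c in DECISION_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"missing decision columns: {missing}")
    return data[DECISION_COLUMNS].to_numpy(dtype=float)


def classify_exact(decisions: Sequence[float] | np.ndarray,
                   matrix: PredictionMatrix,
                   partial: bool = False) -> str:
    """Match a 12-decision vector against the prescription matrix.

    Returns the unique strategy whose prescriptions equal the vector, or
    ``"NA"`` if none matches. Vectors containing missing decisions return
    ``"NA"`` by default; with ``partial=True`` the comparison is restricted
    to the observed decisions and a label is returned only when exactly one
    strategy is consistent with them.
    """
    vec = np.asarray(decisions, dtype=float)
    if vec.shape != (matrix.n_decisions,):
        raise ValueError(
            f"decision vector must have length {matrix.n_decisions}, got {vec.shape}"
        )
    observed = ~np.isnan(vec)
    if not observed.all() and not partial:
        return NA_LABEL
    if not observed.any():
        return NA_LABEL
    hits = np.flatnonzero(
        (matrix.values[:, observed] == vec[observed]).all(axis=1)
    )
    if hits.size == 1:
        return matrix.labels[hits[0]]
    return NA_LABEL  # no match, or ambiguous under a partial vector


def classify_dataset(data: pd.DataFrame, matrix: PredictionMatrix,
                     partial: bool = False) -> pd.Series:
    """Per-participant exact-classification labels, indexed like *data*."""
    arr = _decision_array(data)
    labels = [classify_exact(row, matrix, partial=partial) for row in arr]
    return pd.Series(labels, index=data.index, name="strategy")


def strategy_counts(data: pd.DataFrame, matrix: PredictionMatrix,
                    partial: bool = False) -> pd.DataFrame:
    """Counts and proportions of exactly-classified strategies per country.

    Returns a tidy frame with columns ``country``, ``strategy``, ``n``,
    ``prop``; every (country, strategy) combination appears, including the
    ``"NA"`` bucket, and proportions sum to 1 within each country.
    """
    if data.empty:
        raise ValueError("empty dataset")
    labels = classify_dataset(data, matrix, partial=partial)
    order = matrix.labels + [NA_LABEL]
    rows = []
    for country, grp in data.groupby("country", sort=True):
        tally = labels.loc[grp.index].value_counts()
        n_country = len(grp)
        for strat in order:
            n = int(tally.get(strat, 0))
            rows.append(
                {"country": country, "strategy": strat, "n": n,
                 "prop": n / n_country}
            )
    out = pd.DataFrame(rows)
    out["strategy"] = pd.Categorical(out["strategy"], categories=order, ordered=True)
    return out


def pattern_census(data: pd.DataFrame, k: int,
                   matrix: PredictionMatrix | None = None) -> pd.DataFrame:
    """The *k* most common complete 12-decision patterns.

    Participants with any missing decision are excluded. Patterns are ranked
    by descending count with lexicographic tie-breaking on the pattern
    string, and annotated with the exact-matching strategy label where one
    exists in *matrix*.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arr = _decision_array(data)
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete].astype(int)
    if arr.shape[0] == 0:
        raise ValueError("no complete decision vectors")
    patterns = ["".join(map(str, row)) for row in arr]
    counts = pd.Series(patterns).value_counts()
    # stable rank: count desc, then pattern string asc
    census = (
        counts.rename("n")
        .rename_axis("pattern")
        .reset_index()
        .sort_values(["n", "pattern"], ascending=[False, True], kind="mergesort")
        .head(k)
        .reset_index(drop=True)
    )
    census["prop"] = census["n"] / arr.shape[0]
    if matrix is not None:
        lookup = {"".join(map(str, row)): lab
                  for lab, row in zip(matrix.labels, matrix.values)}
        census["strategy"] = [lookup.get(p, "") for p in census["pattern"]]
    return census


def punish_rates(data: pd.DataFrame) -> pd.DataFrame:
    """Raw punish proportion per (country, game, action) context.

    Missing decisions are excluded from both numerator and denominator.
    Returns a tidy frame with columns ``country``, ``decision``, ``game``,
    ``action``, ``n``, ``rate``.
    """
    if data.empty:
        raise ValueError("empty dataset")
    arr = _decision_array(data)
    rows = []
    for country, idx in data.groupby("country", sort=True).indices.items():
        block = arr[idx]
        for j, col in enumerate(DECISION_COLUMNS):
            obs = block[:, j]
            obs = obs[~np.isnan(obs)]
            game, action = col.split("_")
            rows.append(
                {
                    "country": country,
                    "decision": col,
                    "game": game,
                    "action": action,
                    "n": int(obs.size),
                    "rate": float(obs.mean()) if obs.size else np.nan,
                }
            )
    return pd.DataFrame(rows)
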