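"""Punishment motives as predicates, and the strategy × decision matrix.

Each of the nine deterministic motives is a rule mapping a game context
(which game, whether the target stole) to a punish/no-punish prescription.
Evaluating every motive on every one of the twelve decision contexts yields
the prediction matrix used both for exact classification and as the kernel
of the latent mixture model.

Decision index convention (fixed everywhere in this package): decisions are
ordered (A, steal), (A, nosteal), (B, steal), ..., (F, nosteal) — game-major,
steal before no-steal, so j = 0..11 in code.

Motive semantics, in terms of stage-2 payoffs (after the steal choice) and
stage-3 payoffs (with punishment enacted), for the focal player "self" (P1)
and the punished target (P2):

- ``deterrent``: the target stole, intentionally, from self.
- ``norm_enforcing``: the target stole intentionally (victim irrelevant).
- ``revenge``: the target stole from self (intent irrelevant).
- ``avoid_DI``: self is behind the target at stage 2 and punishment brings
  self at least level (equality counts as avoided disadvantage).
- ``egalitarian``: punishment strictly reduces total inequality, measured as
  the sum of pairwise absolute payoff differences over all players.
- ``seek_AI``: self is at most level with the target at stage 2 and strictly
  ahead after punishing (equality counts as no advantage yet).
- ``competitive``: punishment strictly increases self minus target. The
  comparison is always against the punished target P2, including in the
  third-party game.
- ``antisocial``: the target did not steal.
- ``never_punish``: never.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .games import Game, stage2_payoffs, stage3_payoffs, standard_games, GAME_IDS

__all__ = [
    "Motive",
    "PredictionMatrix",
    "STRATEGY_ORDER",
    "RANDOM_CHOICE",
    "THIRD_PARTY",
    "decision_labels",
    "inequality",
    "standard_motives",
    "prescribes",
    "prediction_matrix",
    "third_party_strategy",
    "base_matrix",
    "extended_matrix",
]

#: Canonical strategy order used in tables, fits and reports.
STRATEGY_ORDER = (
    "deterrent",
    "norm_enforcing",
    "revenge",
    "avoid_DI",
    "egalitarian",
    "seek_AI",
    "competitive",
    "antisocial",
    "never_punish",
)

RANDOM_CHOICE = "random_choice"
THIRD_PARTY = "third_party"


def decision_labels(games: Sequence[Game] | None = None) -> list[str]:
    """Column labels ``{game}_{action}`` in the canonical j order."""
    ids = [g.id for g in games] if games is not None else list(GAME_IDS)
    return [f"{gid}_{action}" for gid in ids for action in ("steal", "nosteal")]


@dataclass(frozen=True)
class Motive:
    """A named punishment motive with its prescription rule."""

    name: str
    predicate: Callable[[Game, bool], bool]

    def __call__(self, game: Game, stole: bool) -> bool:
        return self.predicate(game, stole)


def inequality(payoffs: dict[str, int]) -> int:
    """Total inequality: sum of pairwise absolute payoff differences."""
    values = list(payoffs.values())
    if len(values) < 2:
        raise ValueError("inequality needs at least two roles")
    return sum(abs(a - b) for a, b in combinations(values, 2))


def _deterrent(game: Game, stole: bool) -> bool:
    return stole and game.intentional and game.victim_role == "P1"


def _norm_enforcing(game: Game, stole: bool) -> bool:
    return stole and game.intentional


def _revenge(game: Game, stole: bool) -> bool:
    return stole and game.victim_role == "P1"


def _avoid_di(game: Game, stole: bool) -> bool:
    before = stage2_payoffs(game, stole)
    after = stage3_payoffs(game, stole, punished=True)
    return before["P1"] < before["P2"] and after["P1"] >= after["P2"]


def _egalitarian(game: Game, stole: bool) -> bool:
    before = stage2_payoffs(game, stole)
    after = stage3_payoffs(game, stole, punished=True)
    return inequality(after.payoffs) < inequality(before.payoffs)


def _seek_ai(game: Game, stole: bool) -> bool:
    before = stage2_payoffs(game, stole)
    after = stage3_payoffs(game, stole, punished=True)
    return before["P1"] <= before["P2"] and after["P1"] > after["P2"]


def _competitive(game: Game, stole: bool) -> bool:
    before = stage2_payoffs(game, stole)
    after = stage3_payoffs(game, stole, punished=True)
    return (after["P1"] - after["P2"]) > (before["P1"] - before["P2"])


def _antisocial(game: Game, stole: bool) -> bool:
    return not stole


def _never(game: Game, stole: bool) -> bool:
    return False


_PREDICATES: dict[str, Callable[[Game, bool], bool]] = {
    "deterrent": _deterrent,
    "norm_enforcing": _norm_enforcing,
    "revenge": _revenge,
    "avoid_DI": _avoid_di,
    "egalitarian": _egalitarian,
    "seek_AI": _seek_ai,
    "competitive": _competitive,
    "antisocial": _antisocial,
    "never_punish": _never,
}


def standard_motives() -> list[Motive]:
    """The nine deterministic motives, in canonical order."""
    return [Motive(name, _PREDICATES[name]) for name in STRATEGY_ORDER]


def prescribes(motive: Motive | str, game: Game, stole: bool) -> bool:
    """Whether *motive* prescribes punishing in context (*game*, *stole*)."""
    if isinstance(motive, str):
        try:
            motive = Motive(motive, _PREDICATES[motive])
        except KeyError:
            raise ValueError(f"unknown motive {motive!r}") from None
    return bool(motive(game, stole))


class PredictionMatrix:
    """Binary strategy × decision prescription matrix.

    Rows are strategies, columns the twelve decisions in canonical order.
    Rows must be pairwise distinct — two motives collapsing to the same
    pattern would make exact classification ambiguous and signals a
    predicate bug.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray,
                 columns: Sequence[str] | None = None):
        values = np.asarray(values, dtype=int)
        if values.ndim != 2 or len(labels) != values.shape[0]:
            raise ValueError("labels and matrix rows must align")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("prescriptions must be binary")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate strategy labels")
        seen: dict[tuple, str] = {}
        for lab, row in zip(labels, values):
            key = tuple(row)
            if key in seen:
                raise ValueError(
                    f"strategies {seen[key]!r} and {lab!r} prescribe identical "
                    "patterns; predicates are not separable"
                )
            seen[key] = lab
        self.labels = list(labels)
        self.values = values
        self.columns = list(columns) if columns is not None else decision_labels()
        if len(self.columns) != values.shape[1]:
            raise ValueError("column labels and matrix width must align")

    @property
    def n_strategies(self) -> int:
        return len(self.labels)

    @property
    def n_decisions(self) -> int:
        return self.values.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    def with_row(self, label: str, row: np.ndarray) -> "PredictionMatrix":
        """New matrix with an extra strategy row appended."""
        return PredictionMatrix(
            self.labels + [label],
            np.vstack([self.values, np.asarray(row, dtype=int)]),
            self.columns,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.labels, name="strategy"),
                            columns=self.columns)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PredictionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(list(frame.index), frame.to_numpy(), list(frame.columns))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PredictionMatrix)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"PredictionMatrix({self.n_strategies} strategies × {self.n_decisions} decisions)"


def prediction_matrix(motives: Sequence[Motive] | None = None,
                      games: Sequence[Game] | None = None) -> PredictionMatrix:
    """Derive the prescription matrix by evaluating motives on the battery."""
    if motives is None:
        motives = standard_motives()
    if games is None:
        games = standard_games()
    rows = np.array(
        [
            [int(prescribes(m, g, stole)) for g in games for stole in (True, False)]
            for m in motives
        ],
        dtype=int,
    )
    return PredictionMatrix([m.name for m in motives], rows, decision_labels(games))


def third_party_strategy(games: Sequence[Game] | None = None) -> np.ndarray:
    """Prescription row punishing only third-party theft (Game F, steal).

    This pattern emerged as common in the raw data; it is not derivable from
    the nine motives and is appended to the base matrix for the extended
    model variant.
    """
    if games is None:
        games = standard_games()
    row = np.array(
        [
            int(stole and g.victim_role == "P3")
            for g in games
            for stole in (True, False)
        ],
        dtype=int,
    )
    return row


def base_matrix() -> PredictionMatrix:
    """The canonical 9-strategy matrix on the standard battery."""
    return prediction_matrix()


def extended_matrix() -> PredictionMatrix:
    """Base matrix plus the third-party-only strategy (10 deterministic rows)."""
    return base_matrix().with_row(THIRD_PARTY, third_party_strategy())
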