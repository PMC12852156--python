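"""The six costly-punishment games and their payoff arithmetic.

Each game is a three-stage interaction. A target player (P2) either steals a
fixed amount from a victim or does nothing; the focal player (P1) then decides
whether to pay a fee to impose a larger fine on P2 (the fee and fine are
destroyed, not transferred). Games A-E have two players and P1 is the victim
of the theft; Game F adds a third player (P3) who is the victim, making P1 an
uninvolved bystander. Game C is identical to Game B except that the steal
decision is made by the computer, removing intent. Game D sets the fine equal
to the fee (1:1 fee-fine ratio) so punishment cannot change relative payoffs.

All money is in integer pence (£0.70 == 70) so every payoff comparison in the
strategy predicates is exact integer arithmetic. Payoffs are deliberately not
clamped at zero: a fined non-stealing P2 in Game A ends at -20, and that
negative value is what makes the competitive strategy's prescription there
come out of the relative-payoff arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import yaml

__all__ = [
    "Game",
    "PayoffState",
    "GAME_IDS",
    "standard_games",
    "stage2_payoffs",
    "stage3_payoffs",
    "games_to_yaml",
    "games_from_yaml",
]

GAME_IDS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class Game:
    """One punishment game: endowments plus steal/fee/fine parameters.

    Parameters
    ----------
    id : str
        Game label, one of ``A``-``F``.
    endowments : dict[str, int]
        Starting payoff per role in pence, keyed by ``"P1"``, ``"P2"`` and,
        for three-player games, ``"P3"``.
    steal_amount : int
        Pence moved from the victim to P2 if P2 steals (default 20).
    fee : int
        Cost to P1 of punishing, in pence (default 10).
    fine : int
        Amount removed from P2 when punished, in pence.
    intentional : bool
        False when the steal decision is made by the computer (Game C).
    victim_role : str
        Role the steal is taken from: ``"P1"`` for second-party games,
        ``"P3"`` for the third-party game.
    """

    id: str
    endowments: dict[str, int]
    steal_amount: int = 20
    fee: int = 10
    fine: int = 30
    intentional: bool = True
    victim_role: str = "P1"

    def __post_init__(self) -> None:
        if self.fee <= 0 or self.fine <= 0 or self.steal_amount <= 0:
            raise ValueError("fee, fine and steal_amount must be positive")
        if any(v < 0 for v in self.endowments.values()):
            raise ValueError("endowments must be non-negative")
        roles = set(self.endowments)
        if self.victim_role == "P3":
            if roles != {"P1", "P2", "P3"}:
                raise ValueError("a third-party game needs exactly roles P1, P2, P3")
        elif roles != {"P1", "P2"}:
            raise ValueError("a second-party game needs exactly roles P1, P2")

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(sorted(self.endowments))


@dataclass(frozen=True)
class PayoffState:
    """Payoff per role at a given stage of play. Values may be negative."""

    payoffs: dict[str, int]
    stage: str  # "initial" | "post-choice" | "post-punishment"

    def __getitem__(self, role: str) -> int:
        return self.payoffs[role]

    @property
    def total(self) -> int:
        return sum(self.payoffs.values())


def standard_games() -> list[Game]:
    """The six-game battery, in canonical order A..F.

    Game A (advantageous inequity): P1 70, P2 10 — P2 is still worse off
    after stealing. Game B (equal): P2 reaches equality by stealing.
    Game C (computer): as B but the computer decides whether P2 steals.
    Game D (1:1 fee-fine): fine reduced to 10. Game E (disadvantageous
    inequity): P2 is better off after stealing. Game F (third party):
    P2 steals from P3 while P1 looks on with 100.
    """
    return [
        Game("A", {"P1": 70, "P2": 10}),
        Game("B", {"P1": 70, "P2": 30}),
        Game("C", {"P1": 70, "P2": 30}, intentional=False),
        Game("D", {"P1": 70, "P2": 30}, fine=10),
        Game("E", {"P1": 70, "P2": 50}),
        Game("F", {"P1": 100, "P2": 70, "P3": 70}, victim_role="P3"),
    ]


def stage2_payoffs(game: Game, stole: bool) -> PayoffState:
    """Payoffs after P2's steal/no-steal choice.

    Stealing transfers ``steal_amount`` from the victim to P2; the total is
    conserved. With no steal the payoffs equal the endowments.
    """
    payoffs = dict(game.endowments)
    if stole:
        payoffs[game.victim_role] -= game.steal_amount
        payoffs["P2"] += game.steal_amount
    return PayoffState(payoffs, "post-choice")


def stage3_payoffs(game: Game, stole: bool, punished: bool) -> PayoffState:
    """Payoffs after P1's punish decision.

    Punishing removes ``fee`` from P1 and ``fine`` from P2; both amounts are
    destroyed. Payoffs are not clamped at zero.
    """
    state = stage2_payoffs(game, stole)
    payoffs = dict(state.payoffs)
    if punished:
        payoffs["P1"] -= game.fee
        payoffs["P2"] -= game.fine
    return PayoffState(payoffs, "post-punishment")


# -- YAML round-trip so alternative game batteries can be analyzed ----------

def games_to_yaml(games: Iterable[Game]) -> str:
    return yaml.safe_dump(
        {"games": [asdict(g) for g in games]}, sort_keys=False
    )


def games_from_yaml(text: str) -> list[Game]:
    raw = yaml.safe_load(text)
    return [Game(**entry) for entry in raw["games"]]
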