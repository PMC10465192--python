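"""Game-theoretic scaffold: the kill-game and the cooperation condition.

The simplest framing of interference competition is an extreme
Prisoner's Dilemma in which defectors kill their partners.  A defector
facing a cooperator keeps its maximum fitness ``W`` (the temptation);
mutual cooperators survive but pay a competition cost ``C`` (reward
``W - C``); a cooperator facing a defector dies, as do mutual defectors
(payout 0).  With any positive cost, defection weakly dominates.

Extending the game with competitor replacement (initiator effect ``B``)
and kin assortativity (kin-competition multipliers ``A0`` for
cooperators, ``A1`` for defectors) yields the cooperation condition:
de-escalation is favoured when ``A1 * B > A0`` — the combined initiator
and kin-competition burden on defectors exceeds the kin burden on
cooperators.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GameSpec",
    "PayoffMatrix",
    "simple_kill_game",
    "survivable_kill_game",
    "cooperation_condition",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """Row player's payoffs: Prisoner's-Dilemma-style cell labels."""

    reward: float  # both cooperate
    temptation: float  # defect vs cooperator
    sucker: float  # cooperate vs defector
    punishment: float  # both defect

    def is_prisoners_dilemma(self) -> bool:
        """Classic ordering T > R > P > S."""
        return self.temptation > self.reward > self.punishment > self.sucker


@dataclass(frozen=True)
class GameSpec:
    """Parameters of the extended competition game.

    ``A0``/``A1`` multiply the competition felt by cooperators/defectors
    relative to the population mean; positive kin assortativity implies
    ``A1 > 1 > A0`` (clustered defectors kill each other off, clustered
    cooperators spare kin).
    """

    max_fitness: float = 1.0
    competition_cost: float = 0.4
    initiator: float = 0.5
    kin_cooperator: float = 1.0  # A0
    kin_defector: float = 1.0  # A1

    def __post_init__(self) -> None:
        if self.max_fitness < 0:
            raise ValueError("max_fitness must be non-negative")
        if not 0.0 <= self.competition_cost <= self.max_fitness:
            raise ValueError("competition_cost must lie in [0, max_fitness]")
        if not 0.0 <= self.initiator <= 1.0:
            raise ValueError("initiator term must lie in [0, 1]")
        if self.kin_cooperator <= 0 or self.kin_defector <= 0:
            raise ValueError("kin-competition multipliers must be positive")


def simple_kill_game(max_fitness: float, competition_cost: float) -> PayoffMatrix:
    """Kill-game payoffs: defectors kill; survivors pay a competition cost.

    temptation = W (neighbour killed, no competition), reward = W - C,
    sucker = punishment = 0 (death).  For C > 0 defection weakly
    dominates cooperation.
    """
    if max_fitness < 0:
        raise ValueError("max_fitness must be non-negative")
    if not 0.0 <= competition_cost <= max_fitness:
        raise ValueError(
            f"competition_cost={competition_cost!r} outside [0, W={max_fitness!r}]"
        )
    return PayoffMatrix(
        reward=max_fitness - competition_cost,
        temptation=max_fitness,
        sucker=0.0,
        punishment=0.0,
    )


def survivable_kill_game(spec: GameSpec) -> PayoffMatrix:
    """Non-normative variant: mutual defectors survive their duel.

    Reconstructed parameterized builder for the replacement/kin extension
    of the kill-game: mutual defectors survive with payoff
    ``W - C * B * A1`` (their competition is relieved by the initiator
    effect but amplified by defector kin assortativity), and mutual
    cooperators pay ``W - C * A0``.  Only the cooperation condition
    (:func:`cooperation_condition`) is normative; this builder is a
    convenience for exploring payoff orderings.
    """
    w, c = spec.max_fitness, spec.competition_cost
    return PayoffMatrix(
        reward=w - c * spec.kin_cooperator,
        temptation=w,
        sucker=0.0,
        punishment=w - c * spec.initiator * spec.kin_defector,
    )


def cooperation_condition(
    kin_cooperator: float, kin_defector: float, initiator: float
) -> str:
    """Classify the favoured strategy from the balance A1*B vs A0.

    Returns ``"cooperation"`` iff ``A1 * B > A0``, ``"defection"`` iff
    ``A1 * B < A0`` and ``"neutral"`` at exact equality.  Scale-invariant
    in (A0, A1).
    """
    if kin_cooperator <= 0 or kin_defector <= 0:
        raise ValueError("kin-competition terms A0, A1 must be positive")
    if not 0.0 <= initiator <= 1.0:
        raise ValueError("initiator term B must lie in [0, 1]")
    lhs = kin_defector * initiator
    if lhs > kin_cooperator:
        return "cooperation"
    if lhs < kin_cooperator:
        return "defection"
    return "neutral"
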