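"""Single-round rules of the two capital-exchange games.

Game A is a zero-sum pairwise transfer between a subject node ``i`` and one
of its neighbors ``j``: one capital unit moves from a payer to a payee, so
the population total never changes.  Which node pays depends on the
behavioral pattern:

* ``MATTHEW`` — competition where the subject's win probability is its
  population capital rank ("the rich get richer"),
* ``HARMONY`` — the richer of the pair pays the poorer (object pays on ties),
* ``COOPERATION`` — the subject always donates one unit to the object,
* ``PCRC`` — poor-competition-rich-cooperation: a fair coin decides the
  payer when the subject is not richer than the object; otherwise the
  subject donates,
* ``RANDOM`` — a fair coin picks competition (then a second fair coin picks
  the payer) or cooperation (subject donates).

Game B is a single-player two-branch game: branch 1 (win probability
``p1``) applies while the subject's capital is at or below the arithmetic
mean of its neighbors' capitals, branch 2 (win probability ``p2``)
otherwise.  A win adds one unit to the subject, a loss removes one.

These functions are the reference semantics; the simulation engine's
compiled kernel implements the same rules and is cross-checked against
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "BehaviorPattern",
    "Transfer",
    "BranchOutcome",
    "matthew_win_prob",
    "resolve_game_a",
    "select_branch_b",
    "resolve_game_b",
]


class BehaviorPattern(Enum):
    """The five interaction patterns of the pairwise zero-sum game."""

    MATTHEW = "matthew"
    HARMONY = "harmony"
    COOPERATION = "cooperation"
    PCRC = "pcrc"
    RANDOM = "random"


@dataclass(frozen=True)
class Transfer:
    """One capital unit moving from ``payer`` to ``payee`` (zero-sum)."""

    payer: int
    payee: int

    def __post_init__(self):
        if self.payer == self.payee:
            raise ValueError("payer and payee must differ")


@dataclass(frozen=True)
class BranchOutcome:
    """Resolution of one game-B play: which branch and the capital change."""

    branch: int  # 1 or 2
    delta: int  # +1 or -1


def matthew_win_prob(capitals, i: int, initial_capital: int = 0) -> float:
    """Win probability of node ``i`` under the Matthew (rank) rule.

    phi_i = |{k : W_k <= W_i}| / N with fitness W_k = C_k - C_0.  The count
    includes ``i`` itself, so phi is at least 1/N; when all capitals are
    equal phi equals 1.  Since C_0 is common, ranks of W and of C coincide.
    """
    capitals = np.asarray(capitals)
    return float(np.count_nonzero(capitals <= capitals[i])) / len(capitals)


def resolve_game_a(
    capitals, i: int, j: int, pattern: BehaviorPattern, rand: float
) -> Transfer:
    """Resolve one round of the pairwise zero-sum game between ``i`` and ``j``.

    ``rand`` is a uniform [0, 1) variate; patterns that resolve
    deterministically ignore it.  Exactly one unit moves.
    """
    if i == j:
        raise ValueError("subject and object must differ")
    capitals = np.asarray(capitals)
    ci, cj = int(capitals[i]), int(capitals[j])
    if pattern is BehaviorPattern.MATTHEW:
        win = rand < matthew_win_prob(capitals, i)
        return Transfer(payer=j, payee=i) if win else Transfer(payer=i, payee=j)
    if pattern is BehaviorPattern.HARMONY:
        # richer pays poorer; object pays subject on ties
        return Transfer(payer=i, payee=j) if ci > cj else Transfer(payer=j, payee=i)
    if pattern is BehaviorPattern.COOPERATION:
        return Transfer(payer=i, payee=j)
    if pattern is BehaviorPattern.PCRC:
        if ci > cj:
            return Transfer(payer=i, payee=j)
        return Transfer(payer=j, payee=i) if rand < 0.5 else Transfer(payer=i, payee=j)
    if pattern is BehaviorPattern.RANDOM:
        # first fair coin: competitive vs cooperative; the competitive half
        # re-maps its coin onto [0, 0.5) for the payer choice
        if rand < 0.5:
            return (
                Transfer(payer=j, payee=i)
                if rand < 0.25
                else Transfer(payer=i, payee=j)
            )
        return Transfer(payer=i, payee=j)
    raise ValueError(f"unknown pattern {pattern!r}")


def select_branch_b(capitals, neighbors, i: int) -> int:
    """Branch of game B for node ``i``: 1 iff C_i is at or below the mean
    capital of its neighbors, 2 otherwise.

    The comparison is done in exact integer arithmetic
    (C_i * deg <= sum of neighbor capitals).
    """
    neighbors = list(neighbors)
    if not neighbors:
        raise ValueError(f"node {i} has no neighbors")
    capitals = np.asarray(capitals)
    s = int(capitals[neighbors].sum())
    return 1 if int(capitals[i]) * len(neighbors) <= s else 2


def resolve_game_b(
    capitals, neighbors, i: int, p1: float, p2: float, rand: float
) -> BranchOutcome:
    """Resolve one play of game B for node ``i``.

    The subject wins (delta +1) iff ``rand <= p_b`` where ``b`` is the
    branch from :func:`select_branch_b`; otherwise it loses one unit.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("p1 and p2 must lie in [0, 1]")
    branch = select_branch_b(capitals, neighbors, i)
    p = p1 if branch == 1 else p2
    return BranchOutcome(branch=branch, delta=1 if rand <= p else -1)
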