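"""Exact expected-fitness computation for tiny systems.

Enumerates every stochastic choice of the round-by-round process — subject
(1/N each), game A vs B (p, 1-p), object (1/degree), and win/lose with the
pattern- or branch-probability — as an exact dynamic program over capital
states, using rational arithmetic throughout.  Exponential in the horizon,
so guarded to N <= 6 nodes and T <= 6 rounds; serves as the independence
oracle for the Monte-Carlo engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .engine import GameConfig, GameMode
from .games import BehaviorPattern
from .graph import NetworkGraph

__all__ = ["OracleResult", "exact_mean_fitness", "closed_form_uniform"]

MAX_NODES = 6
MAX_ROUNDS = 6


@dataclass(frozen=True)
class OracleResult:
    expected_mean_fitness: float
    branches: int  # number of enumerated outcome transitions
    probability_total: float  # must be 1 (exact rational arithmetic)

    exact: Fraction = Fraction(0)


def _game_a_outcomes(W: tuple, i: int, j: int, pattern: BehaviorPattern):
    """Yield (prob, i_pays) pairs for one game-A resolution."""
    one = Fraction(1)
    if pattern is BehaviorPattern.MATTHEW:
        phi = Fraction(sum(1 for w in W if w <= W[i]), len(W))
        if phi > 0:
            yield phi, False
        if phi < 1:
            yield one - phi, True
    elif pattern is BehaviorPattern.HARMONY:
        yield one, W[i] > W[j]
    elif pattern is BehaviorPattern.COOPERATION:
        yield one, True
    elif pattern is BehaviorPattern.PCRC:
        if W[i] > W[j]:
            yield one, True
        else:
            yield Fraction(1, 2), False
            yield Fraction(1, 2), True
    elif pattern is BehaviorPattern.RANDOM:
        yield Fraction(1, 4), False
        yield Fraction(3, 4), True
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern {pattern!r}")


def exact_mean_fitness(
    graph: NetworkGraph, config: GameConfig, horizon: int
) -> OracleResult:
    """Exact E[(1/N) sum_i W_i(T)] after ``horizon`` rounds."""
    n = graph.n
    if n > MAX_NODES or horizon > MAX_ROUNDS:
        raise ValueError(
            f"instance too large for enumeration (N <= {MAX_NODES}, "
            f"T <= {MAX_ROUNDS})"
        )
    nbrs = [sorted(graph.neighbors(i)) for i in range(n)]
    p_a = Fraction(config.p)
    p1 = Fraction(config.p1)
    p2 = Fraction(config.p2)
    inv_n = Fraction(1, n)

    if config.mode is GameMode.A_ONLY:
        mode_split = [(Fraction(1), True)]
    elif config.mode is GameMode.B_ONLY:
        mode_split = [(Fraction(1), False)]
    else:
        mode_split = [(p_a, True), (1 - p_a, False)]
    mode_split = [(q, is_a) for q, is_a in mode_split if q > 0]

    states: dict[tuple, Fraction] = {tuple([0] * n): Fraction(1)}
    branches = 0
    for _ in range(horizon):
        nxt: dict[tuple, Fraction] = {}
        for W, prob in states.items():
            for i in range(n):
                p_subject = prob * inv_n
                for q_mode, is_a in mode_split:
                    p_mode = p_subject * q_mode
                    if is_a:
                        inv_deg = Fraction(1, len(nbrs[i]))
                        for j in nbrs[i]:
                            for q_out, i_pays in _game_a_outcomes(
                                W, i, j, config.pattern
                            ):
                                W2 = list(W)
                                if i_pays:
                                    W2[i] -= 1
                                    W2[j] += 1
                                else:
                                    W2[i] += 1
                                    W2[j] -= 1
                                key = tuple(W2)
                                nxt[key] = (
                                    nxt.get(key, Fraction(0))
                                    + p_mode * inv_deg * q_out
                                )
                                branches += 1
                    else:
                        deg = len(nbrs[i])
                        s = sum(W[j] for j in nbrs[i])
                        pb = p1 if W[i] * deg <= s else p2
                        for q_out, delta in ((pb, 1), (1 - pb, -1)):
                            if q_out == 0:
                                continue
                            W2 = list(W)
                            W2[i] += delta
                            key = tuple(W2)
                            nxt[key] = nxt.get(key, Fraction(0)) + p_mode * q_out
                            branches += 1
        states = nxt

    total = sum(states.values())
    exact = sum(prob * Fraction(sum(W), n) for W, prob in states.items())
    return OracleResult(
        expected_mean_fitness=float(exact),
        branches=branches,
        probability_total=float(total),
        exact=exact,
    )


def closed_form_uniform(
    q: float, plays_per_individual: int, p: float, mode: GameMode
) -> float:
    """Expected d when both game-B branches share win probability ``q``.

    Game A contributes zero in expectation (zero-sum), so B rounds are a
    binomial walk: E[d] = (B rounds / N) * (2q - 1).
    """
    if mode is GameMode.A_ONLY:
        return 0.0
    if mode is GameMode.B_ONLY:
        return plays_per_individual * (2 * q - 1)
    return (1 - p) * plays_per_individual * (2 * q - 1)
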