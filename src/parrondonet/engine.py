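"""Round-by-round stochastic process driver.

Runs the games in three modes — game A alone, game B alone, or the
randomized mixture that plays A with probability ``p`` on each round — for
``plays_per_individual * n`` rounds (each round draws one subject, so every
individual plays 100 rounds on average at the default setting).

Two implementations share one documented draw order: a compiled kernel
(:mod:`parrondonet._kernels`) used everywhere, and a pure-Python reference
(:func:`run_reference`) used in tests; with equal seeds they produce
bit-identical results because numba's ``np.random`` reproduces NumPy's
legacy ``RandomState`` stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .games import BehaviorPattern, matthew_win_prob
from .graph import NetworkGraph

__all__ = [
    "GameMode",
    "GameConfig",
    "RunResult",
    "ReplicateSet",
    "run",
    "run_reference",
    "run_replicates",
    "mean_fitness_samples",
]


class GameMode(Enum):
    A_ONLY = "a_only"
    B_ONLY = "b_only"
    A_PLUS_B = "a_plus_b"


_MODE_CODE = {
    GameMode.A_ONLY: _kernels.MODE_A_ONLY,
    GameMode.B_ONLY: _kernels.MODE_B_ONLY,
    GameMode.A_PLUS_B: _kernels.MODE_A_PLUS_B,
}
_PATTERN_CODE = {
    BehaviorPattern.MATTHEW: _kernels.PAT_MATTHEW,
    BehaviorPattern.HARMONY: _kernels.PAT_HARMONY,
    BehaviorPattern.COOPERATION: _kernels.PAT_COOPERATION,
    BehaviorPattern.PCRC: _kernels.PAT_PCRC,
    BehaviorPattern.RANDOM: _kernels.PAT_RANDOM,
}


@dataclass(frozen=True)
class GameConfig:
    """Parameters of one simulation run.

    ``p`` is the per-round probability of playing game A in the mixed mode;
    ``p1``/``p2`` are the win probabilities of game B's two branches;
    ``plays_per_individual`` sets the horizon ``T = plays * n`` rounds.
    """

    pattern: BehaviorPattern = BehaviorPattern.MATTHEW
    mode: GameMode = GameMode.A_PLUS_B
    p: float = 0.5
    p1: float = 0.5
    p2: float = 0.5
    plays_per_individual: int = 100
    initial_capital: int = 0

    def __post_init__(self):
        for name in ("p", "p1", "p2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.plays_per_individual < 1:
            raise ValueError("plays_per_individual must be >= 1")


@dataclass(frozen=True)
class RunResult:
    """Outcome of a single run: per-node fitness and branch-play counts."""

    final_fitness: np.ndarray  # W_i(T) = C_i(T) - C_0, int64
    branch1_plays: np.ndarray
    branch2_plays: np.ndarray
    rounds_played: int
    seed: int

    @property
    def mean_fitness(self) -> float:
        """Population mean fitness d = (1/N) sum_i W_i(T)."""
        return float(self.final_fitness.mean())

    @property
    def n(self) -> int:
        return len(self.final_fitness)


def run(graph: NetworkGraph, config: GameConfig, seed: int) -> RunResult:
    """Execute one seeded run on ``graph`` using the compiled kernel."""
    indptr, indices = graph.csr()
    n = graph.n
    rounds = config.plays_per_individual * n
    C, b1, b2 = _kernels.run_kernel(
        indptr,
        indices,
        n,
        rounds,
        _MODE_CODE[config.mode],
        _PATTERN_CODE[config.pattern],
        config.p,
        config.p1,
        config.p2,
        config.initial_capital,
        seed,
    )
    return RunResult(
        final_fitness=C - config.initial_capital,
        branch1_plays=b1,
        branch2_plays=b2,
        rounds_played=rounds,
        seed=seed,
    )


def run_reference(graph: NetworkGraph, config: GameConfig, seed: int) -> RunResult:
    """Pure-Python mirror of the kernel; same draw order, same stream.

    Intended for small instances in tests; optionally records a play trace
    via ``trace`` entries ``(round, node, game, branch_or_payer, delta_i)``.
    """
    rng = np.random.RandomState(seed)
    indptr, indices = graph.csr()
    n = graph.n
    rounds = config.plays_per_individual * n
    C = np.full(n, config.initial_capital, dtype=np.int64)
    b1 = np.zeros(n, dtype=np.int64)
    b2 = np.zeros(n, dtype=np.int64)
    pat = config.pattern
    for _ in range(rounds):
        i = int(rng.random_sample() * n)
        if config.mode is GameMode.A_PLUS_B:
            play_a = rng.random_sample() < config.p
        else:
            play_a = config.mode is GameMode.A_ONLY
        if play_a:
            start, stop = indptr[i], indptr[i + 1]
            deg = stop - start
            j = int(indices[start + int(rng.random_sample() * deg)])
            if pat is BehaviorPattern.MATTHEW:
                i_pays = not (rng.random_sample() < matthew_win_prob(C, i))
            elif pat is BehaviorPattern.HARMONY:
                i_pays = C[i] > C[j]
            elif pat is BehaviorPattern.COOPERATION:
                i_pays = True
            elif pat is BehaviorPattern.PCRC:
                i_pays = True if C[i] > C[j] else not (rng.random_sample() < 0.5)
            else:
                i_pays = not (rng.random_sample() < 0.25)
            if i_pays:
                C[i] -= 1
                C[j] += 1
            else:
                C[i] += 1
                C[j] -= 1
        else:
            start, stop = indptr[i], indptr[i + 1]
            deg = stop - start
            s = int(C[indices[start:stop]].sum())
            branch1 = int(C[i]) * deg <= s
            u = rng.random_sample()
            if branch1:
                b1[i] += 1
                win = u <= config.p1
            else:
                b2[i] += 1
                win = u <= config.p2
            C[i] += 1 if win else -1
    return RunResult(
        final_fitness=C - config.initial_capital,
        branch1_plays=b1,
        branch2_plays=b2,
        rounds_played=rounds,
        seed=seed,
    )


def mean_fitness_samples(
    graph: NetworkGraph,
    config: GameConfig,
    n_reps: int,
    base_seed: int,
    rounds: int | None = None,
) -> np.ndarray:
    """Vector of d over replicates seeded ``base_seed + r``, in one kernel
    call.

    Equivalent to ``[run(graph, config, base_seed + r).mean_fitness ...]``
    but without per-replicate Python overhead; intended for the
    high-replicate comparisons against the exact enumeration oracle, whose
    horizon is a raw round count (hence the ``rounds`` override).
    """
    indptr, indices = graph.csr()
    n = graph.n
    return _kernels.run_many_mean_fitness(
        indptr,
        indices,
        n,
        config.plays_per_individual * n if rounds is None else rounds,
        _MODE_CODE[config.mode],
        _PATTERN_CODE[config.pattern],
        config.p,
        config.p1,
        config.p2,
        config.initial_capital,
        base_seed,
        n_reps,
    )


@dataclass
class ReplicateSet:
    """Seeded replicate runs plus the aggregates derived from them."""

    results: list[RunResult]
    degrees: list[np.ndarray]  # per-replicate node degrees
    base_seed: int

    @property
    def n_reps(self) -> int:
        return len(self.results)

    @property
    def d_values(self) -> np.ndarray:
        return np.array([r.mean_fitness for r in self.results])

    @property
    def d_mean(self) -> float:
        return float(self.d_values.mean())

    @property
    def d_se(self) -> float:
        d = self.d_values
        if len(d) < 2:
            return float("nan")
        return float(d.std(ddof=1) / np.sqrt(len(d)))

    @property
    def branch1_total(self) -> int:
        return int(sum(r.branch1_plays.sum() for r in self.results))

    @property
    def branch2_total(self) -> int:
        return int(sum(r.branch2_plays.sum() for r in self.results))

    @property
    def branch2_fraction(self) -> float:
        """Pooled fraction of game-B plays resolved in branch 2."""
        total = self.branch1_total + self.branch2_total
        if total == 0:
            raise ValueError("no game-B plays recorded")
        return self.branch2_total / total


GraphSource = Callable[[int], NetworkGraph]


def run_replicates(
    graph_source: NetworkGraph | GraphSource,
    config: GameConfig,
    n_reps: int,
    base_seed: int,
) -> ReplicateSet:
    """Run ``n_reps`` seeded replicates.

    Replicate ``r`` uses seed ``base_seed + r``.  ``graph_source`` is either
    a fixed :class:`NetworkGraph` (reused across replicates, e.g. the
    lattice) or a callable ``seed -> NetworkGraph`` drawing a fresh network
    instance per replicate (the random and scale-free families).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results = []
    degrees = []
    for r in range(n_reps):
        seed = base_seed + r
        graph = graph_source(seed) if callable(graph_source) else graph_source
        results.append(run(graph, config, seed))
        degrees.append(graph.degrees)
    return ReplicateSet(results=results, degrees=degrees, base_seed=base_seed)
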