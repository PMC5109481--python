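"""Fitness summaries, paradox classification, and microcosmic diagnostics.

The central classification compares the replicate-mean population fitness
of game B played alone, d^(B), with that of the randomized mixture,
d^(A+B):

* strong paradox — the mixture wins while B alone loses
  (d^(A+B) > 0 > d^(B));
* weak paradox — the mixture merely outperforms B, on the positive side
  (d^(A+B) > d^(B) > 0) or the negative side (0 > d^(A+B) > d^(B));
* otherwise no paradox.  Boundary equalities classify as no paradox.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .engine import ReplicateSet
from .graph import NetworkGraph

__all__ = [
    "ParadoxLabel",
    "population_mean_fitness",
    "classify_paradox",
    "degree_fitness_profile",
    "favorable_branch_fraction",
]


class ParadoxLabel(Enum):
    STRONG = "STRONG"
    WEAK_POSITIVE = "WEAK_POSITIVE"
    WEAK_NEGATIVE = "WEAK_NEGATIVE"
    NONE = "NONE"


def population_mean_fitness(final_fitness) -> float:
    """d = (1/N) sum_i W_i(T)."""
    final_fitness = np.asarray(final_fitness)
    if final_fitness.size == 0:
        raise ValueError("empty population")
    return float(final_fitness.mean())


def classify_paradox(d_B: float, d_AB: float) -> ParadoxLabel:
    """Classify a (d^(B), d^(A+B)) pair; ties on any boundary give NONE."""
    if not (np.isfinite(d_B) and np.isfinite(d_AB)):
        raise ValueError("fitness values must be finite")
    if d_AB > 0 and d_B < 0:
        return ParadoxLabel.STRONG
    if d_AB > d_B > 0:
        return ParadoxLabel.WEAK_POSITIVE
    if 0 > d_AB > d_B:
        return ParadoxLabel.WEAK_NEGATIVE
    return ParadoxLabel.NONE


def degree_fitness_profile(
    replicates: ReplicateSet, graph: NetworkGraph | None = None
) -> pd.DataFrame:
    """Mean final fitness per node degree.

    Fitness is first averaged over replicates node-by-node when all
    replicates share one graph, then over same-degree nodes; with fresh
    networks per replicate, (degree, fitness) pairs are pooled across
    replicates instead.  Returns a frame with columns ``degree``,
    ``node_count``, ``mean_fitness``; ``node_count`` is the per-replicate
    average number of nodes of that degree, so counts sum to N.
    """
    if graph is not None:
        for r in replicates.results:
            if r.n != graph.n:
                raise ValueError("graph and results disagree on node count")
    degs = np.concatenate(replicates.degrees)
    fits = np.concatenate([r.final_fitness for r in replicates.results])
    if len(degs) != len(fits):
        raise ValueError("degrees and fitness vectors are misaligned")
    df = pd.DataFrame({"degree": degs, "fitness": fits})
    out = (
        df.groupby("degree")["fitness"]
        .agg(node_count="size", mean_fitness="mean")
        .reset_index()
    )
    out["node_count"] = out["node_count"] / replicates.n_reps
    return out


def favorable_branch_fraction(
    replicates: ReplicateSet, p1: float, p2: float
) -> float:
    """Fraction of game-B plays resolved in the favorable branch.

    The favorable branch is the one with the larger win probability; the
    fraction pools plays over nodes and replicates.  Undefined when
    ``p1 == p2`` (no branch is favorable) or when no game-B play occurred.
    """
    if p1 == p2:
        raise ValueError("p1 == p2: neither branch is favorable")
    frac2 = replicates.branch2_fraction  # raises on zero game-B plays
    return frac2 if p2 > p1 else 1.0 - frac2
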