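"""Grid sweeps over the game-B branch probabilities (p1, p2).

A sweep runs, for every cell of a regular (p1, p2) grid, paired replicate
sets of game B alone and of the randomized mixture, classifies the cell
(strong / weak / no paradox), and assembles a paradox map — the phase
diagram whose strong-paradox region grows with the heterogeneity of the
network's degree distribution.

Variance-reduction choices: all cells of a sweep share the same replicate
network instances, and each cell's run seeds are derived from the cell's
(p1, p2) values (not its grid position), so a sub-grid sweep reproduces
the corresponding cells of a full sweep bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .engine import GameConfig, GameMode, ReplicateSet, run, RunResult
from .games import BehaviorPattern
from .graph import NetworkGraph
from .metrics import ParadoxLabel, classify_paradox
from .netgen import make_alpha_graph, make_lattice, rewire_to_random

__all__ = [
    "SweepSpec",
    "ParadoxMap",
    "graph_source",
    "sweep",
    "region_fractions",
    "write_map",
    "read_map",
    "plot_map",
]

_FAMILIES = ("lattice", "rewired", "alpha")


@dataclass(frozen=True)
class SweepSpec:
    """Full description of one paradox-map computation."""

    pattern: BehaviorPattern
    family: str = "lattice"  # lattice | rewired | alpha
    side: int = 30  # lattice / rewired
    L: int = 0  # rewired
    alpha: float = 0.0  # alpha family
    n: int = 900  # alpha family
    mean_degree: float = 4.0
    p: float = 0.5
    plays_per_individual: int = 100
    step: float = 0.025
    n_reps: int = 30
    base_seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if not 0.0 < self.step <= 0.5:
            raise ValueError("step must lie in (0, 0.5]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class ParadoxMap:
    """Per-cell results of a sweep: fitness means, standard errors, label."""

    cells: pd.DataFrame  # columns p1, p2, d_B, se_B, d_AB, se_AB, label

    COLUMNS = ("p1", "p2", "d_B", "se_B", "d_AB", "se_AB", "label")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"paradox map missing columns {missing}")
        bad = set(self.cells["label"]) - {l.value for l in ParadoxLabel}
        if bad:
            raise ValueError(f"unknown paradox labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, p1: float, p2: float) -> pd.Series:
        m = np.isclose(self.cells["p1"], p1) & np.isclose(self.cells["p2"], p2)
        if not m.any():
            raise KeyError(f"no cell at ({p1}, {p2})")
        return self.cells[m].iloc[0]


def graph_source(spec: SweepSpec) -> Callable[[int], NetworkGraph]:
    """Seed -> network factory for the requested network family.

    The lattice is deterministic and cached; the rewired and alpha families
    draw a fresh instance per seed.
    """
    if spec.family == "lattice":
        g = make_lattice(spec.side)
        return lambda seed: g
    if spec.family == "rewired":
        base = make_lattice(spec.side)
        return lambda seed: rewire_to_random(base, spec.L, seed=seed)
    return lambda seed: make_alpha_graph(
        spec.alpha, spec.n, spec.mean_degree, seed=seed
    )


def _cell_seed(base_seed: int, p1: float, p2: float) -> int:
    """Deterministic per-cell seed derived from the probability values."""
    a = int(round(p1 * 1000))
    b = int(round(p2 * 1000))
    return (base_seed * 1_000_003 + a * 1009 + b * 9176) % (2**31 - 1)


def _replicate_set(graphs, config, seeds) -> ReplicateSet:
    results = [run(g, config, s) for g, s in zip(graphs, seeds)]
    return ReplicateSet(
        results=results,
        degrees=[g.degrees for g in graphs],
        base_seed=int(seeds[0]),
    )


def run_cell(
    graphs: list[NetworkGraph], spec: SweepSpec, p1: float, p2: float
) -> tuple[ReplicateSet, ReplicateSet]:
    """Paired B-only and A+B replicate sets for one grid cell."""
    cs = _cell_seed(spec.base_seed, p1, p2)
    seeds = [(cs + r) % (2**31 - 1) for r in range(spec.n_reps)]
    common = dict(
        pattern=spec.pattern,
        p=spec.p,
        p1=p1,
        p2=p2,
        plays_per_individual=spec.plays_per_individual,
    )
    rs_b = _replicate_set(graphs, GameConfig(mode=GameMode.B_ONLY, **common), seeds)
    rs_ab = _replicate_set(graphs, GameConfig(mode=GameMode.A_PLUS_B, **common), seeds)
    return rs_b, rs_ab


def sweep(spec: SweepSpec, progress: Callable[[int, int], None] | None = None) -> ParadoxMap:
    """Compute the paradox map over the full (p1, p2) grid."""
    grid = np.round(np.arange(0.0, 1.0 + spec.step / 2, spec.step), 10)
    src = graph_source(spec)
    graphs = [src(spec.base_seed + r) for r in range(spec.n_reps)]
    rows = []
    total = len(grid) ** 2
    done = 0
    for p1 in grid:
        for p2 in grid:
            rs_b, rs_ab = run_cell(graphs, spec, float(p1), float(p2))
            label = classify_paradox(rs_b.d_mean, rs_ab.d_mean)
            rows.append(
                dict(
                    p1=float(p1),
                    p2=float(p2),
                    d_B=rs_b.d_mean,
                    se_B=rs_b.d_se,
                    d_AB=rs_ab.d_mean,
                    se_AB=rs_ab.d_se,
                    label=label.value,
                )
            )
            done += 1
            if progress is not None:
                progress(done, total)
    return ParadoxMap(cells=pd.DataFrame(rows))


def region_fractions(pmap: ParadoxMap) -> dict[str, float]:
    """Fraction of grid cells per paradox label; the four fractions sum to 1."""
    if len(pmap) == 0:
        raise ValueError("empty paradox map")
    counts = pmap.cells["label"].value_counts()
    return {
        lab.value: float(counts.get(lab.value, 0)) / len(pmap) for lab in ParadoxLabel
    }


def write_map(pmap: ParadoxMap, path) -> None:
    """Write the map as CSV with >= 12 significant digits on floats."""
    pmap.cells.to_csv(path, index=False, float_format="%.12g")


def read_map(path) -> ParadoxMap:
    """Read a paradox-map CSV, validating columns and labels."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed paradox-map file {path}: {exc}") from exc
    missing = [c for c in ParadoxMap.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    valid = {l.value for l in ParadoxLabel}
    for idx, lab in enumerate(df["label"]):
        if lab not in valid:
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: line {idx + 2}: unknown label {lab!r}")
    return ParadoxMap(cells=df[list(ParadoxMap.COLUMNS)].copy())


_LABEL_COLORS = {
    "STRONG": "#2ca02c",  # green, as in the phase diagrams
    "WEAK_POSITIVE": "#8c510a",  # brown
    "WEAK_NEGATIVE": "#bf812d",  # lighter brown
    "NONE": "#f7f7f7",
}


def plot_map(pmap: ParadoxMap, path=None, ax=None, title: str | None = None):
    """Render the green/brown paradox map; returns the matplotlib Axes."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    labels = list(_LABEL_COLORS)
    cmap = ListedColormap([_LABEL_COLORS[l] for l in labels])
    pivot = pmap.cells.pivot(index="p2", columns="p1", values="label")
    codes = pivot.apply(lambda col: col.map({l: i for i, l in enumerate(labels)}))
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    ax.pcolormesh(
        pivot.columns.values,
        pivot.index.values,
        codes.values,
        cmap=cmap,
        vmin=-0.5,
        vmax=len(labels) - 0.5,
        shading="nearest",
    )
    ax.set_xlabel("$p_1$ (branch-1 win probability)")
    ax.set_ylabel("$p_2$ (branch-2 win probability)")
    if title:
        ax.set_title(title)
    ax.legend(
        handles=[Patch(color=_LABEL_COLORS[l], label=l) for l in labels],
        loc="upper right",
        fontsize=7,
    )
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
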