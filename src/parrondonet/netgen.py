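"""Network families for the capital-exchange games.

Three families interpolate between homogeneous and heterogeneous degree
distributions:

* a periodic two-dimensional lattice (every degree exactly 4, the
  delta-distribution endpoint),
* random graphs obtained from the lattice by ``L`` degree-randomizing
  rewirings (delta → Poisson as ``L`` grows),
* configuration-model graphs whose degree sequence is an ``alpha``-mixture
  of a truncated Poisson law (``alpha = 1``, random-graph endpoint) and a
  power law (``alpha = 0``, scale-free endpoint), both tuned to a common
  mean degree.

All generated graphs are simple, connected, and have minimum degree 2.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .graph import NetworkGraph

__all__ = [
    "make_lattice",
    "rewire_to_random",
    "sample_degree_sequence",
    "realize_configuration_model",
    "make_alpha_graph",
    "degree_histogram",
]


def make_lattice(side: int) -> NetworkGraph:
    """Periodic ``side`` x ``side`` lattice (torus, von Neumann neighborhood).

    Every node has degree exactly 4 and the graph has ``2 * side**2`` edges.
    ``side`` must be at least 3; smaller tori wrap onto parallel edges.
    """
    if side < 3:
        raise ValueError(f"side must be >= 3, got {side}")
    g = nx.grid_2d_graph(side, side, periodic=True)
    g = nx.relabel_nodes(g, {(x, y): x * side + y for x, y in g.nodes})
    return NetworkGraph(g)


def rewire_to_random(graph: NetworkGraph, L: int, seed=None) -> NetworkGraph:
    """Apply exactly ``L`` accepted random rewirings to ``graph``.

    Each rewiring picks a uniform random edge, keeps one uniformly chosen
    endpoint, and reconnects the free end to a uniform random node.
    Proposals that would create a self-loop, a parallel edge, a degree-0
    node, or disconnect the graph are rejected and redrawn; rejections do
    not count toward ``L``.  Edge count is conserved.
    """
    if L < 0:
        raise ValueError(f"L must be >= 0, got {L}")
    rng = np.random.default_rng(seed)
    g = graph.nx_graph.copy()
    edges = [tuple(sorted(e)) for e in g.edges]
    n = g.number_of_nodes()
    accepted = 0
    proposals = 0
    max_proposals = 1000 * (L + 1) + 10_000
    while accepted < L:
        proposals += 1
        if proposals > max_proposals:
            raise RuntimeError(
                f"rewiring stalled after {proposals} proposals "
                f"({accepted}/{L} accepted)"
            )
        idx = int(rng.integers(len(edges)))
        u, v = edges[idx]
        keep, free = (u, v) if rng.random() < 0.5 else (v, u)
        target = int(rng.integers(n))
        if target == keep or g.has_edge(keep, target):
            continue
        if g.degree(free) == 1:
            continue  # would isolate the freed endpoint
        g.remove_edge(u, v)
        g.add_edge(keep, target)
        if not nx.is_connected(g):
            g.remove_edge(keep, target)
            g.add_edge(u, v)
            continue
        edges[idx] = tuple(sorted((keep, target)))
        accepted += 1
    return NetworkGraph(g)


def _truncated_poisson_rate(mean_degree: float, k_min: int = 2) -> float:
    """Rate lambda such that a Poisson truncated to ``k >= k_min`` has the
    requested mean."""

    def trunc_mean(lam: float) -> float:
        # E[K | K >= 2] = (lam - lam * e^-lam) / (1 - e^-lam - lam e^-lam)
        e = np.exp(-lam)
        num = lam - lam * e
        den = 1.0 - e - lam * e
        return num / den

    return brentq(lambda lam: trunc_mean(lam) - mean_degree, 1e-6, 4 * mean_degree)


def _power_law_pmf(gamma: float, k_max: int, k_min: int = 2, cutoff: float = np.inf):
    ks = np.arange(k_min, k_max + 1, dtype=np.float64)
    with np.errstate(over="ignore"):
        w = ks ** (-gamma) * np.exp(-ks / cutoff)
    return ks.astype(np.int64), w / w.sum()


def _power_law_gamma(
    mean_degree: float, k_max: int, k_min: int = 2, cutoff: float = np.inf
) -> float:
    """Exponent gamma such that the (possibly cutoff) power law on
    [k_min, k_max] has the requested mean, found by bisection."""

    def mean_of(gamma: float) -> float:
        ks, p = _power_law_pmf(gamma, k_max, k_min, cutoff)
        return float((ks * p).sum())

    # gamma may go negative under a strong cutoff (the cutoff then carries
    # the decay and the power term must lift the mean)
    lo, hi = -30.0, 8.0
    if not (mean_of(hi) <= mean_degree <= mean_of(lo)):
        raise ValueError(
            f"mean degree {mean_degree} not attainable on [{k_min}, {k_max}]"
        )
    return brentq(lambda g: mean_of(g) - mean_degree, lo, hi, xtol=1e-10)


# Small-degree mass of the reference scale-free construction: nodes of degree
# 2 or 3 make up 70% of the network at mean degree 4.  The exponential-cutoff
# scale kappa is the second shape parameter that lets the heavy-tail
# component match this mass in addition to the mean.
SMALL_DEGREE_MASS = 0.70


def _power_law_params(
    mean_degree: float,
    k_max: int,
    k_min: int = 2,
    small_mass: float | None = SMALL_DEGREE_MASS,
) -> tuple[float, float]:
    """Exponent and cutoff of the heavy-tail degree law.

    With ``small_mass`` set, solves (gamma, kappa) jointly so that the mean
    equals ``mean_degree`` and P(k in {k_min, k_min+1}) equals ``small_mass``.
    With ``small_mass=None`` falls back to a pure power law (kappa = inf)
    tuned to the mean only.
    """
    if small_mass is None:
        return _power_law_gamma(mean_degree, k_max, k_min), np.inf

    def mass_residual(log_kappa: float) -> float:
        kappa = float(np.exp(log_kappa))
        gamma = _power_law_gamma(mean_degree, k_max, k_min, cutoff=kappa)
        _, p = _power_law_pmf(gamma, k_max, k_min, cutoff=kappa)
        return float(p[:2].sum()) - small_mass

    lo, hi = np.log(2.0), np.log(1e6)
    if mass_residual(lo) * mass_residual(hi) > 0:
        # requested mass unattainable with a cutoff; pure power law
        return _power_law_gamma(mean_degree, k_max, k_min), np.inf
    log_kappa = brentq(mass_residual, lo, hi, xtol=1e-8)
    kappa = float(np.exp(log_kappa))
    return _power_law_gamma(mean_degree, k_max, k_min, cutoff=kappa), kappa


def sample_degree_sequence(
    alpha: float, n: int, mean_degree: float, seed=None
) -> np.ndarray:
    """Draw a degree sequence from the ``alpha``-mixture model.

    Each node's degree comes, independently, from a truncated Poisson law
    (probability ``alpha``) or from a power law with exponential cutoff,
    ``P(k) ~ k^-gamma * exp(-k/kappa)`` on ``[2, n-1]`` (probability
    ``1 - alpha``).  Both components are tuned so their mean equals
    ``mean_degree``; the heavy-tail component additionally places
    probability mass ``SMALL_DEGREE_MASS`` on degrees {2, 3}, matching the
    small-degree weight of the reference scale-free construction.  If the
    resulting sum is odd, one uniformly chosen node's degree is incremented
    to make the sequence graphical-parity valid.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    if mean_degree < 2:
        raise ValueError(f"mean_degree must be >= 2, got {mean_degree}")
    rng = np.random.default_rng(seed)
    degrees = np.empty(n, dtype=np.int64)

    from_poisson = rng.random(n) < alpha
    n_pois = int(from_poisson.sum())
    if n_pois:
        lam = _truncated_poisson_rate(mean_degree)
        draws = np.empty(n_pois, dtype=np.int64)
        filled = 0
        while filled < n_pois:
            batch = rng.poisson(lam, size=2 * (n_pois - filled) + 16)
            batch = batch[(batch >= 2) & (batch <= n - 1)]
            take = min(len(batch), n_pois - filled)
            draws[filled : filled + take] = batch[:take]
            filled += take
        degrees[from_poisson] = draws
    n_pl = n - n_pois
    if n_pl:
        gamma, kappa = _power_law_params(mean_degree, k_max=n - 1)
        ks, p = _power_law_pmf(gamma, k_max=n - 1, cutoff=kappa)
        degrees[~from_poisson] = rng.choice(ks, size=n_pl, p=p)

    if degrees.sum() % 2 == 1:
        degrees[rng.integers(n)] += 1
    return degrees


def realize_configuration_model(degseq, seed=None) -> NetworkGraph:
    """Realize a simple connected graph with the given degree sequence.

    Starts from a half-edge matching (configuration model), then removes
    self-loops and parallel edges by degree-preserving double-edge swaps,
    and finally joins connected components by swaps between components.
    All repairs preserve the degree sequence exactly.
    """
    degseq = np.asarray(degseq, dtype=np.int64)
    if degseq.sum() % 2 == 1:
        raise ValueError("degree sequence sum must be even")
    if (degseq < 1).any():
        raise ValueError("all degrees must be >= 1")
    n = len(degseq)
    rng = np.random.default_rng(seed)

    # half-edge matching
    stubs = np.repeat(np.arange(n, dtype=np.int64), degseq)
    rng.shuffle(stubs)
    edges = [(int(stubs[2 * i]), int(stubs[2 * i + 1])) for i in range(len(stubs) // 2)]

    multiplicity: Counter = Counter()
    for u, v in edges:
        if u != v:
            multiplicity[frozenset((u, v))] += 1

    def is_bad(e) -> bool:
        u, v = e
        return u == v or multiplicity[frozenset((u, v))] > 1

    max_attempts = 10 * n + 10_000
    attempts = 0
    bad = [i for i, e in enumerate(edges) if is_bad(e)]
    while bad:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"degree sequence not realizable as a simple graph after "
                f"{attempts} repair attempts"
            )
        i = bad[-1]
        if not is_bad(edges[i]):
            bad.pop()
            continue
        j = int(rng.integers(len(edges)))
        if j == i:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u,v),(x,y) -> (u,x),(v,y)
        if u == x or v == y:
            continue
        if multiplicity[frozenset((u, x))] > 0 or multiplicity[frozenset((v, y))] > 0:
            continue
        for a, b in (edges[i], edges[j]):
            if a != b:
                multiplicity[frozenset((a, b))] -= 1
        edges[i] = (u, x)
        edges[j] = (v, y)
        multiplicity[frozenset((u, x))] += 1
        multiplicity[frozenset((v, y))] += 1
        if is_bad(edges[j]):
            bad.append(j)
        if not is_bad(edges[i]):
            bad.pop()

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)

    # join components by degree-preserving swaps; endpoints lie in different
    # components so no parallel edge can arise
    attempts = 0
    while not nx.is_connected(g):
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("failed to connect configuration-model graph")
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        main, other = comps[0], comps[1]
        a, b = _random_edge_in(g, main, rng)
        c, d = _random_edge_in(g, other, rng)
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, c)
        g.add_edge(b, d)

    out = NetworkGraph(g)
    if not np.array_equal(out.degrees, degseq):
        raise RuntimeError("repairs failed to preserve the degree sequence")
    return out


def _random_edge_in(g: nx.Graph, comp: set, rng) -> tuple[int, int]:
    nodes = sorted(comp)
    while True:
        u = nodes[int(rng.integers(len(nodes)))]
        nbrs = sorted(g.neighbors(u))
        if nbrs:
            return u, nbrs[int(rng.integers(len(nbrs)))]


def make_alpha_graph(
    alpha: float, n: int, mean_degree: float = 4.0, seed=None
) -> NetworkGraph:
    """Sample a degree sequence at heterogeneity ``alpha`` and realize it."""
    rng = np.random.default_rng(seed)
    degseq = sample_degree_sequence(alpha, n, mean_degree, seed=rng)
    return realize_configuration_model(degseq, seed=rng)


def degree_histogram(graph: NetworkGraph) -> dict[int, int]:
    """Mapping ``degree -> node count``; counts sum to ``n``."""
    return dict(sorted(Counter(int(d) for d in graph.degrees).items()))
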