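"""MCODE-style dense-complex detection.

The algorithm finds locally dense regions ("complexes") of an interaction
network in three stages:

1. **Vertex weighting.**  For each node v, take the closed neighborhood
   N[v], find its highest k-core (the maximal subgraph of minimum degree k
   for the largest feasible k), and set
   ``weight(v) = k * density(highest k-core)``.  Nodes with degree below
   ``degree_cutoff`` get weight 0.  This rewards nodes sitting inside
   cliquish neighborhoods while damping the star-like neighborhoods of mere
   high-degree nodes.
2. **Complex prediction.**  Nodes are visited in decreasing weight order;
   each unseen node seeds a complex that grows outward, including a
   neighbor w while ``weight(w) >= seed_weight * (1 - node_score_cutoff)``
   and the BFS depth stays within ``max_depth``.  Every node joins at most
   one complex.
3. **Post-processing.**  *Haircut* iteratively removes members with fewer
   than 2 in-complex edges; complexes whose subgraph has no k-core of order
   ``k_core`` are discarded; optional *fluff* adds unassigned boundary
   nodes whose neighborhood density exceeds ``fluff_density_cutoff``.

A complex is scored density * size and the list is returned in decreasing
score order (ties: larger size, then lexicographically smaller seed).  All
ties anywhere are broken lexicographically, so output is deterministic.
Edges are treated as unweighted; parameter defaults follow the Cytoscape
MCODE app.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["McodeParams", "Complex", "vertex_weights", "find_complexes", "seed_of"]


@dataclass(frozen=True)
class McodeParams:
    """Tuning knobs, defaulting to the Cytoscape MCODE app's defaults."""

    include_loops: bool = False
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.node_score_cutoff < 1:
            raise ValueError("node_score_cutoff must be in [0, 1)")
        if self.degree_cutoff < 0 or self.k_core < 1 or self.max_depth < 0:
            raise ValueError("invalid MCODE parameters")


@dataclass(frozen=True)
class Complex:
    """One detected complex: seed, members, density * size score, rank."""

    seed: str
    members: frozenset[str]
    score: float
    density: float
    rank: int = 0

    def __len__(self) -> int:
        return len(self.members)


def _density(sub: nx.Graph) -> float:
    n = sub.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * sub.number_of_edges() / (n * (n - 1))


def _highest_k_core(sub: nx.Graph) -> tuple[int, nx.Graph]:
    """The k-core of ``sub`` for the largest k with a nonempty core."""
    cores = nx.core_number(sub)
    k = max(cores.values())
    keep = [v for v, c in cores.items() if c >= k]
    return k, sub.subgraph(keep)


def vertex_weights(net: nx.Graph, params: McodeParams | None = None) -> dict[str, float]:
    """Core-clustering weight of every node (0 below the degree cutoff)."""
    params = params or McodeParams()
    weights: dict[str, float] = {}
    for v in net:
        if net.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = net.subgraph([v, *net.neighbors(v)])
        k, core = _highest_k_core(closed)
        weights[v] = float(k) * _density(core)
    return weights


def _grow_complex(net: nx.Graph, weights: dict[str, float], seed: str,
                  assigned: set[str], params: McodeParams) -> set[str]:
    """Greedy BFS expansion from one seed under the weight threshold."""
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        nxt = []
        for v in sorted(frontier):
            for w in sorted(net.neighbors(v)):
                if w in members or w in assigned:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    nxt.append(w)
        frontier = nxt
        depth += 1
    return members


def _haircut(sub: nx.Graph) -> set[str]:
    """Iteratively strip members with fewer than 2 in-complex edges."""
    sub = sub.copy()
    while True:
        shave = [v for v in sub if sub.degree(v) < 2]
        if not shave or len(shave) == sub.number_of_nodes():
            if shave:
                return set()
            return set(sub.nodes)
        sub.remove_nodes_from(shave)


def _fluff(net: nx.Graph, members: set[str], assigned: set[str],
           params: McodeParams) -> set[str]:
    """Add unassigned boundary nodes with dense-enough neighborhoods."""
    extra: set[str] = set()
    for v in sorted(members):
        for w in sorted(net.neighbors(v)):
            if w in members or w in extra or w in assigned:
                continue
            closed = net.subgraph([w, *net.neighbors(w)])
            if _density(closed) > params.fluff_density_cutoff:
                extra.add(w)
    return members | extra


def find_complexes(net: nx.Graph, params: McodeParams | None = None) -> list[Complex]:
    """Detect complexes: weight, grow from heaviest seeds, post-process, rank."""
    params = params or McodeParams()
    weights = vertex_weights(net, params)
    order = sorted(net.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        members = _grow_complex(net, weights, seed, assigned, params)
        assigned |= members  # consumed even if post-processing discards them
        if params.haircut:
            members = _haircut(net.subgraph(members))
        if not members:
            continue
        sub = net.subgraph(members)
        if max(nx.core_number(sub).values(), default=0) < params.k_core:
            continue
        if params.fluff:
            members = _fluff(net, set(members), assigned, params)
            assigned |= members
            sub = net.subgraph(members)
        density = _density(sub)
        complexes.append(Complex(
            seed=seed if seed in members else min(members),
            members=frozenset(members),
            score=density * sub.number_of_nodes(),
            density=density,
        ))
    complexes.sort(key=lambda c: (-c.score, -len(c.members), c.seed))
    return [Complex(seed=c.seed, members=c.members, score=c.score,
                    density=c.density, rank=i)
            for i, c in enumerate(complexes, start=1)]


def seed_of(c: Complex) -> str:
    """The node the complex was grown from (its reported representative)."""
    if not c.members:
        raise ValueError("empty complex")
    return c.seed
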