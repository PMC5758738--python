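"""Component decomposition, seed expansion, and degree statistics.

Biological interaction networks are typically dominated by one large
connected component; the analysis substrate is that *main component*.  Their
degree distributions are heavy-tailed, conventionally summarised by a
power-law fit count(k) = a * k**b on the log-log degree/count points (the
display convention of Cytoscape's NetworkAnalyzer), whose R-squared close to
1 is read as evidence of scale-free structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .gene_lists import GeneSet

__all__ = [
    "ComponentPartition",
    "DegreeDistribution",
    "PowerLawFit",
    "connected_components",
    "main_component",
    "expand",
    "degree_distribution",
    "fit_power_law",
]


@dataclass(frozen=True)
class ComponentPartition:
    """Connected components ordered by decreasing size.

    Ties in node count are broken by the lexicographically smallest member
    symbol, so the ordering is deterministic.
    """

    components: tuple[frozenset[str], ...]
    sizes: tuple[tuple[int, int], ...]  # (n_nodes, n_edges) per component


@dataclass(frozen=True)
class DegreeDistribution:
    """Counts of nodes per degree k >= 1; zero-degree nodes counted apart."""

    points: dict[int, int]
    n_isolated: int = 0

    @property
    def n_nodes(self) -> int:
        return sum(self.points.values()) + self.n_isolated

    @property
    def n_edges(self) -> int:
        return sum(k * c for k, c in self.points.items()) // 2


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit count(k) = a * k**b on log10-transformed points."""

    a: float
    b: float
    r_squared: float
    correlation: float
    points: tuple[tuple[int, int], ...] = field(default=(), repr=False)


def _component_key(net: nx.Graph, comp: frozenset[str]):
    return (-len(comp), min(comp))


def connected_components(net: nx.Graph) -> ComponentPartition:
    """Partition the node set into connected components (largest first)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted((frozenset(c) for c in nx.connected_components(net)),
                   key=lambda c: _component_key(net, c))
    sizes = tuple((len(c), net.subgraph(c).number_of_edges()) for c in comps)
    return ComponentPartition(components=tuple(comps), sizes=sizes)


def main_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component (a copy)."""
    part = connected_components(net)
    return net.subgraph(part.components[0]).copy()


def expand(net: nx.Graph, seeds: GeneSet, depth: int = 1) -> nx.Graph:
    """Induced subgraph on nodes within graph distance ``depth`` of any seed.

    Seeds absent from the network are tolerated (and reported via the
    returned graph's ``absent_seeds`` attribute); if *no* seed is present a
    ``ValueError`` is raised.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    present = sorted(s for s in seeds.members if s in net)
    absent = sorted(s for s in seeds.members if s not in net)
    if not present:
        raise ValueError("no seed present in network")
    keep: set[str] = set(present)
    frontier = set(present)
    for _ in range(depth):
        frontier = {w for v in frontier for w in net.neighbors(v)} - keep
        if not frontier:
            break
        keep |= frontier
    sub = net.subgraph(keep).copy()
    sub.graph["absent_seeds"] = absent
    return sub


def degree_distribution(net: nx.Graph) -> DegreeDistribution:
    """Histogram of node degrees; asserts the handshake lemma."""
    points: dict[int, int] = {}
    n_isolated = 0
    for _, k in net.degree():
        if k == 0:
            n_isolated += 1
        else:
            points[k] = points.get(k, 0) + 1
    points = dict(sorted(points.items()))
    assert sum(k * c for k, c in points.items()) == 2 * net.number_of_edges()
    return DegreeDistribution(points=points, n_isolated=n_isolated)


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Fit count(k) = a * k**b by least squares on (log10 k, log10 count).

    Requires at least 3 distinct degrees with positive counts.  Reports the
    coefficient ``a = 10**intercept``, the exponent ``b`` (the slope;
    negative for heavy-tailed data), the R-squared of the log-log fit, and
    the Pearson correlation between observed and fitted counts on the
    original scale — the pair of statistics NetworkAnalyzer prints under its
    degree-distribution panel.
    """
    pts = [(k, c) for k, c in sorted(dist.points.items()) if c > 0]
    if len(pts) < 3:
        raise ValueError("insufficient support for fit: need >=3 distinct degrees")
    logk = np.log10([k for k, _ in pts])
    logc = np.log10([c for _, c in pts])
    res = stats.linregress(logk, logc)
    a = float(10.0 ** res.intercept)
    b = float(res.slope)
    counts = np.array([c for _, c in pts], dtype=float)
    fitted = a * np.array([k for k, _ in pts], dtype=float) ** b
    if np.allclose(counts, fitted):
        corr = 1.0  # degenerate pearsonr when residuals vanish
    else:
        corr = float(stats.pearsonr(counts, fitted)[0])
    return PowerLawFit(a=a, b=b, r_squared=float(res.rvalue**2),
                       correlation=corr, points=tuple(pts))
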