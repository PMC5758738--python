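"""Independent brute-force oracles used only by the tests.

Each oracle computes its quantity by a different route than the package
(path enumeration, subset enumeration, combinatorial sums), so agreement is
a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import networkx as nx


def bfs_distances(net: nx.Graph, source):
    """Plain hand-rolled BFS distances (oracle for closeness)."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in net.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def brute_betweenness_and_stress(net: nx.Graph):
    """Enumerate every shortest path of every unordered pair.

    Betweenness of v: the fraction of each pair's shortest paths with v
    interior, summed over pairs.  Stress of v: the integer count of those
    paths.  Exponential; only for small graphs.
    """
    nodes = sorted(net.nodes)
    betw = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(net, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                betw[v] += 1.0 / len(paths)
                stress[v] += 1
    return betw, stress


def tree_betweenness(tree: nx.Graph):
    """Closed form on a tree: removing v splits it into branches of sizes
    c1..ck; v separates (and hence mediates the unique path of) exactly
    sum_{i<j} ci*cj unordered pairs."""
    out = {}
    for v in tree.nodes:
        rest = tree.subgraph(n for n in tree.nodes if n != v)
        sizes = [len(c) for c in nx.connected_components(rest)]
        out[v] = float(sum(a * b for a, b in itertools.combinations(sizes, 2)))
    return out


def brute_mcode_weight(net: nx.Graph, v, degree_cutoff: int = 2) -> float:
    """MCODE vertex weight by subset enumeration over the closed neighborhood.

    The highest k equals the maximum over nonempty subsets of the minimum
    induced degree; the highest k-core is the union of all subsets reaching
    that minimum degree (induced degrees only grow under union).
    """
    if net.degree(v) < degree_cutoff:
        return 0.0
    closed = sorted([v, *net.neighbors(v)])
    sub = net.subgraph(closed)
    best_k = 0
    for r in range(1, len(closed) + 1):
        for subset in itertools.combinations(closed, r):
            s = sub.subgraph(subset)
            mindeg = min((s.degree(u) for u in subset), default=0)
            best_k = max(best_k, mindeg)
    core_nodes: set = set()
    for r in range(1, len(closed) + 1):
        for subset in itertools.combinations(closed, r):
            s = sub.subgraph(subset)
            if min((s.degree(u) for u in subset), default=0) >= best_k:
                core_nodes |= set(subset)
    core = sub.subgraph(core_nodes)
    n = core.number_of_nodes()
    density = 0.0 if n < 2 else 2.0 * core.number_of_edges() / (n * (n - 1))
    return best_k * density


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by the exact combinatorial sum with integer arithmetic."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total
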