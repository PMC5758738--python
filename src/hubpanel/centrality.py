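"""The four node centralities used to rank interaction-network genes.

* **degree** — raw neighbor count (unnormalized: the hub cutoff
  mean + 2 SD operates on raw degrees).
* **betweenness** — Brandes' exact algorithm; for each unordered pair
  (s, t) with s != v != t, the fraction of shortest s-t paths through v,
  summed over pairs.  Unnormalized by default (top-fraction selection is
  normalization-invariant); optional division by (n-1)(n-2)/2.
* **stress** — like betweenness but counting whole shortest paths through v
  (an integer), not fractions.  Each unordered pair's paths are counted
  once; tools differ by a factor of 2 on this convention.
* **closeness** — (n-1) / sum of shortest-path distances to all other
  nodes, in (0, 1] on a connected graph.

All four are topological: edge scores are ignored, shortest paths are BFS
paths.  Betweenness and stress require a connected graph (compute on the
main component); endpoints never count as mediating their own pairs.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import pandas as pd

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "stress_centrality",
    "closeness_centrality",
    "betweenness_and_stress",
    "centrality_table",
]


def _require_connected(net: nx.Graph) -> None:
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        raise ValueError(
            "network is disconnected; extract the main component first "
            "(hubpanel.graph_core.main_component)"
        )


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw degree of every node."""
    return {v: int(k) for v, k in net.degree()}


def betweenness_and_stress(net: nx.Graph) -> tuple[dict[str, float], dict[str, int]]:
    """One Brandes sweep computing betweenness and stress together.

    For each source s, a BFS builds the shortest-path DAG with path counts
    sigma.  Backward accumulation then yields, per node v, the pair
    dependency delta (fractional, for betweenness) and the count g of
    shortest paths from v to all DAG descendants (for stress, weighted by
    sigma[v]).  Summing over ordered sources counts each unordered pair
    twice, so both totals are halved.
    """
    _require_connected(net)
    betw = {v: 0.0 for v in net}
    stress = {v: 0 for v in net}
    for s in net:
        # forward phase: BFS shortest-path DAG from s
        pred: dict[str, list[str]] = {v: [] for v in net}
        sigma = {v: 0 for v in net}
        dist = {v: -1 for v in net}
        sigma[s] = 1
        dist[s] = 0
        order: list[str] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in net.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # backward phase: accumulate dependencies
        delta = {v: 0.0 for v in net}  # Brandes pair dependency
        g = {v: 0 for v in net}  # shortest paths from v into its DAG subtree
        for w in reversed(order):
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
                g[v] += 1 + g[w]
            if w != s:
                betw[w] += delta[w]
                stress[w] += sigma[w] * g[w]
    # ordered sources count each unordered pair twice
    for v in net:
        betw[v] /= 2.0
        stress[v] //= 2
    return betw, stress


def betweenness_centrality(net: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Brandes betweenness over unordered pairs; optionally normalized."""
    betw, _ = betweenness_and_stress(net)
    if normalized:
        n = net.number_of_nodes()
        scale = (n - 1) * (n - 2) / 2.0
        if scale > 0:
            betw = {v: b / scale for v, b in betw.items()}
    return betw


def stress_centrality(net: nx.Graph) -> dict[str, int]:
    """Integer count of shortest paths (between unordered pairs) through each node."""
    _, stress = betweenness_and_stress(net)
    return stress


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """Normalized closeness (n-1)/sum of BFS distances, per node."""
    _require_connected(net)
    n = net.number_of_nodes()
    if n == 1:
        return {next(iter(net)): 0.0}
    out = {}
    for v in net:
        total = sum(nx.single_source_shortest_path_length(net, v).values())
        out[v] = (n - 1) / total
    return out


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """All four centralities as one DataFrame indexed by node symbol.

    Columns: degree, betweenness (unnormalized), closeness, stress.  Rows
    sorted by degree descending, then symbol — the input contract for hub
    and bottleneck selection.
    """
    _require_connected(net)
    betw, stress = betweenness_and_stress(net)
    close = closeness_centrality(net)
    deg = degree_centrality(net)
    table = pd.DataFrame(
        {
            "degree": pd.Series(deg),
            "betweenness": pd.Series(betw),
            "closeness": pd.Series(close),
            "stress": pd.Series(stress),
        }
    )
    table.index.name = "node"
    table = table.sort_index().sort_values("degree", ascending=False, kind="stable")
    return table
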