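"""Read and write interaction networks.

The in-memory network is a plain :class:`networkx.Graph` over gene-symbol
node labels: simple (no self-loops, no parallel edges), undirected, with an
optional ``score`` attribute per edge.  Supported external formats:

* 2/3-column delimited edge list (``nodeA  nodeB  [score]``),
* STRING ``protein.links`` dialect (``protein1 protein2 combined_score``
  header, whitespace-delimited, scores in [0, 1000]),
* SIF (``nodeA <tab> pp <tab> nodeB``; isolated nodes as bare lines).

All writers emit UTF-8, LF endings, and sorted order so outputs are
byte-stable and diffable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["read_edge_list", "read_string_links", "write_network", "canonical_edge"]

#: STRING medium-confidence combined-score threshold; the conventional default
#: when no threshold is given.  Changing it changes every downstream number.
DEFAULT_STRING_THRESHOLD = 400


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Lexicographically sorted pair — the canonical undirected edge key."""
    return (u, v) if u <= v else (v, u)


def _add_edge(net: nx.Graph, u: str, v: str, score: float | None) -> bool:
    """Add a simple-graph edge, keeping the max score on duplicates.

    Returns True if the edge was new.
    """
    if net.has_edge(u, v):
        if score is not None:
            old = net.edges[u, v].get("score")
            if old is None or score > old:
                net.edges[u, v]["score"] = score
        return False
    if score is None:
        net.add_edge(u, v)
    else:
        net.add_edge(u, v, score=score)
    return True


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    score_column: int | None = 2,
) -> nx.Graph:
    """Read a 2/3-column edge list into a simple undirected graph.

    ``delimiter=None`` splits on any whitespace.  ``score_column`` is the
    0-based index of an optional numeric score column; a non-numeric cell on
    the first line is treated as a header and skipped.  Self-loops are
    dropped and duplicate edges collapsed (keeping the max score), both with
    a logged count.
    """
    path = Path(path)
    net: nx.Graph = nx.Graph()
    n_loops = n_dups = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) == 1:
                # bare single-column line: isolated node (as written by write_network)
                net.add_node(parts[0])
                continue
            if len(parts) == 3 and parts[1] == "pp":
                # SIF dialect: nodeA pp nodeB
                parts = [parts[0], parts[2]]
            u, v = parts[0], parts[1]
            score: float | None = None
            if score_column is not None and len(parts) > score_column:
                try:
                    score = float(parts[score_column])
                except ValueError:
                    if net.number_of_nodes() == 0 and lineno == 1:
                        continue  # header line
                    raise ValueError(f"{path}:{lineno}: non-numeric score {parts[score_column]!r}")
            if u == v:
                n_loops += 1
                net.add_node(u)
                continue
            if not _add_edge(net, u, v, score):
                n_dups += 1
    if net.number_of_nodes() == 0:
        raise ValueError(f"empty graph: {path}")
    if n_loops or n_dups:
        logger.info("%s: dropped %d self-loops, collapsed %d duplicate edges", path, n_loops, n_dups)
    return net


def read_string_links(
    path: str | Path,
    score_threshold: int = DEFAULT_STRING_THRESHOLD,
    keep_prefix: bool = False,
) -> nx.Graph:
    """Read a STRING ``protein.links``-style file with a combined-score cutoff.

    Requires the ``protein1 protein2 combined_score`` header.  Identifiers of
    the form ``taxid.ENSPxxxx`` keep only the part after the first dot unless
    ``keep_prefix`` is set.  Edges scoring below ``score_threshold`` are
    excluded; if that removes every edge, a ``ValueError`` is raised.
    """
    path = Path(path)
    net: nx.Graph = nx.Graph()
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if header[:3] != ["protein1", "protein2", "combined_score"]:
            raise ValueError(f"{path}: missing 'protein1 protein2 combined_score' header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            u, v, raw = parts[0], parts[1], parts[2]
            score = float(raw)
            if score < score_threshold:
                continue
            if not keep_prefix:
                u = u.split(".", 1)[-1]
                v = v.split(".", 1)[-1]
            if u == v:
                continue
            _add_edge(net, u, v, score)
    if net.number_of_edges() == 0:
        raise ValueError(f"{path}: threshold {score_threshold} removed all edges")
    return net


def write_network(net: nx.Graph, path: str | Path, format: str = "edge_list") -> None:
    """Write a network as a sorted edge list or SIF file.

    Edge-list lines are ``u<TAB>v[<TAB>score]``; SIF lines are
    ``u<TAB>pp<TAB>v``.  Isolated nodes are written as bare single-column
    lines in both dialects so the node set round-trips.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    if format not in ("edge_list", "sif"):
        raise ValueError(f"unknown format {format!r}")
    lines: list[str] = []
    for u, v in sorted(canonical_edge(u, v) for u, v in net.edges):
        if format == "sif":
            lines.append(f"{u}\tpp\t{v}")
        else:
            score = net.edges[u, v].get("score")
            lines.append(f"{u}\t{v}" if score is None else f"{u}\t{v}\t{score:g}")
    lines.extend(sorted(n for n in net.nodes if net.degree(n) == 0))
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")
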