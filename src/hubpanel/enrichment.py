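"""Term over-representation analysis with kappa grouping.

Given a query gene set (e.g. the hub-bottlenecks plus complex members of a
network analysis) and a GMT annotation collection, each term is tested with
the hypergeometric upper tail

    p = P[X >= k],   X ~ Hypergeometric(N, K, n)

where N is the universe size, K the term size, n the query size and k the
overlap.  P-values are corrected by Benjamini-Hochberg (Bonferroni by
flag).  Significant terms are then collapsed into redundancy groups by
Cohen's kappa agreement of their membership vectors over the query's genes,
merging pairs with kappa >= 0.4 (single linkage) and labelling each group
by its most significant member — an emulation of the term-grouping style of
ClueGO-like tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .gene_lists import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "read_gmt",
    "write_gmt",
    "hypergeom_p",
    "ora",
    "kappa_grouping",
    "cohens_kappa",
]


@dataclass(frozen=True)
class AnnotationSet:
    """Terms (id -> (name, gene set)) plus the gene universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"empty term {tid!r}")
            if not genes <= self.universe:
                raise ValueError(f"term {tid!r} has genes outside the universe")

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path: str | Path, universe: GeneSet | None = None) -> AnnotationSet:
    """Parse a GMT file: ``term_id <TAB> description <TAB> gene1 <TAB> ...``.

    The universe defaults to the union of all term genes unless supplied.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    union: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            tid, name = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {tid!r} has no genes")
            terms[tid] = (name, genes)
            union |= genes
    uni = frozenset(universe.members) if universe is not None else frozenset(union)
    return AnnotationSet(terms=terms, universe=uni | frozenset(union))


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet in GMT format, sorted for byte-stable output."""
    lines = []
    for tid in sorted(ann.terms):
        name, genes = ann.terms[tid]
        lines.append("\t".join([tid, name, *sorted(genes)]))
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k], X ~ HG(N, K, n)."""
    if not (0 <= k <= K <= N and k <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ora(query: GeneSet, ann: AnnotationSet, alpha: float = 0.05,
        method: str = "fdr_bh") -> pd.DataFrame:
    """Over-representation of every annotation term in the query set.

    Returns a DataFrame sorted by p ascending with columns term_id, name,
    k, K, n, N, p, q, significant.  Query genes outside the universe are
    dropped (logged); an empty effective query is an error.
    """
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unsupported correction method {method!r}")
    effective = query.members & ann.universe
    dropped = len(query.members) - len(effective)
    if dropped:
        logger.info("ora: dropped %d query genes outside the universe", dropped)
    if not effective:
        raise ValueError("query has no genes in the annotation universe")
    N = len(ann.universe)
    n = len(effective)
    rows = []
    for tid in sorted(ann.terms):
        name, genes = ann.terms[tid]
        K = len(genes)
        k = len(effective & genes)
        rows.append({"term_id": tid, "name": name, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_p(k, K, n, N)})
    res = pd.DataFrame(rows)
    res["q"] = multipletests(res["p"].to_numpy(), method=method)[1]
    res["significant"] = res["q"] <= alpha
    res = res.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    return res


def cohens_kappa(members_a: frozenset[str], members_b: frozenset[str],
                 domain: frozenset[str]) -> float:
    """Cohen's kappa between two membership indicators over ``domain``."""
    m = len(domain)
    if m == 0:
        return 0.0
    a = {g for g in domain if g in members_a}
    b = {g for g in domain if g in members_b}
    both = len(a & b)
    neither = m - len(a | b)
    po = (both + neither) / m
    pe = (len(a) * len(b) + (m - len(a)) * (m - len(b))) / (m * m)
    if pe == 1.0:
        return 1.0  # identical constant indicators agree perfectly
    return (po - pe) / (1.0 - pe)


def kappa_grouping(res: pd.DataFrame, ann: AnnotationSet, query: GeneSet,
                   kappa_threshold: float = 0.4) -> pd.DataFrame:
    """Collapse significant terms into kappa-similarity groups.

    Kappa is computed between term membership vectors restricted to the
    query's genes (those in the universe).  Term pairs at or above the
    threshold are merged by single linkage; each group is labelled by its
    most significant term (ties: lexicographic term id).  Returns a copy of
    ``res`` with a ``group`` column (empty string for non-significant rows).
    """
    res = res.copy()
    sig = sorted(res.loc[res["significant"], "term_id"])
    if not sig:
        raise ValueError("no significant term to group")
    domain = frozenset(query.members & ann.universe)
    parent = {t: t for t in sig}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, t1 in enumerate(sig):
        for t2 in sig[i + 1:]:
            kap = cohens_kappa(ann.terms[t1][1], ann.terms[t2][1], domain)
            if kap >= kappa_threshold:
                r1, r2 = sorted((find(t1), find(t2)))
                parent[r2] = r1
    clusters: dict[str, list[str]] = {}
    for t in sig:
        clusters.setdefault(find(t), []).append(t)
    pvals = res.set_index("term_id")["p"]
    label_of: dict[str, str] = {}
    for members in clusters.values():
        label = min(members, key=lambda t: (pvals[t], t))
        for t in members:
            label_of[t] = label
    res["group"] = [label_of.get(t, "") for t in res["term_id"]]
    n_groups = len(set(label_of.values()))
    logger.info("kappa grouping: %d significant terms -> %d groups", len(sig), n_groups)
    return res
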