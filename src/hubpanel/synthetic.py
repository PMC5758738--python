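"""Synthetic study inputs with planted ground truth.

Every input the analysis pipeline consumes can be generated here with a
truth record sufficient to verify downstream recovery:

* three overlapping disease gene lists sharing a planted common core,
* a scale-free interaction network (preferential attachment) with planted
  high-degree/high-betweenness hubs, planted dense complexes, and optional
  extra connected components,
* a GMT annotation collection with planted enriched term blocks whose
  within-block kappa is high and between-block kappa is low.

Design notes.  Hubs are planted by adding edges from each hub to random
*background* nodes (never to other hubs or to complex members), then
verifying arithmetically that every planted hub clears the mean + 2 SD
degree cutoff and no other node does; the boost is increased until the
margin holds, so hub recovery is a construction guarantee, not a
probabilistic hope.  Keeping hub neighborhoods sparse also keeps their
core-clustering weight low, so hubs neither absorb into nor outrank the
planted dense complexes.  Non-enriched annotation terms receive a
*deterministic chance-level* number of query genes (floor(K*n/N)): the
planted negative labels are thereby true negatives by construction, which
makes "exactly the planted terms are significant" a well-defined ground
truth.  Set ``random_background=True`` to draw background terms uniformly
instead (the right mode for false-positive-rate simulations, where the
point is that overlaps fluctuate by chance).

The generators and the analysis modules share no code path for any planted
quantity, so recovery tests are genuine round trips through the parsers
and algorithms.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .gene_lists import GeneSet, write_gene_list
from .enrichment import AnnotationSet, write_gmt
from .graph_io import write_network

__all__ = ["SyntheticSpec", "SyntheticTruth", "make_gene_lists", "make_network",
           "make_annotations", "make_annotation_instance", "make_bundle",
           "write_bundle"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study; defaults mirror the replica shape
    (17-gene core, 8 hubs, 4 components, 3 complexes, 9 term blocks)."""

    rng_seed: int = 42
    # disease gene lists
    list_sizes: tuple[int, int, int] = (232, 143, 132)
    list_names: tuple[str, str, str] = ("colon", "gastric", "esophageal")
    core_size: int = 17
    # interaction network
    graph_n: int = 300
    graph_m: int = 2
    planted_hub_count: int = 8
    hub_degree: int = 150
    component_sizes: tuple[int, ...] = (30, 20, 10)
    complexes: tuple[tuple[int, float], ...] = ((16, 0.8), (11, 0.8), (6, 0.8))
    # annotations
    universe_size: int = 200
    query_size: int = 45
    n_terms: int = 60
    n_blocks: int = 9
    terms_per_block: int = 2
    block_filler: int = 1
    null_term_size: int = 10
    random_background: bool = False

    def __post_init__(self) -> None:
        if self.core_size > min(self.list_sizes):
            raise ValueError("core_size exceeds the smallest list size")
        if any(s <= 0 for s in self.list_sizes) or self.graph_n <= 0:
            raise ValueError("sizes must be positive")
        for size, density in self.complexes:
            if size < 3 or not 0 < density <= 1:
                raise ValueError(f"infeasible complex ({size}, {density})")
        if sum(size for size, _ in self.complexes) + self.planted_hub_count >= self.graph_n:
            raise ValueError("complexes plus hubs exceed the main component")


@dataclass
class SyntheticTruth:
    """Bookkeeping of every planted structure, for downstream verification."""

    core: list[str] = field(default_factory=list)
    hubs: list[str] = field(default_factory=list)
    degree_cutoff: float = 0.0
    component_nodes: list[list[str]] = field(default_factory=list)
    complex_members: list[list[str]] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)
    term_blocks: dict[str, int] = field(default_factory=dict)
    query: list[str] = field(default_factory=list)
    universe: list[str] = field(default_factory=list)


class _SymbolPool:
    """Unique, deterministic, gene-symbol-shaped labels."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.seen: set[str] = set()

    def draw(self, count: int, prefix: str = "") -> list[str]:
        out: list[str] = []
        letters = np.array(list(string.ascii_uppercase))
        while len(out) < count:
            body = "".join(self.rng.choice(letters, size=4))
            sym = f"{prefix}{body}{self.rng.integers(1, 100)}"
            if sym not in self.seen:
                self.seen.add(sym)
                out.append(sym)
        return out


def make_gene_lists(spec: SyntheticSpec | None = None,
                    rng: np.random.Generator | None = None,
                    pool: _SymbolPool | None = None) -> tuple[list[GeneSet], GeneSet]:
    """Three disease gene lists sharing exactly a planted common core."""
    spec = spec or SyntheticSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    pool = pool or _SymbolPool(rng)
    core = pool.draw(spec.core_size)
    lists = []
    for name, size in zip(spec.list_names, spec.list_sizes):
        fillers = pool.draw(size - spec.core_size)
        lists.append(GeneSet(name=name, members=frozenset(core) | frozenset(fillers)))
    return lists, GeneSet(name="planted_core", members=frozenset(core))


def _make_module(members: list[str], density: float,
                 rng: np.random.Generator) -> nx.Graph:
    """A dense module as a random near-regular graph at the target density.

    Regularity keeps the MCODE core-clustering weight homogeneous across
    members, so the module is a coherent planted complex rather than a
    core-plus-fringe structure.  The internal degree is
    ``round(density * (n - 1))``, nudged by one when parity forbids a
    regular graph; the achieved density can therefore differ from the
    request by ~1/(n-1).
    """
    n = len(members)
    d = round(density * (n - 1))
    d = max(2, min(d, n - 1))
    if (d * n) % 2 == 1:
        d = d - 1 if d > 2 else d + 1
    for _ in range(20):
        reg = nx.random_regular_graph(d, n, seed=int(rng.integers(2**31)))
        if nx.is_connected(reg):
            return nx.relabel_nodes(reg, {i: members[i] for i in range(n)})
    raise RuntimeError(f"could not wire a connected {d}-regular module of size {n}")


def make_network(spec: SyntheticSpec | None = None,
                 rng: np.random.Generator | None = None,
                 pool: _SymbolPool | None = None,
                 embed: GeneSet | None = None) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free network with planted hubs, complexes and extra components.

    ``embed`` (e.g. the planted common core of the gene lists) names nodes
    of the main component, so that list genes appear in the network.
    Raises ``RuntimeError`` if hub planting cannot guarantee exact recovery
    under the mean + 2 SD rule — the guarantee is checked arithmetically at
    construction time.
    """
    spec = spec or SyntheticSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    pool = pool or _SymbolPool(rng)
    truth = SyntheticTruth()

    n_module = sum(size for size, _ in spec.complexes)
    n_bg = spec.graph_n - n_module
    embed_syms = sorted(embed.members) if embed is not None else []
    fresh = pool.draw(spec.graph_n - len(embed_syms))
    symbols = list(embed_syms) + fresh
    rng.shuffle(symbols)

    # scale-free background
    base = nx.barabasi_albert_graph(n_bg, spec.graph_m,
                                    seed=int(rng.integers(2**31)))
    net: nx.Graph = nx.relabel_nodes(base, {i: symbols[i] for i in range(n_bg)})
    bg_sorted = sorted(net.nodes)

    # plant dense modules as near-regular subgraphs bridged to the background
    offset = n_bg
    module_nodes: set[str] = set()
    for size, density in spec.complexes:
        members = sorted(symbols[offset:offset + size])
        offset += size
        net = nx.union(net, _make_module(members, density, rng))
        for i in rng.choice(size, size=min(2, size), replace=False):
            net.add_edge(members[i], bg_sorted[rng.integers(len(bg_sorted))])
        truth.complex_members.append(members)
        module_nodes |= set(members)
    main_nodes = sorted(net.nodes)

    # plant hubs among the background nodes
    candidates = [v for v in bg_sorted if v not in module_nodes]
    hub_idx = rng.choice(len(candidates), size=spec.planted_hub_count, replace=False)
    hubs = sorted(candidates[i] for i in hub_idx)
    background = [v for v in candidates if v not in hubs]
    for h1 in hubs:
        for h2 in hubs:
            if net.has_edge(h1, h2):
                net.remove_edge(h1, h2)
    target = spec.hub_degree
    for _ in range(60):
        for h in hubs:
            candidates = [v for v in background if not net.has_edge(h, v)]
            need = target - net.degree(h)
            if need > 0:
                idx = rng.choice(len(candidates), size=min(need, len(candidates)),
                                 replace=False)
                for i in sorted(idx):
                    net.add_edge(h, candidates[i])
        if not hubs:
            break
        degrees = np.array([net.degree(v) for v in main_nodes], dtype=float)
        cutoff = degrees.mean() + 2.0 * degrees.std(ddof=0)
        hub_deg = [net.degree(h) for h in hubs]
        other_max = max(net.degree(v) for v in main_nodes if v not in hubs)
        if min(hub_deg) >= cutoff + 1 and other_max < cutoff - 1:
            break
        target += 25
    else:
        raise RuntimeError("hub planting failed to clear the mean+2SD cutoff")
    truth.hubs = hubs
    degrees = np.array([net.degree(v) for v in main_nodes], dtype=float)
    truth.degree_cutoff = float(degrees.mean() + 2.0 * degrees.std(ddof=0))
    truth.component_nodes.append(list(main_nodes))

    # extra connected components (preferential-attachment trees)
    for size in spec.component_sizes:
        comp = nx.barabasi_albert_graph(size, 1, seed=int(rng.integers(2**31)))
        labels = pool.draw(size)
        comp = nx.relabel_nodes(comp, {i: labels[i] for i in range(size)})
        net = nx.union(net, comp)
        truth.component_nodes.append(sorted(comp.nodes))
    return net, truth


def make_annotations(spec: SyntheticSpec, query: GeneSet,
                     universe: GeneSet | None = None,
                     rng: np.random.Generator | None = None,
                     pool: _SymbolPool | None = None) -> tuple[AnnotationSet, SyntheticTruth]:
    """GMT-style annotations with planted enriched term blocks.

    The query is partitioned into ``n_blocks`` disjoint gene blocks; each
    block yields ``terms_per_block`` enriched terms containing the whole
    block plus ``block_filler`` non-query genes, so within-block kappa over
    the query is 1 and between-block kappa is <= 0.  Background terms get a
    chance-level query overlap (deterministic, or random when
    ``random_background`` is set).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    pool = pool or _SymbolPool(rng)
    truth = SyntheticTruth()
    qgenes = sorted(query.members)
    if universe is None:
        extra = pool.draw(max(spec.universe_size - len(qgenes), 0))
        uni = sorted(set(qgenes) | set(extra))
    else:
        uni = sorted(set(universe.members) | set(qgenes))
    non_query = sorted(set(uni) - set(qgenes))
    N, n = len(uni), len(qgenes)
    truth.universe = uni
    truth.query = qgenes

    if spec.n_blocks > 0:
        block_size = len(qgenes) // spec.n_blocks
        if block_size < 1:
            raise ValueError("query too small for the requested number of blocks")
        shuffled = list(qgenes)
        rng.shuffle(shuffled)
        blocks = [sorted(shuffled[i * block_size:(i + 1) * block_size])
                  for i in range(spec.n_blocks)]
    else:
        blocks = []

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    tid_width = len(str(spec.n_terms))
    t = 0
    for b, block in enumerate(blocks):
        for _ in range(spec.terms_per_block):
            t += 1
            tid = f"T{t:0{tid_width}d}"
            fill = [non_query[i] for i in
                    rng.choice(len(non_query), size=spec.block_filler, replace=False)]
            terms[tid] = (f"planted block {b + 1} term", frozenset(block) | frozenset(fill))
            truth.enriched_terms.append(tid)
            truth.term_blocks[tid] = b + 1
    while t < spec.n_terms:
        t += 1
        tid = f"T{t:0{tid_width}d}"
        K = spec.null_term_size
        if spec.random_background:
            genes = [uni[i] for i in rng.choice(N, size=K, replace=False)]
        else:
            k_chance = (K * n) // N
            gq = [qgenes[i] for i in rng.choice(n, size=k_chance, replace=False)]
            gb = [non_query[i] for i in
                  rng.choice(len(non_query), size=K - k_chance, replace=False)]
            genes = gq + gb
        terms[tid] = ("background term", frozenset(genes))
    ann = AnnotationSet(terms=terms, universe=frozenset(uni))
    return ann, truth


def make_annotation_instance(spec: SyntheticSpec | None = None) -> tuple[GeneSet, AnnotationSet, SyntheticTruth]:
    """Standalone annotation study: a fresh universe, a random query drawn
    from it, and planted annotations against that query."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.rng_seed)
    pool = _SymbolPool(rng)
    uni = sorted(pool.draw(spec.universe_size))
    qidx = rng.choice(len(uni), size=spec.query_size, replace=False)
    query = GeneSet(name="query", members=frozenset(uni[i] for i in qidx))
    ann, truth = make_annotations(spec, query,
                                  universe=GeneSet("universe", frozenset(uni)),
                                  rng=rng, pool=pool)
    return query, ann, truth


def make_bundle(spec: SyntheticSpec | None = None) -> dict:
    """Generate a coherent full-study instance: lists, network, annotations.

    The gene-list core is embedded in the network's main component and the
    annotation query is the planted key-gene set (hubs plus complex
    members), so every pipeline stage has recoverable planted truth.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.rng_seed)
    pool = _SymbolPool(rng)
    lists, core = make_gene_lists(spec, rng, pool)
    net, net_truth = make_network(spec, rng, pool, embed=core)
    key_genes = sorted(set(net_truth.hubs)
                       | {g for m in net_truth.complex_members for g in m})
    query = GeneSet(name="planted_key_genes", members=frozenset(key_genes))
    main_nodes = GeneSet(name="universe", members=frozenset(net_truth.component_nodes[0]))
    ann_spec = spec
    ann, ann_truth = make_annotations(ann_spec, query, universe=main_nodes,
                                      rng=rng, pool=pool)
    truth = SyntheticTruth(
        core=sorted(core.members),
        hubs=net_truth.hubs,
        degree_cutoff=net_truth.degree_cutoff,
        component_nodes=net_truth.component_nodes,
        complex_members=net_truth.complex_members,
        enriched_terms=ann_truth.enriched_terms,
        term_blocks=ann_truth.term_blocks,
        query=ann_truth.query,
        universe=ann_truth.universe,
    )
    return {"spec": spec, "lists": lists, "core": core, "network": net,
            "annotations": ann, "query": query, "truth": truth}


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write a bundle to disk in the pipeline's external formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec: SyntheticSpec = bundle["spec"]
    for gs in bundle["lists"]:
        write_gene_list(gs, out / f"{gs.name}.txt")
    write_network(bundle["network"], out / "network.tsv", format="edge_list")
    write_gmt(bundle["annotations"], out / "annotations.gmt")
    write_gene_list(GeneSet("universe", frozenset(bundle["truth"].universe)),
                    out / "universe.txt")
    truth = asdict(bundle["truth"])
    truth["spec"] = asdict(spec)
    (out / "truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n", encoding="utf-8")
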