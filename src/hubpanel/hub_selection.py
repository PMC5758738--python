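"""Hub and bottleneck selection rules.

A *hub* is a node whose raw degree is at least mean + ``sd_multiplier``
standard deviations of the degree distribution (population SD: the node set
is the whole population under study, not a sample).  A *bottleneck* is a
node in the top fraction (default 5%) by betweenness centrality; a
*hub-bottleneck* is both.  The top-5% sets by stress and closeness are
reported as corroborating columns of the membership matrix, not used as
filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_lists import GeneSet
from .mcode import Complex

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "degree_cutoff",
    "select_hubs",
    "top_fraction",
    "hub_bottlenecks",
    "select",
    "membership_report",
]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the full selection procedure on one centrality table."""

    degree_cutoff: float
    hubs: GeneSet
    top_bc: GeneSet
    top_cc: GeneSet
    top_stress: GeneSet
    hub_bottlenecks: GeneSet


def degree_cutoff(degrees: dict[str, int], sd_multiplier: float = 2.0,
                  population_sd: bool = True) -> float:
    """Hub degree cutoff: mean(degrees) + sd_multiplier * SD(degrees)."""
    if len(degrees) < 2:
        raise ValueError("degree cutoff needs at least 2 nodes")
    values = np.fromiter(degrees.values(), dtype=float)
    sd = values.std(ddof=0 if population_sd else 1)
    return float(values.mean() + sd_multiplier * sd)


def select_hubs(table: pd.DataFrame, cutoff: float) -> GeneSet:
    """All nodes with degree >= cutoff (inclusive boundary)."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    members = frozenset(table.index[table["degree"] >= cutoff])
    if not members:
        logger.warning("degree cutoff %.3f selects no hubs", cutoff)
    return GeneSet(name="hubs", members=members)


def top_fraction(table: pd.DataFrame, metric: str, fraction: float = 0.05) -> GeneSet:
    """The ceil(fraction * n) highest-valued nodes by ``metric``.

    Ties at the boundary are all included, so the set may exceed the nominal
    size (logged when it does) — determinism without a hidden ordering.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    k = math.ceil(fraction * len(table))
    values = table[metric].sort_values(ascending=False, kind="stable")
    boundary = values.iloc[k - 1]
    members = frozenset(values.index[values >= boundary])
    if len(members) > k:
        logger.info("top_fraction(%s): boundary tie expands %d -> %d nodes",
                    metric, k, len(members))
    return GeneSet(name=f"top_{metric}", members=members)


def hub_bottlenecks(hubs: GeneSet, top_bc: GeneSet) -> GeneSet:
    """Hubs that are also bottlenecks (top-fraction betweenness)."""
    return GeneSet(name="hub_bottlenecks", members=hubs.members & top_bc.members)


def select(table: pd.DataFrame, fraction: float = 0.05, sd_multiplier: float = 2.0,
           population_sd: bool = True) -> SelectionResult:
    """Run the whole selection procedure on one centrality table."""
    cutoff = degree_cutoff(dict(table["degree"]), sd_multiplier, population_sd)
    hubs = select_hubs(table, cutoff)
    top_bc = top_fraction(table, "betweenness", fraction)
    top_cc = top_fraction(table, "closeness", fraction)
    top_stress = top_fraction(table, "stress", fraction)
    return SelectionResult(
        degree_cutoff=cutoff,
        hubs=hubs,
        top_bc=top_bc,
        top_cc=top_cc,
        top_stress=top_stress,
        hub_bottlenecks=hub_bottlenecks(hubs, top_bc),
    )


def membership_report(sel: SelectionResult, clusters: list[Complex] | None = None) -> pd.DataFrame:
    """Membership matrix over the hub-bottleneck genes.

    One row per hub-bottleneck; boolean columns hub, hub_bottleneck,
    top_stress, top_cc, and cluster1..k membership — the standard crucial-
    gene summary table of this kind of analysis.
    """
    clusters = clusters or []
    rows = []
    for gene in sorted(sel.hub_bottlenecks.members):
        row = {
            "gene": gene,
            "hub": True,
            "hub_bottleneck": True,
            "top_stress": gene in sel.top_stress,
            "top_cc": gene in sel.top_cc,
        }
        for i, cx in enumerate(clusters, start=1):
            row[f"cluster{i}"] = gene in cx.members
        rows.append(row)
    columns = ["gene", "hub", "hub_bottleneck", "top_stress", "top_cc"]
    columns += [f"cluster{i}" for i in range(1, len(clusters) + 1)]
    matrix = pd.DataFrame(rows, columns=columns)
    if len(matrix):
        counts = {c: int(matrix[c].sum()) for c in columns[1:]}
        logger.info("membership counts: %s", counts)
    return matrix
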