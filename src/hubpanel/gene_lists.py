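"""Disease gene lists and their multi-way intersection.

A cross-disease biomarker screen starts from one gene list per disease and
keeps the symbols shared by all of them (or, more loosely, by at least
``min_sets`` of them).  Symbols are treated as opaque, case-insensitive
strings: files in the wild mix ``tp53`` and ``TP53`` and curated tables are
uppercase, so everything is uppercased on read.  No alias or HGNC resolution
is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "read_gene_list",
    "write_gene_list",
    "intersect",
    "intersection_report",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (uppercase, deduplicated)."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        for sym in self.members:
            if not sym or sym != sym.strip() or any(ch.isspace() for ch in sym):
                raise ValueError(f"invalid gene symbol {sym!r} in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def __iter__(self):
        return iter(sorted(self.members))


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list, one symbol per line.

    Blank lines and lines starting with ``#`` are skipped; symbols are
    trimmed, uppercased and deduplicated.  Raises ``ValueError`` if nothing
    remains after filtering.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    n_read = 0
    members: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            n_read += 1
            members.add(_normalize(stripped))
    if not members:
        raise ValueError(f"empty gene list: {path}")
    logger.info("%s: %d symbols read, %d kept after dedup", path, n_read, len(members))
    return GeneSet(name=name, members=frozenset(members))


def write_gene_list(genes: GeneSet | Iterable[str], path: str | Path) -> None:
    """Write gene symbols one per line, sorted, so output is diffable."""
    symbols = sorted(genes.members if isinstance(genes, GeneSet) else set(genes))
    Path(path).write_text("".join(s + "\n" for s in symbols), encoding="utf-8")


def intersect(sets: Sequence[GeneSet], min_sets: int | None = None) -> GeneSet:
    """Symbols present in at least ``min_sets`` of the input sets.

    The default (``min_sets=None``) requires presence in *all* sets — the
    strict multi-way intersection that defines a common-gene core.
    """
    if len(sets) < 2:
        raise ValueError("intersect requires at least 2 gene sets")
    if min_sets is None:
        min_sets = len(sets)
    if not 2 <= min_sets <= len(sets):
        raise ValueError(f"min_sets must be in [2, {len(sets)}], got {min_sets}")
    counts: dict[str, int] = {}
    for gs in sets:
        for sym in gs.members:
            counts[sym] = counts.get(sym, 0) + 1
    members = frozenset(s for s, c in counts.items() if c >= min_sets)
    name = "intersection_of_" + "+".join(gs.name for gs in sets)
    return GeneSet(name=name, members=members)


def intersection_report(sets: Sequence[GeneSet]) -> "pandas.DataFrame":  # noqa: F821
    """Per-symbol membership table: symbol, n_lists, list_names.

    Also useful for distinguishing the pre-dedup total (sum of list sizes)
    from the number of distinct symbols across lists.
    """
    import pandas as pd

    rows = []
    for sym in sorted(set().union(*(gs.members for gs in sets))):
        present = [gs.name for gs in sets if sym in gs.members]
        rows.append({"symbol": sym, "n_lists": len(present), "list_names": ",".join(present)})
    return pd.DataFrame(rows, columns=["symbol", "n_lists", "list_names"])
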