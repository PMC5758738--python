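"""End-to-end orchestration: lists -> network -> centralities -> selection
-> complexes -> enrichment -> reports.

One declarative config drives the whole run; every intermediate result is
persisted as sorted TSV plus a single JSON summary, so every number in the
reports is recomputable from the files on disk and a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gene_lists import GeneSet, read_gene_list, intersect, intersection_report, write_gene_list
from .graph_io import read_edge_list, read_string_links, write_network, DEFAULT_STRING_THRESHOLD
from .graph_core import connected_components, main_component, expand, degree_distribution, fit_power_law
from .centrality import centrality_table
from .hub_selection import select, membership_report
from .mcode import McodeParams, find_complexes
from .enrichment import read_gmt, ora, kappa_grouping

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """Declarative description of one analysis run."""

    gene_lists: list[str] = field(default_factory=list)
    network: str = ""
    network_format: str = "edge_list"  # or "string"
    gmt: str | None = None
    universe: str | None = None
    out_dir: str = "hubpanel_out"
    string_score_threshold: int = DEFAULT_STRING_THRESHOLD
    expand_depth: int | None = None
    top_fraction: float = 0.05
    sd_multiplier: float = 2.0
    mcode: dict = field(default_factory=dict)
    n_complexes_for_query: int = 3
    alpha: float = 0.05
    kappa_threshold: float = 0.4
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the JSON-ready summary dict.

    Stage failures raise with the stage name; partial outputs written so
    far are renamed with a ``.partial`` suffix.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"hubpanel_version": __version__, "rng_seed": config.rng_seed}
    config_text = yaml.safe_dump(asdict(config), sort_keys=True)
    (out / "config.yaml").write_text(config_text, encoding="utf-8")
    summary["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()
    written: list[Path] = [out / "config.yaml"]
    stage = "setup"
    try:
        # --- gene lists & intersection -----------------------------------
        stage = "gene_lists"
        seeds: GeneSet | None = None
        if config.gene_lists:
            lists = [read_gene_list(p) for p in config.gene_lists]
            seeds = intersect(lists)
            report = intersection_report(lists)
            _write_tsv(report, out / "intersection.tsv")
            write_gene_list(seeds, out / "common_genes.txt")
            written += [out / "intersection.tsv", out / "common_genes.txt"]
            summary["n_lists"] = len(lists)
            summary["list_sizes"] = [len(g) for g in lists]
            summary["n_symbols_pre_dedup"] = sum(len(g) for g in lists)
            summary["n_symbols_distinct"] = len(report)
            summary["intersection_size"] = len(seeds)

        # --- network ------------------------------------------------------
        stage = "network"
        if config.network_format == "string":
            net = read_string_links(config.network, config.string_score_threshold)
        else:
            net = read_edge_list(config.network)
        if config.expand_depth is not None and seeds is not None:
            net = expand(net, seeds, depth=config.expand_depth)
        summary["n_nodes"] = net.number_of_nodes()
        summary["n_edges"] = net.number_of_edges()

        stage = "components"
        part = connected_components(net)
        comp_df = pd.DataFrame(
            [{"component": i + 1, "n_nodes": nn, "n_edges": ne}
             for i, (nn, ne) in enumerate(part.sizes)])
        _write_tsv(comp_df, out / "components.tsv")
        written.append(out / "components.tsv")
        summary["n_components"] = len(part.components)
        summary["component_sizes"] = [list(s) for s in part.sizes]
        main = main_component(net)
        write_network(main, out / "main_component.tsv")
        written.append(out / "main_component.tsv")

        # --- degree distribution & power-law fit --------------------------
        stage = "degree_distribution"
        dist = degree_distribution(main)
        _write_tsv(pd.DataFrame(sorted(dist.points.items()), columns=["k", "count"]),
                   out / "degree_distribution.tsv")
        written.append(out / "degree_distribution.tsv")
        try:
            fit = fit_power_law(dist)
            summary["power_law"] = {"a": fit.a, "b": fit.b,
                                    "r_squared": fit.r_squared,
                                    "correlation": fit.correlation}
        except ValueError as exc:
            summary["power_law"] = {"error": str(exc)}

        # --- centralities & selection -------------------------------------
        stage = "centrality"
        table = centrality_table(main)
        _write_tsv(table.reset_index(), out / "centrality.tsv")
        written.append(out / "centrality.tsv")

        stage = "hub_selection"
        sel = select(table, fraction=config.top_fraction,
                     sd_multiplier=config.sd_multiplier)
        sel_df = pd.DataFrame([
            {"quantity": "degree_cutoff", "value": f"{sel.degree_cutoff:.6g}"},
            {"quantity": "n_hubs", "value": str(len(sel.hubs))},
            {"quantity": "n_top_bc", "value": str(len(sel.top_bc))},
            {"quantity": "n_top_cc", "value": str(len(sel.top_cc))},
            {"quantity": "n_top_stress", "value": str(len(sel.top_stress))},
            {"quantity": "n_hub_bottlenecks", "value": str(len(sel.hub_bottlenecks))},
        ])
        _write_tsv(sel_df, out / "selection.tsv")
        written.append(out / "selection.tsv")
        summary["degree_cutoff"] = sel.degree_cutoff
        summary["hubs"] = sorted(sel.hubs.members)
        summary["hub_bottlenecks"] = sorted(sel.hub_bottlenecks.members)

        # --- complexes ----------------------------------------------------
        stage = "mcode"
        params = McodeParams(**config.mcode)
        complexes = find_complexes(main, params)
        cx_df = pd.DataFrame([
            {"rank": c.rank, "seed": c.seed, "score": round(c.score, 6),
             "density": round(c.density, 6), "n_nodes": len(c.members),
             "members": ",".join(sorted(c.members))}
            for c in complexes])
        _write_tsv(cx_df, out / "complexes.tsv")
        written.append(out / "complexes.tsv")
        summary["n_complexes"] = len(complexes)
        top = complexes[: config.n_complexes_for_query]
        summary["top_complex_seeds"] = [c.seed for c in top]
        summary["top_complex_sizes"] = [len(c.members) for c in top]

        stage = "membership"
        matrix = membership_report(sel, top)
        _write_tsv(matrix, out / "membership.tsv")
        written.append(out / "membership.tsv")
        summary["membership_counts"] = {
            col: int(matrix[col].sum()) for col in matrix.columns[1:]
        } if len(matrix) else {}

        # --- enrichment ---------------------------------------------------
        if config.gmt:
            stage = "enrichment"
            universe = read_gene_list(config.universe) if config.universe else None
            ann = read_gmt(config.gmt, universe=universe)
            query_members = set(sel.hubs.members)
            for c in top:
                query_members |= c.members
            query = GeneSet(name="key_genes", members=frozenset(query_members))
            res = ora(query, ann, alpha=config.alpha)
            if bool(res["significant"].any()):
                res = kappa_grouping(res, ann, query, config.kappa_threshold)
            else:
                res = res.assign(group="")
            _write_tsv(res, out / "enrichment.tsv")
            written.append(out / "enrichment.tsv")
            summary["n_query_genes"] = len(query)
            summary["n_terms_tested"] = len(res)
            summary["n_significant_terms"] = int(res["significant"].sum())
            summary["n_term_groups"] = len({g for g in res["group"] if g})

        stage = "summary"
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return summary
    except Exception as exc:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
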