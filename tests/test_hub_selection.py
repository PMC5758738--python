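import math

import numpy as np
import pandas as pd
import pytest

from hubpanel.gene_lists import GeneSet
from hubpanel.hub_selection import (
    degree_cutoff,
    hub_bottlenecks,
    membership_report,
    select,
    select_hubs,
    top_fraction,
)
from hubpanel.mcode import Complex


def table_from(degrees: dict, **extra_cols) -> pd.DataFrame:
    df = pd.DataFrame({"degree": pd.Series(degrees)})
    for name, values in extra_cols.items():
        df[name] = pd.Series(values)
    df.index.name = "node"
    return df


class TestDegreeCutoff:
    def test_zero_sd(self):
        assert degree_cutoff({"A": 1, "B": 1, "C": 1, "D": 1}) == 1.0

    def test_hand_computed(self):
        # mean 3, population sd 1 -> 3 + 2*1
        assert degree_cutoff({"A": 2, "B": 4}) == 5.0

    def test_sample_sd_switch(self):
        sample = degree_cutoff({"A": 2, "B": 4}, population_sd=False)
        assert math.isclose(sample, 3 + 2 * math.sqrt(2))

    def test_matches_one_pass_oracle(self):
        rng = np.random.default_rng(11)
        import networkx as nx

        g = nx.barabasi_albert_graph(1000, 2, seed=11)
        degrees = {f"N{v}": d for v, d in g.degree()}
        # independent one-pass mean/variance accumulation
        n = s = s2 = 0
        for d in degrees.values():
            n += 1
            s += d
            s2 += d * d
        expected = s / n + 2 * math.sqrt(s2 / n - (s / n) ** 2)
        assert math.isclose(degree_cutoff(degrees), expected, abs_tol=1e-9)

    def test_single_node_is_an_error(self):
        with pytest.raises(ValueError):
            degree_cutoff({"A": 3})


class TestSelectHubs:
    def test_boundary_inclusive(self):
        t = table_from({"A": 10, "B": 2, "C": 1})
        assert select_hubs(t, 9).members == {"A"}
        assert select_hubs(t, 10).members == {"A"}

    def test_cutoff_zero_selects_all(self):
        t = table_from({"A": 3, "B": 1})
        assert select_hubs(t, 0).members == {"A", "B"}

    def test_empty_result_is_legal(self):
        assert select_hubs(table_from({"A": 1, "B": 2}), 99).members == set()

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            select_hubs(table_from({"A": 1}), float("nan"))


class TestTopFraction:
    def test_single_maximum(self):
        t = table_from({f"N{i:02d}": i for i in range(20)},
                       betweenness={f"N{i:02d}": float(i) for i in range(20)})
        assert top_fraction(t, "betweenness", 0.05).members == {"N19"}

    def test_fraction_one_is_identity(self):
        t = table_from({"A": 1, "B": 2}, betweenness={"A": 0.0, "B": 1.0})
        assert top_fraction(t, "betweenness", 1.0).members == {"A", "B"}

    def test_boundary_tie_expansion(self):
        # 100 nodes, ranks 1..4 distinct, 3-way tie spanning rank 5
        values = {f"N{i:03d}": 0.0 for i in range(100)}
        for i, v in enumerate([9.0, 8.0, 7.0, 6.0, 5.0, 5.0, 5.0]):
            values[f"N{i:03d}"] = v
        t = table_from({k: 1 for k in values}, betweenness=values)
        out = top_fraction(t, "betweenness", 0.05)
        assert len(out.members) == 7
        assert out.members == {f"N{i:03d}" for i in range(7)}

    def test_exact_size_without_ties(self):
        rng = np.random.default_rng(0)
        values = {f"N{i:03d}": float(v) for i, v in enumerate(rng.permutation(60))}
        t = table_from({k: 1 for k in values}, stress=values)
        for fraction in (0.05, 0.1, 0.5):
            got = top_fraction(t, "stress", fraction)
            assert len(got.members) == math.ceil(fraction * 60)

    def test_shrinking_fraction_never_grows(self):
        rng = np.random.default_rng(1)
        values = {f"N{i:03d}": float(v) for i, v in enumerate(rng.permutation(40))}
        t = table_from({k: 1 for k in values}, closeness=values)
        previous = None
        for fraction in (1.0, 0.5, 0.25, 0.1, 0.05):
            current = top_fraction(t, "closeness", fraction).members
            if previous is not None:
                assert current <= previous
            previous = current

    def test_invalid_inputs(self):
        t = table_from({"A": 1}, betweenness={"A": 1.0})
        with pytest.raises(ValueError):
            top_fraction(t, "betweenness", 0.0)
        with pytest.raises(ValueError):
            top_fraction(t, "pagerank", 0.05)


class TestHubBottlenecks:
    def test_intersection(self):
        hubs = GeneSet("hubs", frozenset({"A", "B"}))
        top_bc = GeneSet("bc", frozenset({"B", "C"}))
        assert hub_bottlenecks(hubs, top_bc).members == {"B"}

    def test_disjoint(self):
        assert hub_bottlenecks(GeneSet("h", frozenset({"A"})),
                               GeneSet("b", frozenset({"B"}))).members == set()

    def test_planted_hubs_are_all_bottlenecks(self, default_bundle):
        from hubpanel.centrality import centrality_table
        from hubpanel.graph_core import main_component

        truth = default_bundle["truth"]
        table = centrality_table(main_component(default_bundle["network"]))
        sel = select(table)
        assert sel.hubs.members == set(truth.hubs)
        assert sel.hub_bottlenecks.members == set(truth.hubs)
        assert sel.hub_bottlenecks.members <= sel.top_bc.members


class TestMembershipReport:
    def make_selection(self):
        table = table_from(
            {"A": 9, "B": 8, "C": 1, "D": 1},
            betweenness={"A": 5.0, "B": 4.0, "C": 0.0, "D": 0.0},
            closeness={"A": 0.9, "B": 0.2, "C": 0.1, "D": 0.1},
            stress={"A": 7, "B": 6, "C": 0, "D": 0},
        )
        return select(table, fraction=0.5, sd_multiplier=0.5)

    def test_rows_are_hub_bottlenecks(self):
        sel = self.make_selection()
        cx = Complex(seed="A", members=frozenset({"A", "C"}), score=1.0, density=1.0)
        matrix = membership_report(sel, [cx])
        assert list(matrix["gene"]) == sorted(sel.hub_bottlenecks.members)
        assert matrix["hub"].all() and matrix["hub_bottleneck"].all()
        row_a = matrix.set_index("gene").loc["A"]
        assert bool(row_a["cluster1"]) is True

    def test_empty_selection_gives_header_only(self):
        table = table_from({"A": 1, "B": 100},
                           betweenness={"A": 1.0, "B": 0.0},
                           closeness={"A": 0.5, "B": 0.5},
                           stress={"A": 1, "B": 0})
        sel = select(table, fraction=0.5, sd_multiplier=2.0)
        matrix = membership_report(sel, [])
        assert len(matrix) == 0
        assert list(matrix.columns)[:2] == ["gene", "hub"]

    def test_matches_planted_truth_table(self, default_bundle):
        from hubpanel.centrality import centrality_table
        from hubpanel.graph_core import main_component
        from hubpanel.mcode import find_complexes

        truth = default_bundle["truth"]
        main = main_component(default_bundle["network"])
        sel = select(centrality_table(main))
        clusters = find_complexes(main)[:3]
        matrix = membership_report(sel, clusters).set_index("gene")
        assert sorted(matrix.index) == truth.hubs
        # planted hubs are wired into the sparse background, never into modules
        for i in range(1, 4):
            assert not matrix[f"cluster{i}"].any()

    def test_lower_cutoff_never_shrinks_hub_set(self):
        table = table_from({f"N{i}": i for i in range(10)})
        previous = set()
        for cutoff in (9, 6, 3, 0):
            current = select_hubs(table, cutoff).members
            assert current >= previous
            previous = current
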