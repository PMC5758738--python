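import math

import numpy as np
import pytest

from _oracles import hypergeom_upper_tail
from hubpanel.enrichment import (
    AnnotationSet,
    cohens_kappa,
    hypergeom_p,
    kappa_grouping,
    ora,
    read_gmt,
    write_gmt,
)
from hubpanel.gene_lists import GeneSet
from hubpanel.synthetic import SyntheticSpec, make_annotation_instance


def ann_from(terms: dict[str, set[str]], universe: set[str] | None = None) -> AnnotationSet:
    uni = universe if universe is not None else set().union(*terms.values())
    return AnnotationSet(
        terms={tid: (tid.lower(), frozenset(genes)) for tid, genes in terms.items()},
        universe=frozenset(uni),
    )


class TestGmtIo:
    def test_single_line(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc\tA\tB\tC\n")
        ann = read_gmt(p)
        assert ann.terms["T1"] == ("desc", frozenset({"A", "B", "C"}))
        assert ann.universe == {"A", "B", "C"}

    def test_duplicate_gene_deduplicated(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc\tA\tA\tB\n")
        assert read_gmt(p).terms["T1"][1] == frozenset({"A", "B"})

    def test_short_line_is_an_error(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc-without-genes\n")
        with pytest.raises(ValueError, match="3"):
            read_gmt(p)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        genes = [f"G{i:03d}" for i in range(80)]
        terms = {
            f"T{i:02d}": {genes[j] for j in rng.choice(80, size=8, replace=False)}
            for i in range(50)
        }
        ann = ann_from(terms)
        write_gmt(ann, tmp_path / "out.gmt")
        back = read_gmt(tmp_path / "out.gmt")
        assert back.terms == ann.terms and back.universe == ann.universe


class TestHypergeomP:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_p(0, 4, 5, 10) == 1.0

    def test_closed_form_example(self):
        # C(4,4)*C(6,1)/C(10,5) = 6/252
        assert math.isclose(hypergeom_p(4, 4, 5, 10), 6 / 252, abs_tol=1e-12)

    def test_matches_enumeration_on_random_draws(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert math.isclose(
                hypergeom_p(k, K, n, N), hypergeom_upper_tail(k, K, n, N), abs_tol=1e-12
            )

    def test_monotone_in_k(self):
        previous = 1.1
        for k in range(0, 6):
            p = hypergeom_p(k, 8, 6, 30)
            assert p <= previous
            previous = p

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            hypergeom_p(5, 4, 5, 10)


class TestOra:
    def test_full_term_query_single_term(self):
        universe = {f"G{i}" for i in range(20)}
        term = {"G0", "G1", "G2", "G3"}
        ann = ann_from({"T1": term}, universe=universe)
        query = GeneSet("q", frozenset(term))
        res = ora(query, ann)
        expected = hypergeom_upper_tail(4, 4, 4, 20)
        assert math.isclose(res.loc[0, "p"], expected, abs_tol=1e-12)
        assert res.loc[0, "q"] == res.loc[0, "p"]  # single term: q == p

    def test_disjoint_query_all_p_one(self):
        universe = {f"G{i}" for i in range(30)}
        ann = ann_from({"T1": {"G0", "G1"}, "T2": {"G2", "G3"}}, universe=universe)
        res = ora(GeneSet("q", frozenset({"G10", "G11"})), ann)
        assert (res["k"] == 0).all() and (res["p"] == 1.0).all()
        assert not res["significant"].any()

    def test_outside_universe_genes_dropped(self):
        universe = {"A", "B", "C", "D"}
        ann = ann_from({"T1": {"A", "B"}}, universe=universe)
        res = ora(GeneSet("q", frozenset({"A", "ZZZ"})), ann)
        assert res.loc[0, "n"] == 1

    def test_empty_effective_query_is_an_error(self):
        ann = ann_from({"T1": {"A"}}, universe={"A"})
        with pytest.raises(ValueError, match="universe"):
            ora(GeneSet("q", frozenset({"ZZZ"})), ann)

    def test_bh_q_monotone_in_p_rank(self):
        query, ann, _ = make_annotation_instance(SyntheticSpec(rng_seed=3))
        res = ora(query, ann)
        assert (res["q"].diff().dropna() >= -1e-12).all()
        assert ((res["q"] >= res["p"] - 1e-15) & (res["q"] <= 1.0)).all()

    def test_planted_terms_are_all_and_only_calls(self):
        query, ann, truth = make_annotation_instance(SyntheticSpec(rng_seed=11))
        res = ora(query, ann)
        called = set(res.loc[res["significant"], "term_id"])
        assert called == set(truth.enriched_terms)

    def test_bonferroni_flag(self):
        query, ann, _ = make_annotation_instance(SyntheticSpec(rng_seed=5))
        bh = ora(query, ann, method="fdr_bh")
        bf = ora(query, ann, method="bonferroni")
        merged = bh.set_index("term_id")["q"], bf.set_index("term_id")["q"]
        assert (merged[1] >= merged[0] - 1e-12).all()


class TestKappaGrouping:
    def test_identical_terms_merge(self):
        universe = {f"G{i}" for i in range(12)}
        term = {"G0", "G1", "G2", "G3"}
        ann = ann_from({"T1": set(term), "T2": set(term)}, universe=universe)
        query = GeneSet("q", frozenset(term | {"G4"}))
        res = kappa_grouping(ora(query, ann, alpha=0.5), ann, query)
        groups = {g for g in res["group"] if g}
        assert len(groups) == 1

    def test_disjoint_terms_stay_apart(self):
        universe = {f"G{i}" for i in range(40)}
        ann = ann_from({"T1": {"G0", "G1", "G2"}, "T2": {"G3", "G4", "G5"}},
                       universe=universe)
        query = GeneSet("q", frozenset({f"G{i}" for i in range(6)}))
        res = kappa_grouping(ora(query, ann, alpha=1.0), ann, query)
        assert len({g for g in res["group"] if g}) == 2

    def test_kappa_values(self):
        domain = frozenset({"A", "B", "C", "D"})
        assert cohens_kappa(frozenset({"A", "B"}), frozenset({"A", "B"}), domain) == 1.0
        assert cohens_kappa(frozenset({"A", "B"}), frozenset({"C", "D"}), domain) <= 0.0

    def test_nine_planted_blocks_give_nine_groups(self):
        query, ann, truth = make_annotation_instance(SyntheticSpec(rng_seed=42))
        res = kappa_grouping(ora(query, ann), ann, query)
        sig = res.loc[res["significant"]]
        groups = {g for g in sig["group"] if g}
        assert len(groups) == 9
        # groups must coincide with the planted blocks
        block_of_group = {}
        for _, row in sig.iterrows():
            block = truth.term_blocks[row["term_id"]]
            block_of_group.setdefault(row["group"], set()).add(block)
        assert all(len(blocks) == 1 for blocks in block_of_group.values())

    def test_grouping_invariant_to_term_order(self):
        query, ann, _ = make_annotation_instance(SyntheticSpec(rng_seed=8))
        res = ora(query, ann)
        shuffled = res.sample(frac=1.0, random_state=0)
        a = kappa_grouping(res, ann, query)
        b = kappa_grouping(shuffled, ann, query)
        mapping_a = dict(zip(a["term_id"], a["group"]))
        mapping_b = dict(zip(b["term_id"], b["group"]))
        assert mapping_a == mapping_b

    def test_no_significant_terms_is_an_error(self):
        universe = {f"G{i}" for i in range(30)}
        ann = ann_from({"T1": {"G0", "G1"}}, universe=universe)
        query = GeneSet("q", frozenset({"G10"}))
        res = ora(query, ann)
        with pytest.raises(ValueError, match="no significant term"):
            kappa_grouping(res, ann, query)

    def test_groups_partition_significant_terms(self):
        query, ann, _ = make_annotation_instance(SyntheticSpec(rng_seed=21))
        res = kappa_grouping(ora(query, ann), ann, query)
        sig = res.loc[res["significant"]]
        assert (sig["group"] != "").all()
        assert (res.loc[~res["significant"], "group"] == "").all()
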