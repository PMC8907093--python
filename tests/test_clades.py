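"""Clade delimitation by MRCA, placement classification, table extraction."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from amf_lsu.clades import (
    AMF_CLADE, UNCLASSIFIED_AMF, CladeError, CladeModel, classify_placement,
    define_clade, extract_tables, root_tree, summarize_fractions,
)
from amf_lsu.cluster import dereplicate
from amf_lsu.placement import ROOT_EDGE, BackboneTree, Placement
from amf_lsu.simdata import simulate_tree

from oracles import brute_member_edges


def make_backbone(newick: str) -> BackboneTree:
    return BackboneTree.from_newick(newick)


class TestRootTree:
    def test_already_rooted_is_unchanged(self):
        t = dendropy.Tree.get(data="(OUT,(A,(B,C)));", schema="newick",
                              preserve_underscores=True)
        rooted = root_tree(t, "OUT")
        assert {c.taxon.label for c in rooted.seed_node.child_nodes()
                if c.is_leaf()} == {"OUT"}

    def test_reroot_places_outgroup_at_root(self):
        t = dendropy.Tree.get(data="((A,OUT),(B,C));", schema="newick",
                              preserve_underscores=True)
        rooted = root_tree(t, "OUT")
        kids = rooted.seed_node.child_nodes()
        leaf_kids = [c.taxon.label for c in kids if c.is_leaf()]
        assert "OUT" in leaf_kids

    def test_idempotent(self):
        t = dendropy.Tree.get(data="((A,OUT),(B,C));", schema="newick",
                              preserve_underscores=True)
        once = root_tree(t, "OUT")
        twice = root_tree(once, "OUT")
        assert once.as_string(schema="newick") == twice.as_string(schema="newick")

    def test_missing_outgroup_rejected(self):
        t = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        with pytest.raises(CladeError):
            root_tree(t, "ZZZ")


class TestDefineClade:
    def test_smallest_cherry(self):
        bt = make_backbone("((A,B),C);")
        entry = define_clade(bt, ["A", "B"], "cherry")
        assert entry.member_edges == {bt.edge_of_tip("A"), bt.edge_of_tip("B")}

    def test_tips_spanning_root_cover_all_edges(self):
        bt = make_backbone("((A,B),(C,D));")
        entry = define_clade(bt, ["A", "C"], "all")
        assert entry.member_edges == set(range(bt.n_edges))
        assert entry.mrca_edge_id == ROOT_EDGE

    def test_matches_brute_force_containment_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            bt = BackboneTree(simulate_tree(12, 700 + trial))
            k = int(rng.integers(2, 7))
            tips = list(rng.choice(bt.tip_labels, size=k, replace=False))
            entry = define_clade(bt, tips, "X")
            assert entry.member_edges == brute_member_edges(bt, set(tips))

    def test_too_few_or_unknown_tips_rejected(self):
        bt = make_backbone("((A,B),C);")
        with pytest.raises(CladeError):
            define_clade(bt, ["A"], "X")
        with pytest.raises(CladeError):
            define_clade(bt, ["A", "Z"], "X")

    def test_membership_invariant_to_tip_rotation(self):
        bt1 = make_backbone("((A,B),(C,D));")
        bt2 = make_backbone("((B,A),(D,C));")
        tips1 = {bt1.edge_label(e) for e in define_clade(bt1, ["A", "B"], "X").member_edges}
        tips2 = {bt2.edge_label(e) for e in define_clade(bt2, ["A", "B"], "X").member_edges}
        assert tips1 == tips2 == {"A", "B"}


def toy_model(include_stem=False):
    """(((F1a,F1b),(F2a,F2b)),OUT): AMF = 4 tips in two families."""
    bt = make_backbone("(((F1a,F1b),(F2a,F2b)),OUT);")
    import pandas as pd
    fam = pd.DataFrame([
        {"id": "F1a", "group_label": "Fam1", "is_amf": "1"},
        {"id": "F1b", "group_label": "Fam1", "is_amf": "1"},
        {"id": "F2a", "group_label": "Fam2", "is_amf": "1"},
        {"id": "F2b", "group_label": "Fam2", "is_amf": "1"},
        {"id": "OUT", "group_label": "Outgroup", "is_amf": "0"},
    ])
    model = CladeModel.from_family_map(bt, fam, include_stem=include_stem)
    return bt, model


def placement_at(edge_id, qid="q"):
    return Placement(query_id=qid, best_edge_id=edge_id, parsimony_score=0,
                     score_margin=0, tie_count=1)


class TestClassifyPlacement:
    def test_family_edge(self):
        bt, model = toy_model()
        a = classify_placement(placement_at(bt.edge_of_tip("F1a")), model)
        assert a.is_amf and a.family == "Fam1"

    def test_amf_stem_is_outside_by_default(self):
        bt, model = toy_model()
        stem = model.amf.mrca_edge_id
        a = classify_placement(placement_at(stem), model)
        assert not a.is_amf and a.family is None

    def test_amf_stem_inside_with_include_stem(self):
        bt, model = toy_model(include_stem=True)
        a = classify_placement(placement_at(model.amf.mrca_edge_id), model)
        assert a.is_amf

    def test_between_families_is_unclassified_amf(self):
        bt, model = toy_model()
        fam_stems = {f.mrca_edge_id for f in model.families.values()}
        inside_not_family = (model.amf.member_edges
                             - set().union(*[f.member_edges for f in model.families.values()])
                             - set())
        # family stem edges sit inside AMF but belong to no family
        for e in fam_stems:
            a = classify_placement(placement_at(e), model)
            assert a.is_amf and a.family == UNCLASSIFIED_AMF

    def test_root_edge_is_non_amf(self):
        bt, model = toy_model()
        a = classify_placement(placement_at(ROOT_EDGE), model)
        assert not a.is_amf

    def test_unknown_edge_rejected(self):
        bt, model = toy_model()
        with pytest.raises(CladeError):
            classify_placement(placement_at(999), model)

    def test_eleven_families_resolved_from_fixture(self, small_fixture):
        bt = BackboneTree.from_newick(small_fixture.newick)
        model = CladeModel.from_family_map(bt, small_fixture.family_map)
        assert len(model.families) == small_fixture.config.n_families
        # family edge sets are pairwise disjoint
        all_edges = [model.families[f].member_edges for f in model.family_names]
        for i in range(len(all_edges)):
            for j in range(i + 1, len(all_edges)):
                assert not (all_edges[i] & all_edges[j])
        # every family edge set sits inside the AMF clade
        for edges in all_edges:
            assert edges <= model.amf.member_edges


def toy_table():
    return dereplicate([
        ("f1", "AAAA", {"s": 10}), ("f2", "CCCC", {"s": 20}),
        ("f3", "GGGG", {"s": 30}), ("f4", "TTTT", {"s": 40}),
    ])


class TestExtractAndSummarize:
    def test_partition_property(self):
        bt, model = toy_model()
        table = toy_table()
        from amf_lsu.clades import CladeAssignment
        assignments = [
            CladeAssignment("f1", True, "Fam1"),
            CladeAssignment("f2", True, "Fam2"),
            CladeAssignment("f3", True, UNCLASSIFIED_AMF),
            CladeAssignment("f4", False, None),
        ]
        out = extract_tables(table, assignments, model)
        fam_features = [f for t in out.families.values() for f in t.feature_ids]
        assert sorted(fam_features + out.unclassified_amf.feature_ids) == \
            sorted(out.amf.feature_ids)
        assert sorted(out.amf.feature_ids + out.non_amf.feature_ids) == \
            sorted(table.feature_ids)
        assert out.amf.total_reads() + out.non_amf.total_reads() == 100

    def test_features_without_assignment_are_non_amf(self):
        bt, model = toy_model()
        out = extract_tables(toy_table(), [], model)
        assert len(out.non_amf.feature_ids) == 4
        assert out.amf.feature_ids == []

    def test_fraction_arithmetic(self):
        from amf_lsu.clades import CladeAssignment
        table = dereplicate([
            ("f1", "AAAA", {"s": 70}), ("f2", "CCCC", {"s": 10}),
            ("f3", "GGGG", {"s": 10}), ("f4", "TTTT", {"s": 10}),
        ])
        assignments = [
            CladeAssignment("f1", True, "FamX"),
            CladeAssignment("f2", True, "FamY"),
            CladeAssignment("f3", True, "FamY"),
            CladeAssignment("f4", True, "FamY"),
        ]
        df = summarize_fractions(assignments, table).set_index("clade")
        assert df.loc["FamX", "pct_features"] == 25.0
        assert df.loc["FamX", "pct_reads"] == 70.0
        assert df["pct_features"].sum() == pytest.approx(100.0)
        assert df["pct_reads"].sum() == pytest.approx(100.0)

    def test_zero_amf_features_reports_empty(self):
        df = summarize_fractions([], toy_table())
        assert df.empty
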