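"""Fitch scoring and minimum-parsimony query attachment."""

from __future__ import annotations

import numpy as np
import pytest

from amf_lsu.placement import (
    ROOT_EDGE, BackboneTree, PlacementError, build_fitch_index,
    fitch_parsimony_score, place_batch, place_query,
)
from amf_lsu.simdata import mutate, simulate_tree

from oracles import naive_fitch_score, naive_place, to_tuples


def rand_rows(tree: BackboneTree, rng, width=20):
    return {t: "".join("ACGT"[i] for i in rng.integers(0, 4, size=width))
            for t in tree.tip_labels}


def random_backbone(n_tips, seed) -> BackboneTree:
    return BackboneTree(simulate_tree(n_tips, seed))


class TestFitchScore:
    def test_identical_tips_score_zero(self):
        bt = BackboneTree.from_newick("((A,B),(C,D));")
        rows = {t: "ACGTACGT" for t in "ABCD"}
        assert fitch_parsimony_score(bt, rows) == 0

    def test_textbook_single_column(self):
        bt = BackboneTree.from_newick("((A,B),(C,D));")
        rows = {"A": "A", "B": "A", "C": "T", "D": "T"}
        assert fitch_parsimony_score(bt, rows) == 1

    def test_missing_data_is_wildcard(self):
        bt = BackboneTree.from_newick("((A,B),(C,D));")
        rows = {"A": "A", "B": "N", "C": "-", "D": "T"}
        assert fitch_parsimony_score(bt, rows) == 1

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(21)
        for trial in range(20):
            bt = random_backbone(6, 100 + trial)
            rows = rand_rows(bt, rng, width=20)
            assert fitch_parsimony_score(bt, rows) == \
                naive_fitch_score(to_tuples(bt), rows)

    def test_missing_row_rejected(self):
        bt = BackboneTree.from_newick("((A,B),(C,D));")
        with pytest.raises(PlacementError, match="D"):
            fitch_parsimony_score(bt, {"A": "A", "B": "A", "C": "A"})


class TestPlaceQuery:
    def test_query_identical_to_tip_lands_on_its_pendant_edge(self):
        rng = np.random.default_rng(31)
        bt = random_backbone(8, 55)
        rows = rand_rows(bt, rng, width=40)
        index = build_fitch_index(bt, rows)
        for tip in bt.tip_labels[:4]:
            p = place_query(index, "q", rows[tip])
            assert p.best_edge_id == bt.edge_of_tip(tip)
            assert p.score_margin >= 0

    def test_symmetric_tie_resolves_rootward(self):
        bt = BackboneTree.from_newick("((A,B),(C,D));")
        rows = {"A": "AAAA", "B": "GGGG", "C": "TTTT", "D": "TTTT"}
        index = build_fitch_index(bt, rows)
        # query equidistant between sister tips A and B
        p = place_query(index, "q", "AAGG")
        assert p.tie_count >= 2
        oracle_edge, oracle_score, oracle_ties, _ = naive_place(
            bt, rows, "q", "AAGG")
        assert p.best_edge_id == oracle_edge
        assert p.parsimony_score == oracle_score
        assert p.tie_count == oracle_ties

    def test_equals_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(41)
        for trial in range(25):
            n_tips = int(rng.integers(4, 12))
            bt = random_backbone(n_tips, 500 + trial)
            width = int(rng.integers(10, 30))
            rows = rand_rows(bt, rng, width=width)
            index = build_fitch_index(bt, rows)
            query = "".join("ACGT"[i] for i in rng.integers(0, 4, size=width))
            p = place_query(index, "q", query)
            oe, os_, ot, om = naive_place(bt, rows, "q", query)
            assert (p.best_edge_id, p.parsimony_score, p.tie_count,
                    p.score_margin) == (oe, os_, ot, om)

    def test_query_near_tip_places_in_its_neighborhood(self):
        rng = np.random.default_rng(51)
        bt = random_backbone(10, 77)
        rows = rand_rows(bt, rng, width=200)
        index = build_fitch_index(bt, rows)
        for tip in bt.tip_labels:
            q = mutate(rows[tip], 0.02, rng)
            p = place_query(index, "q", q)
            dist = bt.topological_edge_distance(p.best_edge_id,
                                                bt.edge_of_tip(tip))
            assert dist <= 1

    def test_all_missing_query_flagged_unplaceable(self):
        bt = BackboneTree.from_newick("((A,B),(C,D));")
        rows = {t: "ACGT" for t in "ABCD"}
        index = build_fitch_index(bt, rows)
        p = place_query(index, "q", "NN--")
        assert p.unplaceable

    def test_width_mismatch_rejected(self):
        bt = BackboneTree.from_newick("((A,B),(C,D));")
        index = build_fitch_index(bt, {t: "ACGT" for t in "ABCD"})
        with pytest.raises(PlacementError):
            place_query(index, "q", "ACGTACGT")

    def test_degradation_monotone_in_divergence(self):
        """Mean edge distance between origin and placement grows (weakly)
        with simulated substitution divergence."""
        rng = np.random.default_rng(61)
        bt = random_backbone(12, 88)
        rows = rand_rows(bt, rng, width=300)
        index = build_fitch_index(bt, rows)
        means = []
        for rate in (0.0, 0.1, 0.4):
            dists = []
            for tip in bt.tip_labels:
                q = mutate(rows[tip], rate, rng)
                p = place_query(index, "q", q)
                dists.append(bt.topological_edge_distance(
                    p.best_edge_id, bt.edge_of_tip(tip)))
            means.append(np.mean(dists))
        assert means[0] <= means[1] <= means[2] + 1e-9
        assert means[0] == 0.0


class TestPlaceBatch:
    def test_batch_size_does_not_change_placements(self):
        rng = np.random.default_rng(71)
        bt = random_backbone(10, 99)
        rows = rand_rows(bt, rng, width=60)
        index = build_fitch_index(bt, rows)
        queries = [(f"q{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 60)))
                   for i in range(20)]
        p1, audit1 = place_batch(index, queries, batch_size=1)
        p500, audit500 = place_batch(index, queries, batch_size=500)
        assert p1 == p500
        assert len(audit1) == 20 and len(audit500) == 1

    def test_order_independence(self):
        rng = np.random.default_rng(81)
        bt = random_backbone(8, 111)
        rows = rand_rows(bt, rng, width=40)
        index = build_fitch_index(bt, rows)
        queries = [(f"q{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 40)))
                   for i in range(10)]
        fwd, _ = place_batch(index, queries)
        rev, _ = place_batch(index, list(reversed(queries)))
        assert {p.query_id: p for p in fwd} == {p.query_id: p for p in rev}

    def test_empty_queries(self):
        bt = BackboneTree.from_newick("((A,B),(C,D));")
        index = build_fitch_index(bt, {t: "ACGT" for t in "ABCD"})
        placements, audit = place_batch(index, [])
        assert placements == [] and audit == []

    def test_audit_tree_contains_reference_and_query_tips(self):
        rng = np.random.default_rng(91)
        bt = random_backbone(6, 222)
        rows = rand_rows(bt, rng, width=30)
        index = build_fitch_index(bt, rows)
        queries = [("qX", rows[bt.tip_labels[0]])]
        _, audit = place_batch(index, queries)
        import dendropy
        aug = dendropy.Tree.get(data=audit[0], schema="newick",
                                preserve_underscores=True)
        labels = {lf.taxon.label for lf in aug.leaf_node_iter()}
        assert labels == set(bt.tip_labels) | {"qX"}
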