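"""Parsimony placement of aligned study sequences into a backbone tree.

Each query is attached, one at a time, to every candidate edge of the rooted
reference tree (every real edge plus a virtual attachment above the root)
and the augmented tree is scored by Fitch small parsimony over the
concatenated alignment columns; the query's placement is the minimum-score
edge. N and '-' are wildcards (missing data), so columns with no query
information add nothing.

The per-edge score is computed without rebuilding trees: for an edge e above
node v, root the augmented tree at the new attachment node. Its two non-query
subtrees are v's subtree (down-pass Fitch set D[v]) and the rest of the tree
(up-pass set R[v]); both passes are O(n) once per tree, after which scoring
an attachment is a single vectorised intersection against the precomputed
per-edge state set:

    score(e) = base_score + #columns where edge_set(e) & query = empty

with base_score the Fitch score of the un-augmented tree (a constant). This
is exact for binary trees; multifurcations are deterministically resolved
into zero-length caterpillars first.

Queries are placed independently, so placements are invariant to batch size
and query-set composition — study sequences can never attract one another
into spurious groupings, by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .iupac import encode_mask

ROOT_EDGE = -1  # virtual attachment above the root (outside all ingroups)


class PlacementError(ValueError):
    pass


class BackboneTree:
    """A rooted backbone tree with stable preorder edge numbering.

    Edge k is the edge *above* (subtending) the k-th non-root node in
    preorder; tip labels are reference ids. Multifurcations are resolved
    deterministically (in child order, zero-length edges) so Fitch scoring
    on the binary tree is exact.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
        tree.suppress_unifurcations()
        self.tree = tree
        self._index()

    def _index(self) -> None:
        self.nodes: list[dendropy.Node] = list(self.tree.preorder_node_iter())
        self.root = self.nodes[0]
        self.node_id = {id(n): i for i, n in enumerate(self.nodes)}
        self.edge_nodes: list[dendropy.Node] = self.nodes[1:]  # node below each edge
        self.edge_depth: list[int] = []
        depth = {id(self.root): 0}
        for n in self.nodes[1:]:
            depth[id(n)] = depth[id(n.parent_node)] + 1
            self.edge_depth.append(depth[id(n)])
        self.tip_labels: list[str] = [
            lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise PlacementError("duplicate tip labels in backbone tree")

    @classmethod
    def from_newick(cls, source: str | Path) -> "BackboneTree":
        text = str(source)
        if not text.lstrip().startswith("(") and len(text) < 4096 and Path(text).exists():
            text = Path(text).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    @property
    def n_edges(self) -> int:
        return len(self.edge_nodes)

    def edge_of_tip(self, label: str) -> int:
        for i, n in enumerate(self.edge_nodes):
            if n.is_leaf() and n.taxon.label == label:
                return i
        raise KeyError(label)

    def edge_label(self, edge_id: int) -> str | None:
        """Tip label for pendant edges, None for internal edges."""
        if edge_id == ROOT_EDGE:
            return None
        n = self.edge_nodes[edge_id]
        return n.taxon.label if n.is_leaf() else None

    def topological_edge_distance(self, e1: int, e2: int) -> int:
        """Number of nodes separating two edges (0 = same edge)."""
        def path_to_root(e: int) -> list[int]:
            if e == ROOT_EDGE:
                # the virtual root edge is incident to the root node
                return [self.node_id[id(self.root)]]
            path = []
            n = self.edge_nodes[e]
            while n is not None:
                path.append(self.node_id[id(n)])
                n = n.parent_node
            return path
        p1, p2 = path_to_root(e1), path_to_root(e2)
        s2 = set(p2)
        for d1, nid in enumerate(p1):
            if nid in s2:
                return d1 + p2.index(nid)
        return len(p1) + len(p2)

    def newick(self, *, edge_numbers: bool = False) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True).strip()
        if not edge_numbers:
            return s

        # jplace convention: {edge_num} after the branch it annotates
        def write(node: dendropy.Node) -> str:
            if node.is_leaf():
                base = node.taxon.label
            else:
                base = "(" + ",".join(write(c) for c in node.child_nodes()) + ")"
            if node is self.root:
                return base
            eid = self._edge_id_of_node(node)
            bl = node.edge.length
            blpart = f":{bl:g}" if bl is not None else ""
            return f"{base}{blpart}{{{eid}}}"
        return write(self.root) + ";"

    def _edge_id_of_node(self, node: dendropy.Node) -> int:
        return self.node_id[id(node)] - 1


def encode_alignment_row(row: str) -> np.ndarray:
    """Fitch state bitmasks for one aligned row; N and '-' are wildcards."""
    return encode_mask(row, allow_gap=True)


@dataclass
class FitchIndex:
    """Precomputed per-edge Fitch state sets for query attachment scoring."""

    backbone: BackboneTree
    base_score: int
    edge_sets: np.ndarray       # (n_edges, L) uint8, preorder edge order
    root_set: np.ndarray        # (L,) uint8 — D[root], for the virtual root edge
    n_columns: int
    tip_masks: dict[int, np.ndarray] = None  # pendant edge id -> tip state row


def _check_rows(tree: BackboneTree, rows: Mapping[str, str]) -> int:
    missing = [t for t in tree.tip_labels if t not in rows]
    if missing:
        raise PlacementError(f"alignment rows missing for tips: {missing}")
    widths = {len(rows[t]) for t in tree.tip_labels}
    if len(widths) != 1:
        raise PlacementError(f"ragged alignment rows: widths {sorted(widths)}")
    return widths.pop()


def build_fitch_index(tree: BackboneTree, rows: Mapping[str, str]) -> FitchIndex:
    """Down- and up-pass Fitch sets over all columns, vectorised per node."""
    L = _check_rows(tree, rows)
    D: dict[int, np.ndarray] = {}
    cost_down: dict[int, int] = {}
    for node in reversed(tree.nodes):  # postorder
        nid = tree.node_id[id(node)]
        if node.is_leaf():
            D[nid] = encode_alignment_row(rows[node.taxon.label])
            cost_down[nid] = 0
        else:
            children = node.child_nodes()
            a, b = (tree.node_id[id(c)] for c in children)
            inter = D[a] & D[b]
            empty = inter == 0
            D[nid] = np.where(empty, D[a] | D[b], inter)
            cost_down[nid] = cost_down[a] + cost_down[b] + int(empty.sum())
    base = cost_down[0]

    R: dict[int, np.ndarray] = {}
    cost_up: dict[int, int] = {}
    for node in tree.nodes[1:]:  # preorder, skipping root
        nid = tree.node_id[id(node)]
        parent = node.parent_node
        pid = tree.node_id[id(parent)]
        siblings = [c for c in parent.child_nodes() if c is not node]
        sid = tree.node_id[id(siblings[0])]
        if parent is tree.root:
            R[nid] = D[sid]
            cost_up[nid] = cost_down[sid]
        else:
            inter = R[pid] & D[sid]
            empty = inter == 0
            R[nid] = np.where(empty, R[pid] | D[sid], inter)
            cost_up[nid] = cost_up[pid] + cost_down[sid] + int(empty.sum())

    edge_sets = np.empty((tree.n_edges, L), dtype=np.uint8)
    for eid, node in enumerate(tree.edge_nodes):
        nid = tree.node_id[id(node)]
        inter = D[nid] & R[nid]
        empty = inter == 0
        edge_sets[eid] = np.where(empty, D[nid] | R[nid], inter)
        # consistency: cd + cu + penalty reconstructs the base score
        total = cost_down[nid] + cost_up[nid] + int(empty.sum())
        if total != base:
            raise AssertionError("Fitch up/down decomposition inconsistent")
    tip_masks = {eid: D[tree.node_id[id(node)]]
                 for eid, node in enumerate(tree.edge_nodes) if node.is_leaf()}
    return FitchIndex(backbone=tree, base_score=base, edge_sets=edge_sets,
                      root_set=D[0], n_columns=L, tip_masks=tip_masks)


def fitch_parsimony_score(tree: BackboneTree, rows: Mapping[str, str]) -> int:
    """Total Fitch changes over all columns for the tree's tips."""
    L = _check_rows(tree, rows)
    score = 0
    stack_sets: dict[int, np.ndarray] = {}
    for node in reversed(tree.nodes):
        nid = tree.node_id[id(node)]
        if node.is_leaf():
            stack_sets[nid] = encode_alignment_row(rows[node.taxon.label])
        else:
            a, b = (tree.node_id[id(c)] for c in node.child_nodes())
            inter = stack_sets[a] & stack_sets[b]
            empty = inter == 0
            stack_sets[nid] = np.where(empty, stack_sets[a] | stack_sets[b], inter)
            score += int(empty.sum())
    return score


@dataclass(frozen=True)
class Placement:
    query_id: str
    best_edge_id: int          # ROOT_EDGE (-1) = attached above the root
    parsimony_score: int
    score_margin: int          # second-best minus best score (>= 0)
    tie_count: int
    unplaceable: bool = False


def place_query(index: FitchIndex, query_id: str, query_row: str) -> Placement:
    """Attach one aligned query to its minimum-parsimony edge.

    Tie-breaking: a query that is identical to a reference tip (compatible
    state-by-state, with N/'-' wildcards) is placed on that tip's pendant
    edge whenever it is among the optima — equally parsimonious rootward
    attachments must not eject an exact reference match onto a clade stem.
    All other ties resolve to the edge closest to the root (the virtual root
    edge is root-most), then to the smallest edge id.
    """
    if len(query_row) != index.n_columns:
        raise PlacementError(
            f"query row width {len(query_row)} != alignment width {index.n_columns}")
    q = encode_alignment_row(query_row)
    if (q == 15).all():
        return Placement(query_id=query_id, best_edge_id=ROOT_EDGE,
                         parsimony_score=index.base_score, score_margin=0,
                         tie_count=index.backbone.n_edges + 1, unplaceable=True)
    pens = ((index.edge_sets & q) == 0).sum(axis=1)
    root_pen = int((((index.root_set & q) == 0)).sum())
    best_pen = min(int(pens.min()), root_pen)
    ties = [ROOT_EDGE] if root_pen == best_pen else []
    ties += [int(e) for e in np.nonzero(pens == best_pen)[0]]
    all_pens = np.concatenate(([root_pen], pens))
    second = int(np.partition(all_pens, 1)[1]) if all_pens.size > 1 else best_pen
    exact = [e for e in ties
             if e != ROOT_EDGE and e in index.tip_masks
             and bool(((index.tip_masks[e] & q) != 0).all())]
    if exact:
        best_edge = min(exact)
    else:
        best_edge = min(ties, key=lambda e: (
            0 if e == ROOT_EDGE else index.backbone.edge_depth[e], e))
    return Placement(query_id=query_id, best_edge_id=best_edge,
                     parsimony_score=index.base_score + best_pen,
                     score_margin=second - best_pen,
                     tie_count=len(ties))


def place_batch(index: FitchIndex, queries: Iterable[tuple[str, str]],
                batch_size: int = 500) -> tuple[list[Placement], list[str]]:
    """Place queries independently, emitting one audit tree per batch.

    Batching affects only audit-tree emission, never the placements.
    Returns (placements, audit newick strings).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    queries = list(queries)
    placements = [place_query(index, qid, row) for qid, row in queries]
    audit_trees = []
    for start in range(0, len(queries), batch_size):
        batch = placements[start:start + batch_size]
        audit_trees.append(_audit_newick(index.backbone, batch))
    return placements, audit_trees


def _audit_newick(backbone: BackboneTree, placements: Sequence[Placement]) -> str:
    """Newick of the backbone with each batch query grafted at its best edge."""
    tree = backbone.tree.clone(depth=1)
    # original preorder node references; edge k subtends original_nodes[k + 1]
    original_nodes = list(tree.preorder_node_iter())
    taxa = tree.taxon_namespace
    for p in placements:
        if p.unplaceable:
            continue
        leaf = dendropy.Node()
        leaf.taxon = taxa.new_taxon(p.query_id)
        if p.best_edge_id == ROOT_EDGE:
            old_root = tree.seed_node
            new_root = dendropy.Node()
            new_root.add_child(old_root)
            new_root.add_child(leaf)
            tree.seed_node = new_root
        else:
            child = original_nodes[p.best_edge_id + 1]
            parent = child.parent_node
            mid = dendropy.Node()
            parent.remove_child(child)
            mid.add_child(child)
            mid.add_child(leaf)
            parent.add_child(mid)
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def write_jplace(index: FitchIndex, placements: Sequence[Placement],
                 path: str | Path) -> None:
    """Write placements in jplace-style JSON with edge-numbered tree."""
    doc = {
        "version": 3,
        "tree": index.backbone.newick(edge_numbers=True),
        "fields": ["edge_num", "parsimony_score", "score_margin", "tie_count"],
        "placements": [
            {"p": [[p.best_edge_id, p.parsimony_score, p.score_margin, p.tie_count]],
             "n": [p.query_id]}
            for p in placements if not p.unplaceable
        ],
        "metadata": {
            "placer": "internal-fitch-parsimony",
            "base_parsimony_score": index.base_score,
            "unplaceable": [p.query_id for p in placements if p.unplaceable],
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
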