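"""Independent reference implementations used only to check the package.

These deliberately share no code with the implementation: trees are nested
tuples, Fitch is per-column set recursion, and clade membership is tip-set
containment. Slow but obviously correct on small instances.
"""

from __future__ import annotations

from amf_lsu.placement import ROOT_EDGE, BackboneTree

_MASKS = {"A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}}


def char_states(ch: str) -> frozenset[str]:
    return frozenset(_MASKS.get(ch.upper(), {"A", "C", "G", "T"}))


# --- nested-tuple trees -----------------------------------------------------
# leaf: ("L", name, edge_id); internal: ("I", left, right, edge_id)
# edge_id is the id of the edge above the node (None for the root).

def to_tuples(backbone: BackboneTree):
    def conv(node):
        eid = None if node is backbone.root else backbone._edge_id_of_node(node)
        if node.is_leaf():
            return ("L", node.taxon.label, eid)
        children = node.child_nodes()
        assert len(children) == 2, "oracle expects binary trees"
        return ("I", conv(children[0]), conv(children[1]), eid)
    return conv(backbone.root)


def insert_at_edge(node, edge_id: int, leaf_name: str):
    """New tree with a leaf attached on the given edge (ROOT_EDGE = above root)."""
    if edge_id == ROOT_EDGE:
        return ("I", node, ("L", leaf_name, None), None)

    def walk(n):
        if n[-1] == edge_id:
            return ("I", n, ("L", leaf_name, None), None), True
        if n[0] == "L":
            return n, False
        left, hit = walk(n[1])
        if hit:
            return ("I", left, n[2], n[3]), True
        right, hit = walk(n[2])
        return ("I", n[1], right, n[3]), hit

    out, hit = walk(node)
    assert hit, f"edge {edge_id} not found"
    return out


def iter_edges(node):
    if node[-1] is not None:
        yield node[-1]
    if node[0] == "I":
        yield from iter_edges(node[1])
        yield from iter_edges(node[2])


def tip_set(node) -> frozenset[str]:
    if node[0] == "L":
        return frozenset([node[1]])
    return tip_set(node[1]) | tip_set(node[2])


# --- naive Fitch ------------------------------------------------------------

def fitch_column(node, states: dict[str, frozenset[str]]):
    """(state set, changes) for one column by textbook Fitch recursion."""
    if node[0] == "L":
        return states[node[1]], 0
    s1, c1 = fitch_column(node[1], states)
    s2, c2 = fitch_column(node[2], states)
    inter = s1 & s2
    if inter:
        return inter, c1 + c2
    return s1 | s2, c1 + c2 + 1


def naive_fitch_score(node, rows: dict[str, str]) -> int:
    width = len(next(iter(rows.values())))
    total = 0
    for j in range(width):
        states = {name: char_states(row[j]) for name, row in rows.items()}
        total += fitch_column(node, states)[1]
    return total


def naive_place(backbone: BackboneTree, ref_rows: dict[str, str],
                query_id: str, query_row: str):
    """Exhaustive minimum-parsimony attachment over every candidate edge.

    Returns (best_edge, best_score, tie_count, margin) with the same
    tie-break convention as the package: a tied pendant edge whose tip is
    state-compatible with the query at every column wins (smallest edge id
    among such); otherwise smallest depth (root edge depth 0), then smallest
    edge id.
    """
    base = to_tuples(backbone)
    rows = dict(ref_rows)
    rows[query_id] = query_row
    candidates = [ROOT_EDGE] + list(range(backbone.n_edges))
    scores = {}
    for eid in candidates:
        aug = insert_at_edge(base, eid, query_id)
        scores[eid] = naive_fitch_score(aug, rows)
    best = min(scores.values())
    ties = [e for e in candidates if scores[e] == best]

    def compatible_tip(e: int) -> bool:
        if e == ROOT_EDGE:
            return False
        label = backbone.edge_label(e)
        if label is None:
            return False
        tip_row = ref_rows[label]
        return all(char_states(a) & char_states(b)
                   for a, b in zip(tip_row, query_row))

    exact = [e for e in ties if compatible_tip(e)]
    depth = lambda e: 0 if e == ROOT_EDGE else backbone.edge_depth[e]
    best_edge = min(exact) if exact else min(ties, key=lambda e: (depth(e), e))
    second = sorted(scores.values())[1] if len(scores) > 1 else best
    return best_edge, best, len(ties), second - best


# --- brute-force clade membership ------------------------------------------

def brute_member_edges(backbone: BackboneTree, defining_tips: set[str]) -> set[int]:
    """Edges strictly inside the smallest subtree containing the tips.

    The MRCA subtree is found as the smallest tip set (over all edges plus
    the whole tree) containing the defining tips; member edges are the edges
    whose own subtree tips are a subset of it, excluding the stem edge.
    """
    base = to_tuples(backbone)

    def subtrees(node):
        yield node
        if node[0] == "I":
            yield from subtrees(node[1])
            yield from subtrees(node[2])

    best_node = None
    for node in subtrees(base):
        ts = tip_set(node)
        if defining_tips <= ts:
            if best_node is None or len(ts) < len(tip_set(best_node)):
                best_node = node
    assert best_node is not None
    members = set()
    for node in subtrees(best_node):
        if node is best_node:
            continue
        if node[-1] is not None:
            members.add(node[-1])
    return members
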