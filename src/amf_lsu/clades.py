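"""Clade definition and classification of placements.

The Glomeromycota (AMF) clade and the 11 described family clades are each
delimited by the MRCA of their defining reference tips in the rooted
backbone tree; a clade's member edges are every edge strictly inside the
MRCA's subtree. The stem edge (the branch subtending the MRCA) is excluded
by default: a query attaching there may be sister to the clade rather than
inside it, so counting it as a member would over-claim — `include_stem=True`
flips this for sensitivity analysis.

A placement is AMF iff its edge is an AMF member edge; its family is the
smallest named family clade containing the edge, or "Glomeromycota
_unclassified" for AMF edges between family clades. The virtual root edge is
outside every clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .cluster import FeatureTable
from .placement import ROOT_EDGE, BackboneTree, Placement

AMF_CLADE = "Glomeromycota"
UNCLASSIFIED_AMF = "Glomeromycota_unclassified"


class CladeError(ValueError):
    pass


def root_tree(tree: dendropy.Tree, outgroup_tip: str) -> dendropy.Tree:
    """(Re)root a tree on the pendant edge of the designated outgroup tip.

    Idempotent: a tree already rooted with the outgroup as one child of the
    root is returned unchanged (topologically).
    """
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup_tip:
            leaf = lf
            break
    if leaf is None:
        raise CladeError(f"outgroup tip {outgroup_tip!r} not found in tree")
    root_children = tree.seed_node.child_nodes()
    if leaf in root_children and len(root_children) == 2:
        return tree
    edge = leaf.edge
    if edge.length is not None and edge.length > 0:
        tree.reroot_at_edge(edge, length1=edge.length / 2.0,
                            length2=edge.length / 2.0,
                            update_bipartitions=False)
    else:
        tree.reroot_at_edge(edge, update_bipartitions=False)
    tree.suppress_unifurcations()
    return tree


@dataclass(frozen=True)
class CladeEntry:
    name: str
    defining_tips: frozenset[str]
    mrca_edge_id: int              # stem edge of the clade's MRCA
    member_edges: frozenset[int]   # edges strictly inside the MRCA subtree


def define_clade(backbone: BackboneTree, defining_tip_ids: Sequence[str],
                 name: str) -> CladeEntry:
    """Delimit a named clade by the MRCA of its defining tips."""
    tips = list(dict.fromkeys(defining_tip_ids))
    if len(tips) < 2:
        raise CladeError(f"clade {name!r} needs >= 2 defining tips, got {len(tips)}")
    known = set(backbone.tip_labels)
    unknown = [t for t in tips if t not in known]
    if unknown:
        raise CladeError(f"clade {name!r} defining tips absent from tree: {unknown}")
    taxa = backbone.tree.taxon_namespace
    mrca = backbone.tree.mrca(taxa=[taxa.get_taxon(t) for t in tips])
    member = set()
    for node in mrca.preorder_iter():
        if node is mrca:
            continue
        member.add(backbone._edge_id_of_node(node))
    mrca_edge = (backbone._edge_id_of_node(mrca)
                 if mrca is not backbone.root else ROOT_EDGE)
    return CladeEntry(name=name, defining_tips=frozenset(tips),
                      mrca_edge_id=mrca_edge, member_edges=frozenset(member))


@dataclass
class CladeModel:
    """The AMF clade and its family clades resolved to edge sets."""

    backbone: BackboneTree
    amf: CladeEntry
    families: dict[str, CladeEntry]
    include_stem: bool = False

    @property
    def family_names(self) -> list[str]:
        return sorted(self.families)

    def _members(self, entry: CladeEntry) -> frozenset[int]:
        if self.include_stem and entry.mrca_edge_id != ROOT_EDGE:
            return entry.member_edges | {entry.mrca_edge_id}
        return entry.member_edges

    @classmethod
    def from_family_map(cls, backbone: BackboneTree, family_map: pd.DataFrame,
                        *, amf_families: Iterable[str] | None = None,
                        include_stem: bool = False) -> "CladeModel":
        """Build the model from the reference family map.

        ``amf_families`` restricts which group labels count as AMF families;
        by default the map's ``is_amf`` column (truthy values) decides, and
        failing that every group label with >= 2 tips in the tree is a family.
        """
        fam = family_map.copy()
        present = set(backbone.tip_labels)
        fam = fam[fam["id"].isin(present)]
        if amf_families is not None:
            fam_names = [f for f in amf_families]
        elif "is_amf" in fam.columns and fam["is_amf"].astype(str).str.strip().str.len().gt(0).any():
            truthy = {"1", "true", "yes", "amf"}
            fam_names = sorted(fam.loc[
                fam["is_amf"].astype(str).str.strip().str.lower().isin(truthy),
                "group_label"].unique())
        else:
            fam_names = sorted(fam["group_label"].unique())
        families = {}
        amf_tips: list[str] = []
        for name in fam_names:
            tips = list(fam.loc[fam["group_label"] == name, "id"])
            amf_tips.extend(tips)
            if len(tips) >= 2:
                families[name] = define_clade(backbone, tips, name)
        if len(amf_tips) < 2:
            raise CladeError("fewer than 2 AMF reference tips in the tree")
        amf = define_clade(backbone, amf_tips, AMF_CLADE)
        return cls(backbone=backbone, amf=amf, families=families,
                   include_stem=include_stem)


@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    is_amf: bool
    family: str | None  # family name, UNCLASSIFIED_AMF, or None (non-AMF)

    def __post_init__(self) -> None:
        if self.family is not None and not self.is_amf:
            raise ValueError("family label requires is_amf")


def classify_placement(placement: Placement, model: CladeModel) -> CladeAssignment:
    """Assign a placement to AMF / a family / unclassified-AMF / non-AMF."""
    edge = placement.best_edge_id
    if edge != ROOT_EDGE and not 0 <= edge < model.backbone.n_edges:
        raise CladeError(f"unknown edge id {edge}")
    if placement.unplaceable or edge == ROOT_EDGE:
        return CladeAssignment(placement.query_id, False, None)
    if edge not in model._members(model.amf):
        return CladeAssignment(placement.query_id, False, None)
    containing = [f for f in model.families.values()
                  if edge in model._members(f)]
    if not containing:
        return CladeAssignment(placement.query_id, True, UNCLASSIFIED_AMF)
    smallest = min(containing, key=lambda f: (len(f.member_edges), f.name))
    return CladeAssignment(placement.query_id, True, smallest.name)


@dataclass
class ExtractedTables:
    amf: FeatureTable
    families: dict[str, FeatureTable]
    unclassified_amf: FeatureTable
    non_amf: FeatureTable


def extract_tables(table: FeatureTable, assignments: Sequence[CladeAssignment],
                   model: CladeModel) -> ExtractedTables:
    """Partition a feature table by clade assignment.

    Features without an assignment (screened out or unplaceable) are
    non-AMF. Family tables partition the family-assigned features; the AMF
    table is their union plus unclassified-AMF features. Counts per feature
    are never altered.
    """
    by_id = {a.query_id: a for a in assignments}
    amf_ids, non_ids, uncls_ids = [], [], []
    fam_ids: dict[str, list[str]] = {f: [] for f in model.family_names}
    for fid in table.feature_ids:
        a = by_id.get(fid)
        if a is None or not a.is_amf:
            non_ids.append(fid)
            continue
        amf_ids.append(fid)
        if a.family == UNCLASSIFIED_AMF or a.family is None:
            uncls_ids.append(fid)
        else:
            fam_ids.setdefault(a.family, []).append(fid)
    return ExtractedTables(
        amf=table.subset(amf_ids),
        families={f: table.subset(ids) for f, ids in fam_ids.items()},
        unclassified_amf=table.subset(uncls_ids),
        non_amf=table.subset(non_ids))


def summarize_fractions(assignments: Sequence[CladeAssignment],
                        table: FeatureTable) -> pd.DataFrame:
    """Per-family % of AMF features and % of AMF reads.

    Percentages are computed over AMF-assigned features only; the
    unclassified bucket absorbs the remainder, so each metric sums to 100
    (or to 0 when no feature is AMF).
    """
    totals = table.feature_totals()
    amf = [a for a in assignments if a.is_amf and a.query_id in totals.index]
    n_features = len(amf)
    n_reads = int(sum(totals[a.query_id] for a in amf))
    rows = []
    fams = sorted({a.family for a in amf if a.family})
    for fam in fams:
        members = [a.query_id for a in amf if a.family == fam]
        reads = int(sum(totals[m] for m in members))
        rows.append({
            "clade": fam,
            "n_features": len(members),
            "n_reads": reads,
            "pct_features": 100.0 * len(members) / n_features if n_features else 0.0,
            "pct_reads": 100.0 * reads / n_reads if n_reads else 0.0,
        })
    return pd.DataFrame(rows, columns=["clade", "n_features", "n_reads",
                                       "pct_features", "pct_reads"])


def write_extracted(tables: ExtractedTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables.amf.write_tsv(outdir / "amf.tsv")
    tables.amf.write_fasta(outdir / "amf.fasta")
    tables.unclassified_amf.write_tsv(outdir / "unclassified_amf.tsv")
    tables.unclassified_amf.write_fasta(outdir / "unclassified_amf.fasta")
    tables.non_amf.write_tsv(outdir / "non_amf.tsv")
    tables.non_amf.write_fasta(outdir / "non_amf.fasta")
    for fam, t in tables.families.items():
        safe = fam.replace("/", "_").replace(" ", "_")
        t.write_tsv(outdir / f"family_{safe}.tsv")
        t.write_fasta(outdir / f"family_{safe}.fasta")
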