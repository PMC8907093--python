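"""Synthetic fixtures: reference tree, family-labelled sequences, reads.

Generates a fully self-contained analog of an LSU amplicon study design:
a rooted binary reference tree whose ingroup is organised into labelled,
disjoint "family" clades (mirroring the 11 described Glomeromycota
families) with outgroup tips outside the ingroup; reference sequences
evolved along the tree under Jukes–Cantor substitution; study read pairs
derived from chosen tips with additional divergence; and non-homologous
junk reads (i.i.d. uniform nucleotides) that emulate the off-target
artifacts real datasets contain. A truth table records each query's origin
tip, family, and AMF status so every pipeline stage can be scored against
known labels.

All randomness flows from a single integer seed; fixtures are byte-identical
across reruns.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .iupac import revcomp
from .refdb import DEFAULT_FLR2, DEFAULT_LROR, PrimerPair

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for a synthetic fixture.

    Defaults emulate a compact version of the reference database this kind
    of pipeline runs against: an ingroup of 60 AMF tips in 11 family clades
    plus 20 outgroup tips over a 600 bp inter-primer region, 150 bp paired
    reads, queries at 2% divergence from their origin tip, and 15 junk reads.
    """

    n_amf_tips: int = 60
    n_families: int = 11
    n_outgroup_tips: int = 20
    region_length: int = 600
    substitution_rate: float = 0.05
    r1_len: int = 150
    r2_len: int = 150
    query_divergence: float = 0.02
    n_queries: int = 100
    n_junk_reads: int = 15
    seed: int = 0
    with_primers: bool = True

    def __post_init__(self) -> None:
        if self.n_amf_tips < 2 * self.n_families:
            raise ValueError("need >= 2 AMF tips per family")
        if self.n_outgroup_tips < 1:
            raise ValueError("need at least one outgroup tip (the root)")
        if not 0 <= self.substitution_rate < 0.75 or not 0 <= self.query_divergence < 0.75:
            raise ValueError("rates must be in [0, 0.75)")
        if self.r1_len + self.r2_len > self.region_length:
            raise ValueError("r1_len + r2_len must not exceed region_length")


def simulate_tree(n_tips: int, seed: int, *, labels: Sequence[str] | None = None,
                  mean_branch_length: float = 1.0) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths.

    Topology is built by repeatedly joining two uniformly chosen lineages
    (a Yule-like coalescent in reverse); deterministic for a given seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(n_tips)]
    elif len(labels) != n_tips:
        raise ValueError("len(labels) != n_tips")
    taxa = dendropy.TaxonNamespace()
    lineages = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(lab)
        node.edge.length = float(rng.exponential(mean_branch_length))
        lineages.append(node)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        parent.edge.length = float(rng.exponential(mean_branch_length))
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    root = lineages[0]
    root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return tree


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability p (Jukes–Cantor:
    a substituted site takes one of the three other bases uniformly)."""
    if p <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p
    if hit.any():
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        base_idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(base_idx + shifts) % 4]
    return "".join(arr)


def evolve_sequences(tree: dendropy.Tree, root_seq: str, rate: float,
                     seed: int) -> dict[str, str]:
    """Evolve a root sequence to the tips under per-branch substitution.

    The per-branch substitution probability is rate * branch_length (capped
    at 0.75, the Jukes–Cantor saturation limit).
    """
    if any(c not in "ACGT" for c in root_seq):
        raise ValueError("root sequence must be over ACGT")
    rng = np.random.default_rng(seed)
    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length if node.edge.length is not None else 1.0
        p = min(rate * bl, 0.75)
        seqs[id(node)] = mutate(seqs[id(node.parent_node)], p, rng)
        if node.is_leaf():
            out[node.taxon.label] = seqs[id(node)]
    return out


@dataclass
class Fixture:
    """A complete synthetic study: references, tree, queries, junk, truth."""

    config: SimConfig
    primer_pair: PrimerPair
    reference_raw: dict[str, str]      # id -> primered raw sequence
    reference_regions: dict[str, str]  # id -> clean inter-primer region
    family_map: pd.DataFrame           # id, group_label, taxon, accession, is_amf
    tree: dendropy.Tree
    newick: str
    queries: list[dict] = field(default_factory=list)
    junk_reads: list[dict] = field(default_factory=list)
    outgroup_root_tip: str = ""

    def truth(self) -> pd.DataFrame:
        rows = [{"query_id": q["id"], "origin_tip": q["origin_tip"],
                 "family": q["family"], "is_amf": q["is_amf"]}
                for q in self.queries]
        rows += [{"query_id": j["id"], "origin_tip": "", "family": "",
                  "is_amf": False} for j in self.junk_reads]
        return pd.DataFrame(rows, columns=["query_id", "origin_tip", "family", "is_amf"])

    def read_pairs(self) -> list[tuple[str, str, str]]:
        """(id, r1, r2) for all study reads, queries first then junk."""
        return ([(q["id"], q["r1"], q["r2"]) for q in self.queries]
                + [(j["id"], j["r1"], j["r2"]) for j in self.junk_reads])

    # ---- file emission ---------------------------------------------------
    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference_fasta": outdir / "reference.fasta",
            "family_map": outdir / "family_map.tsv",
            "tree": outdir / "backbone.nwk",
            "r1_fastq": outdir / "reads_R1.fastq",
            "r2_fastq": outdir / "reads_R2.fastq",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["reference_fasta"], "w") as fh:
            for rid, seq in self.reference_raw.items():
                fh.write(f">{rid}\n{seq}\n")
        self.family_map.to_csv(paths["family_map"], sep="\t", index=False)
        paths["tree"].write_text(self.newick + "\n")
        with open(paths["r1_fastq"], "w") as f1, open(paths["r2_fastq"], "w") as f2:
            for rid, r1, r2 in self.read_pairs():
                f1.write(f"@{rid}\n{r1}\n+\n{'F' * len(r1)}\n")   # Q37
                f2.write(f"@{rid}\n{r2}\n+\n{'F' * len(r2)}\n")
        self.truth().to_csv(paths["truth"], sep="\t", index=False)
        return paths


_FAMILY_NAMES = [
    "Acaulosporaceae", "Ambisporaceae", "Archaeosporaceae",
    "Claroideoglomeraceae", "Diversisporaceae", "Gigasporaceae",
    "Glomeraceae", "Pacisporaceae", "Paraglomeraceae",
    "Pervetustaceae", "Sacculosporaceae",
]


def _partition_tips(n_tips: int, n_groups: int, rng: np.random.Generator) -> list[int]:
    """Split n_tips into n_groups parts of size >= 2, randomly."""
    sizes = [2] * n_groups
    for _ in range(n_tips - 2 * n_groups):
        sizes[int(rng.integers(0, n_groups))] += 1
    return sizes


def _join_subtrees(roots: list[dendropy.Node], rng: np.random.Generator,
                   mean_bl: float) -> dendropy.Node:
    roots = list(roots)
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(roots[i])
        parent.add_child(roots[j])
        parent.edge.length = float(rng.exponential(mean_bl))
        roots = [r for k, r in enumerate(roots) if k not in (i, j)] + [parent]
    return roots[0]


def make_fixture(config: SimConfig) -> Fixture:
    """Build the full synthetic study from a config (deterministic per seed).

    Tree shape: each family is a random binary subtree; families join into
    the AMF (ingroup) clade; outgroup tips join into an outgroup clade; the
    last outgroup tip is the designated root outgroup, sister to everything
    else. Family clades are therefore disjoint by construction.
    """
    rng = np.random.default_rng(config.seed)
    mean_bl = 1.0

    fam_names = (_FAMILY_NAMES[:config.n_families]
                 if config.n_families <= len(_FAMILY_NAMES)
                 else [f"Family{i + 1}" for i in range(config.n_families)])
    sizes = _partition_tips(config.n_amf_tips, config.n_families, rng)
    taxa = dendropy.TaxonNamespace()

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label)
        node.edge.length = float(rng.exponential(mean_bl))
        return node

    tip_family: dict[str, str] = {}
    fam_roots = []
    tip_no = 0
    for fam, size in zip(fam_names, sizes):
        leaves = []
        for _ in range(size):
            tip_no += 1
            lab = f"AMF_{tip_no:03d}"
            tip_family[lab] = fam
            leaves.append(leaf(lab))
        sub = _join_subtrees(leaves, rng, mean_bl)
        fam_roots.append(sub)
    amf_root = _join_subtrees(fam_roots, rng, mean_bl)

    out_labels = [f"OUT_{i + 1:03d}" for i in range(config.n_outgroup_tips)]
    root_out = out_labels[-1]
    near_outs = [leaf(lab) for lab in out_labels[:-1]]
    if near_outs:
        out_root = _join_subtrees(near_outs, rng, mean_bl)
        ingroup = dendropy.Node()
        ingroup.add_child(amf_root)
        ingroup.add_child(out_root)
        ingroup.edge.length = float(rng.exponential(mean_bl))
    else:
        ingroup = amf_root
    root = dendropy.Node()
    root.add_child(ingroup)
    root.add_child(leaf(root_out))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root

    root_seq = random_sequence(config.region_length, rng)
    regions = evolve_sequences(tree, root_seq, config.substitution_rate,
                               int(rng.integers(0, 2**31 - 1)))

    primers = PrimerPair()
    raw = {}
    for rid, region in regions.items():
        raw[rid] = (DEFAULT_LROR + region + revcomp(DEFAULT_FLR2)
                    if config.with_primers else region)

    fam_rows = []
    for lab in regions:
        is_amf = lab.startswith("AMF_")
        fam_rows.append({
            "id": lab,
            "group_label": tip_family.get(lab, "Outgroup"),
            "taxon": (f"{tip_family[lab]} sp. {lab}" if is_amf
                      else f"Outgroup sp. {lab}"),
            "accession": f"SYN{zlib.crc32(lab.encode()) % 10**6:06d}",
            "is_amf": "1" if is_amf else "0",
        })
    family_map = pd.DataFrame(fam_rows)

    all_tips = list(regions)
    queries = []
    for i in range(config.n_queries):
        origin = all_tips[int(rng.integers(0, len(all_tips)))]
        mutated = mutate(regions[origin], config.query_divergence, rng)
        r1 = mutated[:config.r1_len]
        r2 = revcomp(mutated[-config.r2_len:])
        if config.with_primers:
            r1 = DEFAULT_LROR + r1
            r2 = DEFAULT_FLR2 + r2
        queries.append({
            "id": f"Q{i + 1:04d}", "origin_tip": origin,
            "family": tip_family.get(origin, ""),
            "is_amf": origin.startswith("AMF_"),
            "r1": r1, "r2": r2,
        })

    junk = []
    for i in range(config.n_junk_reads):
        r1 = random_sequence(config.r1_len, rng)
        r2 = random_sequence(config.r2_len, rng)
        if config.with_primers:
            r1 = DEFAULT_LROR + r1
            r2 = DEFAULT_FLR2 + r2
        junk.append({"id": f"JUNK{i + 1:04d}", "r1": r1, "r2": r2})

    newick = tree.as_string(schema="newick", suppress_rooting=True,
                            unquoted_underscores=True).strip()
    return Fixture(config=config, primer_pair=primers, reference_raw=raw,
                   reference_regions=dict(regions), family_map=family_map,
                   tree=tree, newick=newick, queries=queries, junk_reads=junk,
                   outgroup_root_tip=root_out)
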