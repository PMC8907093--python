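"""Feature tables, dereplication, greedy OTU clustering and ASV passthrough.

After read cleaning and merging, study sequences are summarised as a feature
table (features x samples, integer counts, one representative sequence per
feature). Features can stay as exact amplicon sequence variants (ASVs) or be
clustered into OTUs by the classic greedy centroid algorithm: process
dereplicated sequences in decreasing abundance; each sequence joins the
first existing centroid whose end-to-end global alignment identity reaches
the threshold, otherwise it founds a new cluster. Identity counts matching
columns over all alignment columns (gap columns are mismatches). At a
threshold of 1.0 the clustering degenerates to the ASV table exactly.

A simplified truncate/filter/merge step stands in for a full denoising
workflow: reads are truncated to the configured lengths, pairs containing N
are dropped, and R1 + revcomp(R2) are concatenated. Externally denoised ASV
tables are accepted as input unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ScoringScheme, global_identity
from .iupac import revcomp
from .refdb import ReadPair


@dataclass
class FeatureTable:
    """Integer counts of features (OTUs/ASVs) across samples + rep sequences."""

    counts: pd.DataFrame  # features x samples, int
    rep_seqs: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        missing = [f for f in self.counts.index if f not in self.rep_seqs]
        if missing:
            raise ValueError(f"features without representative sequence: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def feature_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset(self, feature_ids: Sequence[str]) -> "FeatureTable":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return FeatureTable(counts=self.counts.loc[keep].copy(),
                            rep_seqs={f: self.rep_seqs[f] for f in keep})

    def drop_empty_features(self) -> "FeatureTable":
        keep = self.counts.index[self.counts.sum(axis=1) > 0]
        return self.subset(list(keep))

    def equals(self, other: "FeatureTable") -> bool:
        return (self.counts.equals(other.counts)
                and self.rep_seqs == other.rep_seqs)

    # ---- I/O -------------------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for fid in self.feature_ids:
                fh.write(f">{fid}\n{self.rep_seqs[fid]}\n")

    @classmethod
    def read(cls, tsv_path: str | Path, fasta_path: str | Path) -> "FeatureTable":
        from Bio import SeqIO
        counts = pd.read_csv(tsv_path, sep="\t", index_col=0)
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        return cls(counts=counts, rep_seqs=seqs)


@dataclass(frozen=True)
class Cluster:
    centroid_id: str
    member_ids: tuple[str, ...]
    abundance: int


def _abundance_order(table: FeatureTable) -> list[str]:
    """Descending abundance; ties by sequence then id (deterministic)."""
    totals = table.feature_totals()
    return sorted(table.feature_ids,
                  key=lambda f: (-totals[f], table.rep_seqs[f], f))


def dereplicate(records: Iterable[tuple[str, str, Mapping[str, int]]]) -> FeatureTable:
    """Collapse identical sequences, aggregating per-sample counts.

    records: iterable of (id, sequence, {sample_id: count}). The feature id of
    each unique sequence is the lexicographically smallest contributing id.
    The output table is sorted by decreasing total abundance (ties by
    sequence, then id).
    """
    by_seq: dict[str, dict] = {}
    samples: list[str] = []
    seen_samples: set[str] = set()
    for rid, seq, counts in records:
        seq = seq.upper()
        entry = by_seq.setdefault(seq, {"ids": [], "counts": {}})
        entry["ids"].append(rid)
        for s, c in counts.items():
            if s not in seen_samples:
                seen_samples.add(s)
                samples.append(s)
            entry["counts"][s] = entry["counts"].get(s, 0) + int(c)
    rows = []
    rep_seqs = {}
    for seq, entry in by_seq.items():
        fid = min(entry["ids"])
        rep_seqs[fid] = seq
        rows.append((fid, entry["counts"]))
    counts = pd.DataFrame(
        [[row[1].get(s, 0) for s in samples] for row in rows],
        index=[row[0] for row in rows], columns=samples, dtype=np.int64)
    table = FeatureTable(counts=counts, rep_seqs=rep_seqs)
    order = _abundance_order(table)
    return FeatureTable(counts=table.counts.loc[order].copy(),
                        rep_seqs={f: rep_seqs[f] for f in order})


def cluster_otus(uniques: FeatureTable, identity_threshold: float = 0.97,
                 scoring: ScoringScheme | None = None) -> tuple[list[Cluster], FeatureTable]:
    """Greedy centroid OTU clustering of dereplicated features.

    Features are processed in decreasing abundance; each joins the first
    (most abundant) centroid with global identity >= threshold, else founds a
    new cluster. Cluster counts are the per-sample sums over members; the
    centroid sequence represents the cluster.
    """
    if not 0.5 <= identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in [0.5, 1.0]")
    scoring = scoring or ScoringScheme()
    order = _abundance_order(uniques)
    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for fid in order:
        seq = uniques.rep_seqs[fid]
        assigned = False
        for cid in centroids:
            if identity_threshold >= 1.0:
                ident = 1.0 if seq == uniques.rep_seqs[cid] else 0.0
            else:
                ident = global_identity(seq, uniques.rep_seqs[cid], scoring)
            if ident >= identity_threshold:
                members[cid].append(fid)
                assigned = True
                break
        if not assigned:
            centroids.append(fid)
            members[fid] = [fid]

    totals = uniques.feature_totals()
    clusters = [Cluster(centroid_id=cid, member_ids=tuple(members[cid]),
                        abundance=int(sum(totals[m] for m in members[cid])))
                for cid in centroids]
    counts = pd.DataFrame(
        [uniques.counts.loc[members[cid]].sum(axis=0) for cid in centroids],
        index=centroids)
    table = FeatureTable(counts=counts,
                         rep_seqs={cid: uniques.rep_seqs[cid] for cid in centroids})
    order2 = _abundance_order(table)
    table = FeatureTable(counts=table.counts.loc[order2].copy(),
                         rep_seqs={f: table.rep_seqs[f] for f in order2})
    return clusters, table


def asv_passthrough(uniques: FeatureTable) -> FeatureTable:
    """Keep exact sequence variants as features (identical to 100% OTUs)."""
    return FeatureTable(counts=uniques.counts.copy(), rep_seqs=dict(uniques.rep_seqs))


@dataclass
class MergeStats:
    n_input: int = 0
    n_merged: int = 0
    n_dropped_short: int = 0
    n_dropped_n: int = 0
    merged: list[tuple[str, str]] = field(default_factory=list)  # (id, sequence)


def truncate_filter_merge(pairs: Iterable[ReadPair], r1_len: int, r2_len: int) -> MergeStats:
    """Simplified quality-control and merge of primer-trimmed read pairs.

    Truncates R1/R2 to fixed lengths, drops pairs that are too short or
    contain N, then joins R1 + revcomp(R2) into one study sequence in region
    orientation. This is a deterministic stand-in for a full denoising step;
    externally denoised ASV inputs bypass it entirely.
    """
    stats = MergeStats()
    for pair in pairs:
        stats.n_input += 1
        if len(pair.r1_seq) < r1_len or len(pair.r2_seq) < r2_len:
            stats.n_dropped_short += 1
            continue
        r1 = pair.r1_seq[:r1_len].upper()
        r2 = pair.r2_seq[:r2_len].upper()
        if "N" in r1 or "N" in r2:
            stats.n_dropped_n += 1
            continue
        stats.merged.append((pair.id, r1 + revcomp(r2)))
        stats.n_merged += 1
    return stats
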