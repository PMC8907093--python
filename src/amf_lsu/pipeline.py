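"""End-to-end pipeline orchestration and the per-cycle quality report.

Stage order: primer trimming -> truncate/filter/merge -> dereplication ->
homology pre-screen -> OTU clustering or ASV passthrough -> split R1/R2
alignment -> parsimony placement -> clade extraction. A machine-readable
run manifest records parameters and the number of features surviving each
stage, so the funnel from raw reads to family tables is fully auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .align import ScoringScheme
from .clades import CladeModel, classify_placement, extract_tables, root_tree, \
    summarize_fractions, write_extracted
from .cluster import FeatureTable, asv_passthrough, cluster_otus, dereplicate, \
    truncate_filter_merge
from .iupac import revcomp
from .placement import BackboneTree, build_fitch_index, place_batch, write_jplace
from .prescreen import screen_queries
from .refdb import PrimerPair, ReadLengthCut, ReadPair, build_reference_db, \
    cut_reference_to_read_lengths, trim_read_pair, write_manifest, write_region_fasta
from .profile_align import SplitAlignment, add_queries, build_reference_alignment, \
    concatenate_blocks


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    reference_fasta: str
    family_map: str
    tree: str
    output_dir: str
    # either paired FASTQ per sample ...
    samples: dict[str, tuple[str, str]] = field(default_factory=dict)
    # ... or a pre-denoised ASV table + FASTA
    asv_table: str | None = None
    asv_fasta: str | None = None

    primer_pair: PrimerPair = field(default_factory=PrimerPair)
    r1_len: int = 150
    r2_len: int = 150
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_score: float = 40.0
    mode: str = "otu"           # "otu" | "asv"
    otu_identity: float = 0.97
    batch_size: int = 500
    include_stem: bool = False
    outgroup_tip: str | None = None
    primer_policy: str = "drop"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("otu", "asv"):
            raise ValueError("mode must be 'otu' or 'asv'")
        if not self.samples and not (self.asv_table and self.asv_fasta):
            raise ValueError("provide FASTQ samples or an ASV table + FASTA")

    @property
    def cut(self) -> ReadLengthCut:
        return ReadLengthCut(self.r1_len, self.r2_len)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "primer_pair" in raw:
            raw["primer_pair"] = PrimerPair(**raw["primer_pair"])
        if "scoring" in raw:
            raw["scoring"] = ScoringScheme(**raw["scoring"])
        if "samples" in raw:
            raw["samples"] = {k: tuple(v) for k, v in raw["samples"].items()}
        return cls(**raw)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    r1s = list(SeqIO.parse(str(r1_path), "fastq"))
    r2s = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1s) != len(r2s):
        raise ValueError(f"R1/R2 record counts differ: {len(r1s)} vs {len(r2s)}")
    pairs = []
    for a, b in zip(r1s, r2s):
        pairs.append(ReadPair(
            id=a.id, r1_seq=str(a.seq).upper(), r2_seq=str(b.seq).upper(),
            r1_qual=tuple(a.letter_annotations["phred_quality"]),
            r2_qual=tuple(b.letter_annotations["phred_quality"])))
    return pairs


def quality_profile(fastq_path: str | Path, side: str = "R1") -> pd.DataFrame:
    """Per-cycle quality summary (mean and quartiles) of a FASTQ file.

    The report is the basis for choosing the R1/R2 truncation lengths.
    """
    per_pos: list[list[int]] = []
    n_reads = 0
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        n_reads += 1
        for i, q in enumerate(rec.letter_annotations["phred_quality"]):
            if i >= len(per_pos):
                per_pos.append([])
            per_pos[i].append(q)
    rows = []
    for i, quals in enumerate(per_pos):
        arr = np.asarray(quals)
        rows.append({
            "side": side, "position": i + 1, "n": len(quals),
            "mean": float(arr.mean()),
            "q25": float(np.percentile(arr, 25)),
            "median": float(np.percentile(arr, 50)),
            "q75": float(np.percentile(arr, 75)),
        })
    df = pd.DataFrame(rows, columns=["side", "position", "n", "mean",
                                     "q25", "median", "q75"])
    if not df.empty and int(df["n"].iloc[0]) != n_reads:
        pass  # variable-length reads: later cycles cover fewer reads
    return df


def pipeline_run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    Any stage failure aborts with the stage name; outputs written so far are
    moved under ``failed/`` in the output directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pipeline_version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "parameters": {
            "r1_len": config.r1_len, "r2_len": config.r2_len,
            "min_score": config.min_score, "otu_identity": config.otu_identity,
            "batch_size": config.batch_size, "include_stem": config.include_stem,
            "scoring": vars(config.scoring) | {},
        },
        "stages": {},
    }
    stage = "init"
    try:
        # --- reference curation ------------------------------------------
        stage = "refdb"
        db = build_reference_db(config.reference_fasta, config.family_map,
                                config.primer_pair)
        config.cut.validate_against(db.target_region_length)
        write_region_fasta(db, outdir / "reference_region.fasta")
        write_manifest(db, outdir / "reference_manifest.json")
        manifest["stages"]["refdb"] = db.summary()

        # --- study input --------------------------------------------------
        if config.samples:
            stage = "trim"
            per_sample_merged: dict[str, list[tuple[str, str]]] = {}
            n_pairs = n_trimmed = n_merged = 0
            for sample, (p1, p2) in sorted(config.samples.items()):
                pairs = read_fastq_pairs(p1, p2)
                trimmed = trim_read_pair(pairs, config.primer_pair,
                                         policy=config.primer_policy)
                stage = "filter_merge"
                merged = truncate_filter_merge(trimmed.pairs,
                                               config.r1_len, config.r2_len)
                per_sample_merged[sample] = merged.merged
                n_pairs += trimmed.n_input
                n_trimmed += trimmed.n_trimmed
                n_merged += merged.n_merged
            manifest["stages"]["trim"] = {"n_read_pairs": n_pairs,
                                          "n_primer_trimmed": n_trimmed}
            manifest["stages"]["filter_merge"] = {"n_merged": n_merged}
            stage = "dereplicate"
            records = []
            for sample, merged in sorted(per_sample_merged.items()):
                for rid, seq in merged:
                    records.append((rid, seq, {sample: 1}))
            table = dereplicate(records)
        else:
            stage = "load_asv"
            table = FeatureTable.read(config.asv_table, config.asv_fasta)
        manifest["stages"]["dereplicate"] = {
            "n_features": len(table.feature_ids),
            "n_reads": table.total_reads()}

        # --- homology pre-screen -----------------------------------------
        stage = "screen"
        results = screen_queries(
            [(f, table.rep_seqs[f]) for f in table.feature_ids],
            db.region_seqs(), config.scoring, config.min_score)
        retained_ids = [r.query_id for r in results if r.retained]
        screened = table.subset(retained_ids)
        pd.DataFrame([{
            "query_id": r.query_id, "best_subject": r.best_subject_id or "",
            "score": r.best_score, "identity": round(r.identity, 4),
            "strand": r.strand, "retained": r.retained,
        } for r in results]).to_csv(outdir / "screen_report.tsv", sep="\t", index=False)
        screened.write_tsv(outdir / "screened.tsv")
        screened.write_fasta(outdir / "screened.fasta")
        manifest["stages"]["screen"] = {
            "n_in": len(results), "n_retained": len(retained_ids),
            "n_dropped": len(results) - len(retained_ids)}

        # --- features: OTU or ASV ----------------------------------------
        stage = "features"
        if config.mode == "otu":
            _, features = cluster_otus(screened, config.otu_identity, config.scoring)
        else:
            features = asv_passthrough(screened)
        features.write_tsv(outdir / f"{config.mode}_table.tsv")
        features.write_fasta(outdir / f"{config.mode}_seqs.fasta")
        manifest["stages"]["features"] = {
            "mode": config.mode, "n_features": len(features.feature_ids),
            "n_reads": features.total_reads()}

        # --- split alignment ---------------------------------------------
        stage = "align"
        frags = cut_reference_to_read_lengths(db, config.cut)
        r1_ref = build_reference_alignment(
            {k: v[0] for k, v in frags.items()}, config.scoring)
        r2_ref = build_reference_alignment(
            {k: revcomp(v[1]) for k, v in frags.items()}, config.scoring)
        q_r1 = [(f, features.rep_seqs[f][:config.r1_len])
                for f in features.feature_ids]
        q_r2 = [(f, features.rep_seqs[f][-config.r2_len:])
                for f in features.feature_ids]
        b1, ins1 = add_queries(r1_ref, q_r1, config.scoring)
        b2, ins2 = add_queries(r2_ref, q_r2, config.scoring)
        concat = concatenate_blocks(SplitAlignment(b1, b2))
        b1.write_fasta(outdir / "aligned_R1.fasta")
        b2.write_fasta(outdir / "aligned_R2.fasta")
        concat.write_fasta(outdir / "aligned_concat.fasta")
        pd.DataFrame(
            [{"query_id": q, "dropped_insertions_r1": ins1.get(q, 0),
              "dropped_insertions_r2": ins2.get(q, 0)}
             for f, _ in q_r1 for q in [f]]
        ).to_csv(outdir / "insertion_report.tsv", sep="\t", index=False)
        manifest["stages"]["align"] = {
            "r1_width": b1.width, "r2_width": b2.width,
            "concat_width": concat.width}

        # --- placement -----------------------------------------------------
        stage = "place"
        backbone = BackboneTree.from_newick(config.tree)
        if config.outgroup_tip:
            backbone = BackboneTree(root_tree(backbone.tree, config.outgroup_tip))
        ref_rows = {rid: concat.row(rid) for rid in backbone.tip_labels}
        index = build_fitch_index(backbone, ref_rows)
        queries = [(f, concat.row(f)) for f in features.feature_ids]
        placements, audit = place_batch(index, queries, config.batch_size)
        write_jplace(index, placements, outdir / "placements.jplace")
        (outdir / "audit_trees.nwk").write_text("\n".join(audit) + "\n" if audit else "")
        manifest["stages"]["place"] = {
            "n_placed": sum(not p.unplaceable for p in placements),
            "n_unplaceable": sum(p.unplaceable for p in placements),
            "base_parsimony_score": index.base_score}

        # --- clade extraction ---------------------------------------------
        stage = "extract"
        fam_df = pd.read_csv(config.family_map, sep="\t", dtype=str).fillna("")
        model = CladeModel.from_family_map(backbone, fam_df,
                                           include_stem=config.include_stem)
        assignments = [classify_placement(p, model) for p in placements]
        tables = extract_tables(features, assignments, model)
        write_extracted(tables, outdir)
        summary = summarize_fractions(assignments, features)
        summary.to_csv(outdir / "clade_summary.tsv", sep="\t", index=False)
        manifest["stages"]["extract"] = {
            "n_amf": len(tables.amf.feature_ids),
            "n_unclassified_amf": len(tables.unclassified_amf.feature_ids),
            "n_non_amf": len(tables.non_amf.feature_ids),
            "per_family": {f: len(t.feature_ids)
                           for f, t in tables.families.items()},
        }
    except Exception as exc:  # noqa: BLE001 - stage context matters more
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "error.txt").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc

    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
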