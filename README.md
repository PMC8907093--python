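# amf-lsu

A phylogenetic-placement pipeline for environmental sequencing of arbuscular
mycorrhizal fungi (AMF, phylum Glomeromycota) with the large-subunit (LSU,
28S) rRNA gene region.

Most AMF in environmental samples are undescribed, so database matching
discards the bulk of the data. Phylogenetic placement avoids this: any
amplicon that can be aligned is attached to a fixed, well-supported backbone
tree of curated reference sequences, and called "putative AMF" if it lands
inside the Glomeromycota clade — and assigned to one of the 11 described AMF
families (Acaulosporaceae, Ambisporaceae, Archaeosporaceae,
Claroideoglomeraceae, Diversisporaceae, Gigasporaceae, Glomeraceae,
Pacisporaceae, Paraglomeraceae, Pervetustaceae, Sacculosporaceae) if it
lands inside that family's clade. This package implements the complete
workflow for Illumina paired-end LROR/FLR2 amplicons, plus a synthetic-data
generator so every stage is testable without downloads.

## Pipeline stages

| Stage | What it does |
|---|---|
| `refdb` | Trims reference sequences in silico to the LROR–FLR2 region (both orientations, IUPAC-aware, mismatch tolerance `floor(rate·|primer|)`), pads short entries with `N` to a common region length, and cuts references to the study read lengths (first `r1` bp; last `r2` bp reverse-complemented). |
| `reads` | Primer/adaptor clipping and a per-cycle quality report for choosing truncation lengths. |
| `screen` | A permissive homology pre-screen: each study sequence is kept iff its best Smith–Waterman local score (either strand, affine gaps, default `+1/−2/−5/−2`) against *any* reference reaches `min_score` (default 40). This removes non-homologous reads that would otherwise produce spurious clusters and long branches in the tree. Seeding only orders the exact comparisons; retention equals exhaustive all-pairs DP. |
| `features` | Dereplication, then greedy centroid OTU clustering at an identity threshold (default 0.97; identity = matching columns / alignment columns, end-to-end) — or ASV passthrough, which is exactly OTU clustering at 1.0. |
| `align` | The R1 and R2 read sections cover two disjoint pieces of the LSU, so they are aligned *separately* against the read-length-cut reference alignment and only then concatenated; R1 content can never occupy R2 columns. Reference columns are frozen; query insertions are dropped and counted. |
| `place` | Each feature is attached independently to every candidate edge of the rooted backbone (including a virtual root edge) and scored by Fitch parsimony with `N`/`-` as wildcards; the minimum-score edge wins. The per-edge score is computed from precomputed up/down state sets, `score(e) = base + #{columns: edge_set(e) ∩ query = ∅}`, so placement is exact and fast. Output is jplace. |
| `extract` | The Glomeromycota clade and family clades are delimited by the MRCA of their reference tips; member edges exclude the stem branch (conservative; `--include-stem` flips this). Features are partitioned into per-family tables, unclassified-AMF, and non-AMF, with per-clade feature-% and read-% summaries. |
| `simulate` | Clade-structured reference tree with labelled family clades and outgroups, Jukes–Cantor sequence evolution, primered read pairs from chosen tips, uniform-random junk reads, and a truth table. Byte-identical under a fixed seed. |

## Worked example

Generate a synthetic study (30 AMF references in 6 family clades, 8
outgroups, 20 real queries at 2% divergence, 5 junk reads) and run the full
ASV pipeline:

```bash
amf-lsu simulate --seed 42 --out fixture --amf-tips 30 --families 6 \
    --outgroup-tips 8 --queries 20 --junk-reads 5

cat > config.yaml <<'YAML'
reference_fasta: fixture/reference.fasta
family_map: fixture/family_map.tsv
tree: fixture/backbone.nwk
output_dir: out
samples:
  S1: [fixture/reads_R1.fastq, fixture/reads_R2.fastq]
mode: asv
YAML

amf-lsu pipeline --config config.yaml
```

The command prints the per-stage funnel (abridged):

```json
"screen":   {"n_in": 25, "n_retained": 20, "n_dropped": 5},
"features": {"mode": "asv", "n_features": 20, "n_reads": 20},
"place":    {"n_placed": 20, "n_unplaceable": 0, "base_parsimony_score": 923},
"extract":  {"n_amf": 14, "n_unclassified_amf": 0, "n_non_amf": 6,
             "per_family": {"Acaulosporaceae": 0, "Ambisporaceae": 1,
                            "Archaeosporaceae": 1, "Claroideoglomeraceae": 2,
                            "Diversisporaceae": 6, "Gigasporaceae": 4}}
```

Reading the funnel: all 5 junk reads were removed by the homology screen
(25 → 20); every retained feature was placed; 14 of the 20 genuine queries
came from AMF tips and all of them landed inside the Glomeromycota clade,
distributed over their families, while the 6 outgroup-derived queries ended
up in `non_amf.tsv`. `out/` also contains the jplace placements, the split
and concatenated alignments, per-family `family_<name>.{tsv,fasta}` tables,
and `clade_summary.tsv` with feature-% and read-% per family.

Each stage is also available as an individual subcommand (`refdb build`,
`refdb cut`, `reads trim/quality`, `screen run`, `features derep|otu|asv`,
`align refblocks|queries|concat`, `place run`, `extract run`) operating on
plain FASTA/FASTQ/TSV/Newick/jplace files.

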