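# Methods

This note documents the models, algorithms and design choices behind
`amf-lsu`, in the order the pipeline runs them.

## Reference curation

Raw LSU reference sequences were historically amplified with many primer
combinations, so they start and end at different positions. Each record is
trimmed in silico to the region between the pipeline primers: the forward
primer and the reverse complement of the reverse primer are located as
fixed-length windows with at most `floor(max_error_rate · |primer|)`
incompatible positions (IUPAC codes match every base they denote; `N`
matches anything; no indels — windows are exact length, which keeps the
search deterministic and O(|seq|·|primer|)). Both strand orientations are
tried; the one locating both sites with fewest total mismatches wins and
the region is reported in forward orientation. Records in which only one or
neither primer is found are kept untrimmed and padded (a strict mode drops
them); a reverse site upstream of the forward site is a hard error, since
it indicates a malformed (e.g. chimeric or mis-assembled) entry.

Short records are padded with `N` to the database-wide region length
(default: the longest trimmed region). Padding is 5′-anchored by default —
whether real curation anchored short amplicons at the 5′ or 3′ end is not
derivable from the region definition, so the anchor is exposed as an option.

Primer defaults are the published LROR (`ACCCGCTGAACTTAAGC`) and FLR2
(`GTCGTTTAAAGCCATTACGTC`) sequences from the primer literature; they are
configuration, not constants. `max_error_rate` defaults to 0.1, the common
convention of read-trimming tools.

The *read-length cut* takes the study truncation lengths (r1, r2) and
applies them to every curated region: the first r1 bases and the last r2
bases (reverse-complemented into read orientation). After this step
references and study reads cover exactly the same sites, which is what
makes end-to-end alignment between them meaningful.

## Homology pre-screen

Sequences that are not LSU at all (chimeras, off-target amplification,
unidentifiable artifacts) must be removed before tree building; placed
anyway, they form spurious clusters on long branches. The screen computes
the Smith–Waterman optimum (affine gaps, Gotoh recurrences; a gap of length
k costs `open + (k−1)·extend`) of each study sequence against each curated
reference, on both query strands, and retains the query iff any score
reaches `min_score`.

The default scheme (+1 match, −2 mismatch, −5 open, −2 extend, `min_score`
40) means roughly "a perfect 40 bp match somewhere", a deliberately
permissive operationalisation of "any similarity": the screen is meant to
remove garbage wholesale, not to classify. `N` scores 0 against everything,
so padded reference tails neither attract nor repel alignments.

A 7-mer seed index orders the (strand, reference) pairs by shared-seed
count so homologous queries terminate after their first exact comparison;
pairs without seeds are still aligned exactly if the query has not yet been
retained. Retention is therefore identical to exhaustive all-pairs DP — the
index is purely an ordering heuristic. The DP kernel is numba-compiled;
scores are checked against an independent full-matrix Smith–Waterman
implementation in the test suite and acceptance script.

## Features: OTUs and ASVs

Dereplication aggregates identical sequences and sorts by decreasing total
abundance (ties: lexicographic sequence, then id — fixed so reruns are
bit-identical). OTU clustering is the classic greedy centroid pass: in
abundance order, each sequence joins the first centroid whose end-to-end
global alignment identity reaches the threshold, else founds a cluster.
Identity is matching columns over all alignment columns, gaps counting as
mismatches — stated explicitly because "identity" has many dialects. The
default threshold 0.97 is the field convention. At threshold 1.0 the
algorithm reduces exactly to ASV passthrough, and the test suite asserts
table equality, not just feature counts.

Denoising proper is out of scope. The built-in substitute truncates R1/R2
at the configured lengths, drops pairs containing `N`, and joins
R1 + revcomp(R2) into region orientation. Externally denoised ASV tables
are accepted unchanged.

## Split R1/R2 alignment

The R1 and R2 cuts cover two disjoint pieces of the LSU, so each is aligned
in its own block and the blocks are concatenated afterwards; by
construction R1 characters can never occupy R2 columns.

The reference side of each block is built once by progressive
sequence-to-profile alignment in input order; insertions open all-gap
columns in the existing rows. Study fragments are then aligned one at a
time against the frozen reference profile: position-specific ACGT
frequencies (gaps and N are uninformative), column score = expected match
score of the query base against the column distribution, affine gap
penalties from the shared scoring scheme. Reference columns are immutable
and query insertions are dropped and counted, which keeps every query row
independent of every other query — the property that makes placement
results invariant to batch composition.

Alignments are end-to-end (terminal gaps pay the normal cost). With the
linear expected-score profile model, free terminal gaps would make
staggered overlaps score-optimal between diverged fragments, destroying
the shared coordinate system; since the read-length cut guarantees that
reference and study fragments span the same region, end-to-end is the
correct model, and genuinely shorter fragments simply pay for the columns
they miss.

## Parsimony placement

Each feature is attached to every candidate edge of the rooted backbone —
all 2n−2 real edges plus a virtual edge above the root (placement there
means "outside all ingroups"; it is reported as edge −1) — and each
augmented tree is scored by Fitch small parsimony over the concatenated
columns, with `N` and `-` as wildcard states. Multifurcations in the input
tree are resolved deterministically before scoring, so Fitch is exact.

Rather than rebuilding trees, the implementation roots each augmented tree
at the attachment point: the two non-query subtrees there are the edge's
down-pass set D[v] and up-pass (rest-of-tree) set R[v], both computed once
in O(n) per tree, giving

    score(edge) = base_score + #{columns : edge_set(edge) ∩ query = ∅}

with `edge_set = fitch_combine(D, R)` precomputed as a bitmask matrix; a
query then costs one vectorised AND per edge. An internal consistency check
verifies `cost_down + cost_up + combine_penalty = base_score` on every
edge. The whole scheme is validated against exhaustive attachment
enumeration with an independently coded set-recursion Fitch scorer on
hundreds of random instances, including tie counts and score margins.

Tie-breaking: a tied pendant edge whose tip states are compatible with the
query at every column (i.e. the query is the reference, up to missing data)
wins first; remaining ties go to the edge closest to the root, then the
smallest edge id. The exact-match rule matters for two-member families: if
the sibling carries private substitutions, attaching an exact copy of a tip
on its pendant edge or on the family stem is equally parsimonious, and the
root-ward rule alone would eject the query onto the stem, where the
conservative stem rule (below) would then refuse the family label. The
root-ward rule is kept for genuinely ambiguous ties (e.g. a query
equidistant between two sister tips), where the less specific edge is the
honest summary.

Queries are placed one at a time, never jointly, so placements are
independent of query-set composition and order; batching only controls
audit-tree emission. Queries whose aligned row is entirely missing data are
flagged unplaceable and routed to the non-AMF bucket downstream.

## Clade extraction

The Glomeromycota clade and each family clade are delimited by the MRCA of
their defining reference tips in the outgroup-rooted tree; member edges are
all edges strictly inside the MRCA's subtree. The stem branch is excluded
by default: a sequence attaching there may be sister to the clade rather
than inside it, so counting it in would over-claim. `include_stem` flips
this for sensitivity analysis. A placement's family is the smallest
enclosing family clade (families are disjoint in practice; the rule is safe
under nesting); AMF placements inside no family are
`Glomeromycota_unclassified`. Screened-out and unplaceable features are
kept in the outputs with reason codes rather than silently dropped — such
sequences may represent undescribed taxa.

Summaries report, per family, the percentage of AMF features and of AMF
reads; the two can diverge strongly (few features can carry most reads),
which is why both are emitted.

## Synthetic data

The generator emulates the study design this pipeline targets: a rooted
binary reference tree whose ingroup is organised into labelled, disjoint
family clades (default 11, matching the described AMF families, 60 AMF
tips) plus outgroup tips (default 20) with one designated root outgroup;
sequences evolved from a random 600 bp root region under per-branch
Jukes–Cantor substitution (`p = rate · branch_length`, exponential branch
lengths, default rate 0.05 — within-family identities in the 80–95% range,
realistic for this marker); 150/150 bp primered read pairs from chosen tips
at a configurable extra divergence (default 2%, 100 queries); and
uniform-random junk reads (default 15) that carry primers, as real
off-target amplicons do, so they reach the homology screen. All randomness
derives from one integer seed and fixture files are byte-identical across
reruns.

What the generator does *not* model — indels (an optional stress mode
aside), rate heterogeneity across sites and lineages, chimeras, quality
degradation, PCR/abundance bias — bounds what passing tests show: they
validate the algorithms and their wiring under clean substitution-only
divergence, not robustness to every artifact of real Illumina runs.

## Problem sizes and runtime

The acceptance checks use the default study design (80 reference tips, 100
queries + 15 junk reads, 300 aligned columns), 500 random pairs up to
200 bp for the aligner oracle, 200 random instances up to 15 tips × 50
columns for the placement oracle, and 100 random 20-tip trees for the clade
oracle; the full suite plus acceptance script completes in about a minute
on one CPU. These sizes exercise every code path at desk scale; the
algorithms themselves are exact, so larger instances change cost, not
correctness.

## Known limitations

- Parsimony placement has no branch lengths and no likelihood weighting; an
  external-placer adapter interface exists conceptually but only the
  internal placer is implemented and tested.
- Progressive profile alignment is order-dependent in principle (reference
  order is fixed in the database, so outputs are deterministic) and is a
  heuristic, not an optimal MSA.
- The pre-screen reports a certificate score (first score reaching the
  threshold), not necessarily the global best subject, for retained
  queries.
- The OTU/ASV layer assumes substitution-dominated variation; heavy indel
  variation would lower end-to-end identities and over-split OTUs.
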