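"""Permissive homology pre-screen of study sequences against the reference DB.

Amplicon datasets routinely contain reads that are not LSU rDNA at all
(chimeras, off-target amplification, unidentifiable artifacts). Placing such
non-homologous sequences into a phylogeny produces abnormal clusters and
unacceptably long branches, so before any tree work every study sequence is
screened for basal similarity to the reference database: a query is retained
iff its best local-alignment score against *any* reference reaches a
permissive minimum (default 40, i.e. roughly a 40 bp perfect match under the
default +1 match reward). Both query strands are tried.

A word-seed index accelerates the scan: exact Smith–Waterman is run
reference-by-reference in descending order of shared seed count, stopping as
soon as the threshold is reached. Seeds only order the exact comparisons —
every pair is eventually aligned with the full DP unless the query was
already retained — so the retained set is identical to an exhaustive
all-pairs Smith–Waterman screen.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import PairwiseAlignment, ScoringScheme, align_pair, encode_codes, local_score
from .iupac import SequenceError, revcomp


@dataclass(frozen=True)
class ScreenResult:
    query_id: str
    best_subject_id: str | None
    best_score: float
    identity: float
    aligned_length: int
    strand: str  # "+", "-" or "." when nothing aligned
    retained: bool


def local_align(query: str, subject: str, scoring: ScoringScheme | None = None
                ) -> tuple[PairwiseAlignment, str]:
    """Best local alignment of the query (either strand) against the subject.

    Returns the alignment and the query strand ("+" forward, "-" reverse
    complement) that achieved it; the forward strand wins ties.
    """
    scoring = scoring or ScoringScheme()
    if not query or not subject:
        raise SequenceError("cannot align an empty sequence")
    fwd = align_pair(query, subject, scoring, mode="local")
    rev = align_pair(revcomp(query), subject, scoring, mode="local")
    return (fwd, "+") if fwd.score >= rev.score else (rev, "-")


def _seed_index(ref_codes: Mapping[str, np.ndarray], k: int) -> dict[tuple, set[str]]:
    index: dict[tuple, set[str]] = defaultdict(set)
    for rid, codes in ref_codes.items():
        for i in range(len(codes) - k + 1):
            word = codes[i:i + k]
            if (word == 4).any():  # skip ambiguous words
                continue
            index[tuple(int(c) for c in word)].add(rid)
    return index


def _seed_hits(codes: np.ndarray, index: Mapping[tuple, set[str]], k: int) -> dict[str, int]:
    hits: dict[str, int] = defaultdict(int)
    for i in range(len(codes) - k + 1):
        word = codes[i:i + k]
        if (word == 4).any():
            continue
        for rid in index.get(tuple(int(c) for c in word), ()):
            hits[rid] += 1
    return hits


def screen_queries(
    queries: Iterable[tuple[str, str]],
    references: Mapping[str, str],
    scoring: ScoringScheme | None = None,
    min_score: float = 40.0,
) -> list[ScreenResult]:
    """Screen study sequences against the reference database.

    queries: iterable of (id, sequence); references: id -> curated region.
    A query is retained iff its best local score against any reference (either
    strand) reaches min_score. Results keep the best subject/score seen for
    reporting; once a query is retained the remaining references need not be
    scanned, so the reported best score is a certificate, not necessarily the
    global optimum over all references.
    """
    scoring = scoring or ScoringScheme()
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    queries = list(queries)
    qids = [q for q, _ in queries]
    if len(set(qids)) != len(qids):
        raise ValueError("query ids must be unique")
    if not references:
        raise ValueError("reference database is empty")

    ref_codes = {rid: encode_codes(seq) for rid, seq in references.items()}
    k = scoring.word_size
    index = _seed_index(ref_codes, k)

    results: list[ScreenResult] = []
    for qid, qseq in queries:
        strands = {"+": encode_codes(qseq), "-": encode_codes(revcomp(qseq))}
        # order (strand, reference) pairs by shared-seed count, best first
        scored_pairs = []
        seen = set()
        for strand, codes in strands.items():
            for rid, nhits in _seed_hits(codes, index, k).items():
                scored_pairs.append((-nhits, strand, rid))
                seen.add((strand, rid))
        scored_pairs.sort(key=lambda t: (t[0], t[2], t[1]))
        for strand in ("+", "-"):
            for rid in references:
                if (strand, rid) not in seen:
                    scored_pairs.append((0, strand, rid))

        best_score = 0.0
        best_subject: str | None = None
        best_strand = "."
        for _, strand, rid in scored_pairs:
            score = local_score(strands[strand], ref_codes[rid], scoring)
            if score > best_score:
                best_score, best_subject, best_strand = score, rid, strand
            if best_score >= min_score:
                break

        if best_subject is not None:
            qaln = qseq if best_strand == "+" else revcomp(qseq)
            aln = align_pair(qaln, references[best_subject], scoring, mode="local")
            identity, aligned_len = aln.identity, aln.columns
        else:
            identity, aligned_len = 0.0, 0
        results.append(ScreenResult(
            query_id=qid, best_subject_id=best_subject, best_score=best_score,
            identity=identity, aligned_length=aligned_len, strand=best_strand,
            retained=best_score >= min_score))
    return results


def split_by_retention(results: Sequence[ScreenResult]) -> tuple[list[str], list[str]]:
    """Partition query ids into (retained, dropped)."""
    retained = [r.query_id for r in results if r.retained]
    dropped = [r.query_id for r in results if not r.retained]
    return retained, dropped
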