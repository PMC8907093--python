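"""Split R1/R2 alignment: universal reference blocks plus query rows.

The forward (R1) and reverse (R2) read cuts cover two disjoint sections of
the LSU region, so they are aligned as two independent blocks and only
concatenated afterwards — R1 content can never occupy R2 columns or vice
versa, which removes the failure mode of one sequence's R1 aligning against
another's R2.

The reference side of each block is built once by progressive alignment of
the read-length-cut reference fragments (guide order = input order). Study
fragments are then aligned one at a time against the frozen column profile:
reference columns are immutable, and query insertions relative to the
reference coordinate system are dropped and counted. This keeps query rows
mutually independent — adding or removing queries never changes any other
row, the property that makes batch composition irrelevant downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import NEG_INF, ScoringScheme, _affine_dp, _traceback, encode_codes


@dataclass
class AlignedBlock:
    """A fixed-width alignment block: reference rows first, then query rows."""

    row_ids: list[str]
    rows: list[str]
    n_reference: int
    insertion_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged block: row widths {sorted(widths)}")
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows length mismatch")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def reference_ids(self) -> list[str]:
        return self.row_ids[:self.n_reference]

    def row(self, rid: str) -> str:
        return self.rows[self.row_ids.index(rid)]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.row_ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


@dataclass
class SplitAlignment:
    """Paired R1/R2 blocks over identical row sets, concatenatable."""

    r1: AlignedBlock
    r2: AlignedBlock

    def __post_init__(self) -> None:
        if self.r1.row_ids != self.r2.row_ids:
            only1 = set(self.r1.row_ids) - set(self.r2.row_ids)
            only2 = set(self.r2.row_ids) - set(self.r1.row_ids)
            raise ValueError(
                f"row sets differ between blocks (r1-only: {sorted(only1)}, "
                f"r2-only: {sorted(only2)})")


def _column_profiles(rows: Sequence[str]) -> np.ndarray:
    """Per-column ACGT frequencies (w x 4); gaps and N are uninformative."""
    w = len(rows[0])
    counts = np.zeros((w, 4), dtype=np.float64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in rows:
        for j, ch in enumerate(row):
            idx = base_idx.get(ch)
            if idx is not None:
                counts[j, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return freqs


def _profile_score_matrix(query: str, freqs: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    """Expected match score of each query char against each column profile."""
    lut = scheme.substitution_lookup()[:4, :4]  # ACGT vs ACGT
    codes = encode_codes(query)
    w = freqs.shape[0]
    S = np.zeros((len(query), w), dtype=np.float32)
    informative = codes < 4
    if informative.any():
        # S[i, j] = sum_b freqs[j, b] * lut[code_i, b]; N-like chars score 0
        S[informative] = (freqs @ lut[codes[informative]].T).T.astype(np.float32)
    return S


def _pad_free_tail(col_a: list[str], col_b: list[str], query: str, w: int,
                   bi: int, bj: int) -> tuple[list[str], list[str]]:
    """Complete a traceback that stopped before the last column/char."""
    for j in range(bj, w):
        col_a.append("-")
        col_b.append(".")
    for ch in query[bi:]:
        col_a.append(ch)
        col_b.append("-")
    return col_a, col_b


def _align_chars_to_profile(query: str, freqs: np.ndarray, scheme: ScoringScheme
                            ) -> tuple[str, int, float]:
    """Globally align a fragment to a frozen column profile.

    Returns (aligned row of width = n columns, dropped insertion count,
    score). The alignment is end-to-end: the read-length cut guarantees that
    reference fragments and study fragments span the same region, so
    terminal gaps carry their normal cost and short fragments simply pay for
    the columns they miss.
    """
    w = freqs.shape[0]
    S = _profile_score_matrix(query, freqs, scheme)
    go, ge = np.float32(scheme.gap_open), np.float32(scheme.gap_extend)
    H, E, F, best, bi, bj = _affine_dp(S, go, ge, False, False, False, False, False)
    col_a, col_b, _, _ = _traceback(S, H, E, F, query, "." * w, bi, bj, False,
                                    float(go), float(ge))
    col_a, col_b = _pad_free_tail(col_a, col_b, query, w, bi, bj)
    row_chars: list[str] = []
    dropped = 0
    for qa, cb in zip(col_a, col_b):
        if cb == "-":  # query insertion: no reference column, drop the char
            if qa != "-":
                dropped += 1
            continue
        row_chars.append(qa)  # query char or '-' (deletion) in this column
    row = "".join(row_chars)
    if len(row) != w:
        raise AssertionError("profile alignment lost reference columns")
    return row, dropped, float(best)


def build_reference_alignment(fragments: Mapping[str, str] | Iterable[tuple[str, str]],
                              scheme: ScoringScheme | None = None) -> AlignedBlock:
    """Progressively align reference fragments into one universal block.

    Fragments are added in input order; each new fragment is aligned against
    the profile of the rows so far, and its insertions open all-gap columns
    in the existing rows (standard progressive profile alignment).
    """
    scheme = scheme or ScoringScheme()
    items = list(fragments.items()) if isinstance(fragments, Mapping) else list(fragments)
    if len(items) < 2:
        raise ValueError("need at least 2 reference fragments per block")
    ids = [i for i, _ in items]
    rows = [items[0][1].upper()]
    for rid, frag in items[1:]:
        frag = frag.upper()
        freqs = _column_profiles(rows)
        w = freqs.shape[0]
        S = _profile_score_matrix(frag, freqs, scheme)
        go, ge = np.float32(scheme.gap_open), np.float32(scheme.gap_extend)
        H, E, F, best, bi, bj = _affine_dp(S, go, ge, False, False, False, False, False)
        col_a, col_b, _, _ = _traceback(S, H, E, F, frag, "." * w, bi, bj, False,
                                        float(go), float(ge))
        col_a, col_b = _pad_free_tail(col_a, col_b, frag, w, bi, bj)
        # rebuild all rows, inserting gap columns where the new row has insertions
        new_rows = ["" for _ in rows]
        new_row = ""
        col_idx = 0
        for qa, cb in zip(col_a, col_b):
            if cb == "-":  # insertion: new all-gap column for existing rows
                for k in range(len(rows)):
                    new_rows[k] += "-"
                new_row += qa
            else:
                for k in range(len(rows)):
                    new_rows[k] += rows[k][col_idx]
                new_row += qa
                col_idx += 1
        rows = new_rows + [new_row]
    return AlignedBlock(row_ids=ids, rows=rows, n_reference=len(ids))


def align_query_to_block(query: str, block: AlignedBlock,
                         scheme: ScoringScheme | None = None) -> tuple[str, int]:
    """Align one study fragment against a block's frozen reference profile.

    Only the reference rows define the profile; the returned row has exactly
    the block's width and reports how many query characters were dropped as
    insertions relative to the reference columns.
    """
    scheme = scheme or ScoringScheme()
    if not query:
        raise ValueError("empty query fragment")
    freqs = _column_profiles(block.rows[:block.n_reference])
    row, dropped, _ = _align_chars_to_profile(query.upper(), freqs, scheme)
    return row, dropped


def add_queries(block: AlignedBlock, queries: Iterable[tuple[str, str]],
                scheme: ScoringScheme | None = None) -> tuple[AlignedBlock, dict[str, int]]:
    """Add query rows to a block; reference rows are bitwise untouched."""
    scheme = scheme or ScoringScheme()
    new_ids = list(block.row_ids)
    new_rows = list(block.rows)
    dropped: dict[str, int] = dict(block.insertion_counts)
    for qid, frag in queries:
        if qid in new_ids:
            raise ValueError(f"duplicate row id {qid!r}")
        row, d = align_query_to_block(frag, block, scheme)
        new_ids.append(qid)
        new_rows.append(row)
        dropped[qid] = d
    return AlignedBlock(row_ids=new_ids, rows=new_rows,
                        n_reference=block.n_reference,
                        insertion_counts=dropped), dropped


def concatenate_blocks(split: SplitAlignment) -> AlignedBlock:
    """Row-wise concatenation, R1 block first; characters are never altered."""
    r1, r2 = split.r1, split.r2
    rows = [a + b for a, b in zip(r1.rows, r2.rows)]
    return AlignedBlock(row_ids=list(r1.row_ids), rows=rows,
                        n_reference=r1.n_reference)
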