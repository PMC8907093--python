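"""Pairwise alignment engine: affine-gap local, global, and overlap DP.

All aligners in the package funnel through one Gotoh-style dynamic program
over a precomputed position score matrix, so the local homology screen, the
global identity used for OTU clustering, and the query-to-profile alignment
share identical gap conventions:

* a gap of length k costs ``gap_open + (k - 1) * gap_extend`` (the opening
  position carries ``gap_open``);
* N scores 0 against anything (missing data, neither reward nor penalty);
* local alignment is the Smith–Waterman optimum (scores clamped at 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .iupac import SequenceError, validate_iupac

NEG_INF = np.float32(-1e9)

# scoring codes: A,C,G,T -> 0..3, anything ambiguous -> 4 (N-like)
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE_TABLE[ord(_c)] = _i
    _CODE_TABLE[ord(_c.lower())] = _i
_GAP_CODE = 5
_CODE_TABLE_GAP = _CODE_TABLE.copy()
_CODE_TABLE_GAP[ord("-")] = _GAP_CODE


def encode_codes(seq: str, *, allow_gap: bool = False) -> np.ndarray:
    """Map a sequence to scoring codes (ACGT -> 0..3, ambiguity -> 4, '-' -> 5)."""
    validate_iupac(seq, allow_gap=allow_gap)
    table = _CODE_TABLE_GAP if allow_gap else _CODE_TABLE
    return table[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Scores for the permissive homology screen and downstream alignments.

    The defaults (+1/-2, gaps -5/-2, 7-mer seeds) make a ~40 bp perfect match
    reach the default screen threshold, operationalising a deliberately
    permissive "any similarity" filter.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 7

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")

    def substitution_lookup(self) -> np.ndarray:
        """5x5 score table over codes; code 4 (N) scores 0 vs everything."""
        lut = np.full((5, 5), self.mismatch, dtype=np.float32)
        np.fill_diagonal(lut, self.match)
        lut[4, :] = 0.0
        lut[:, 4] = 0.0
        return lut


def score_matrix(a_codes: np.ndarray, b_codes: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    lut = scheme.substitution_lookup()
    return lut[a_codes[:, None], b_codes[None, :]]


@njit(cache=True)
def _affine_dp(S, gap_open, gap_extend, local, free_a_start, free_a_end,
               free_b_start, free_b_end):  # pragma: no cover - jitted
    """Fill Gotoh matrices for the score matrix S (rows = seq A, cols = seq B).

    E = gap in A (consume B), F = gap in B (consume A). Returns (H, E, F,
    best_score, best_i, best_j) where (best_i, best_j) is the traceback start.
    """
    m, n = S.shape
    H = np.full((m + 1, n + 1), NEG_INF, dtype=np.float32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.float32)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.float32)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        if free_a_start or local:
            H[0, j] = 0.0
        else:
            H[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        if free_b_start or local:
            H[i, 0] = 0.0
        else:
            H[i, 0] = gap_open + (i - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0.0:
                h = 0.0
            H[i, j] = h
    if local:
        best = np.float32(0.0)
        bi = 0
        bj = 0
        for i in range(m + 1):
            for j in range(n + 1):
                if H[i, j] > best:
                    best = H[i, j]
                    bi = i
                    bj = j
        return H, E, F, best, bi, bj
    best = H[m, n]
    bi = m
    bj = n
    if free_a_end:
        for j in range(n + 1):
            if H[m, j] > best:
                best = H[m, j]
                bi = m
                bj = j
    if free_b_end:
        for i in range(m + 1):
            if H[i, n] > best:
                best = H[i, n]
                bi = i
                bj = n
    return H, E, F, best, bi, bj


@njit(cache=True)
def _local_score_only(S, gap_open, gap_extend):  # pragma: no cover - jitted
    """Smith–Waterman best score with two rolling rows (no traceback)."""
    m, n = S.shape
    Hp = np.zeros(n + 1, dtype=np.float32)  # previous row of H
    Hc = np.zeros(n + 1, dtype=np.float32)
    Fv = np.full(n + 1, NEG_INF, dtype=np.float32)  # vertical gap state per column
    best = np.float32(0.0)
    for i in range(1, m + 1):
        e = NEG_INF  # horizontal gap state along this row
        Hc[0] = 0.0
        for j in range(1, n + 1):
            e1 = Hc[j - 1] + gap_open
            e = e + gap_extend
            if e1 > e:
                e = e1
            f1 = Hp[j] + gap_open
            f2 = Fv[j] + gap_extend
            f = f1 if f1 > f2 else f2
            Fv[j] = f
            h = Hp[j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            Hc[j] = h
            if h > best:
                best = h
        Hp, Hc = Hc, Hp
    return best


def local_score(a_codes: np.ndarray, b_codes: np.ndarray, scheme: ScoringScheme) -> float:
    """Best local alignment score of A vs B (no traceback)."""
    if a_codes.size == 0 or b_codes.size == 0:
        raise SequenceError("cannot align an empty sequence")
    S = score_matrix(a_codes, b_codes, scheme)
    return float(_local_score_only(S, np.float32(scheme.gap_open), np.float32(scheme.gap_extend)))


@dataclass(frozen=True)
class PairwiseAlignment:
    """A traced pairwise alignment of A (rows) against B (columns)."""

    score: float
    aligned_a: str
    aligned_b: str
    a_interval: tuple[int, int]  # half-open on the input A
    b_interval: tuple[int, int]
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        """Matching columns over aligned columns (gaps count as mismatch)."""
        return self.matches / self.columns if self.columns else 0.0


def _traceback(S, H, E, F, a: str, b: str, start_i: int, start_j: int, local: bool,
               gap_open: float, gap_extend: float) -> tuple[list[str], list[str], int, int]:
    """Walk back through the Gotoh matrices from (start_i, start_j)."""
    i, j = start_i, start_j
    col_a: list[str] = []
    col_b: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if local and H[i, j] == 0.0 and state == "H":
            break
        if state == "H":
            if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + S[i - 1, j - 1]):
                col_a.append(a[i - 1])
                col_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif j > 0 and np.isclose(H[i, j], E[i, j]):
                state = "E"
            elif i > 0 and np.isclose(H[i, j], F[i, j]):
                state = "F"
            elif j > 0:  # boundary gap row
                col_a.append("-")
                col_b.append(b[j - 1])
                j -= 1
            else:
                col_a.append(a[i - 1])
                col_b.append("-")
                i -= 1
        elif state == "E":
            col_a.append("-")
            col_b.append(b[j - 1])
            if np.isclose(E[i, j], H[i, j - 1] + gap_open):
                state = "H"
            j -= 1
        else:  # F
            col_a.append(a[i - 1])
            col_b.append("-")
            if np.isclose(F[i, j], H[i - 1, j] + gap_open):
                state = "H"
            i -= 1
        if not local and i == 0 and j == 0:
            break
    return col_a[::-1], col_b[::-1], i, j


def align_pair(a: str, b: str, scheme: ScoringScheme, *, mode: str = "local",
               free_a_ends: bool = False, free_b_ends: bool = False) -> PairwiseAlignment:
    """Align two sequences with traceback.

    mode="local" gives the Smith–Waterman optimum; mode="global" an
    end-to-end Needleman–Wunsch alignment; the ``free_*_ends`` flags make
    terminal gaps in the respective sequence free (overlap alignment).
    """
    if not a or not b:
        raise SequenceError("cannot align an empty sequence")
    local = mode == "local"
    ac = encode_codes(a)
    bc = encode_codes(b)
    S = score_matrix(ac, bc, scheme)
    go = np.float32(scheme.gap_open)
    ge = np.float32(scheme.gap_extend)
    H, E, F, best, bi, bj = _affine_dp(S, go, ge, local,
                                       free_a_ends, free_a_ends,
                                       free_b_ends, free_b_ends)
    col_a, col_b, ai, aj = _traceback(S, H, E, F, a, b, bi, bj, local,
                                      float(go), float(ge))
    if not local:
        # pad out unreached terminal free gaps so the alignment is end-to-end
        lead_a = a[:ai] if ai else ""
        lead_b = b[:aj] if aj else ""
        if lead_a or lead_b:
            pad = max(len(lead_a), len(lead_b))
            col_a = list(lead_a.rjust(pad, "-")) + col_a
            col_b = list(lead_b.rjust(pad, "-")) + col_b
            ai = aj = 0
        tail_a = a[bi:]
        tail_b = b[bj:]
        if tail_a or tail_b:
            pad = max(len(tail_a), len(tail_b))
            col_a = col_a + list(tail_a.ljust(pad, "-"))
            col_b = col_b + list(tail_b.ljust(pad, "-"))
            bi, bj = len(a), len(b)
    matches = sum(1 for x, y in zip(col_a, col_b) if x == y and x != "-")
    return PairwiseAlignment(
        score=float(best),
        aligned_a="".join(col_a),
        aligned_b="".join(col_b),
        a_interval=(ai, bi),
        b_interval=(aj, bj),
        matches=matches,
        columns=len(col_a),
    )


def global_identity(a: str, b: str, scheme: ScoringScheme) -> float:
    """End-to-end global alignment identity (gap columns count as mismatch)."""
    return align_pair(a, b, scheme, mode="global").identity
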