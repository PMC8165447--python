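"""Affine-gap pairwise alignment cores (Gotoh) shared by scanning,
classification and phylogeny.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend``, i.e.
the opening penalty is charged together with the first gap residue.
Traceback tie-breaks prefer diagonal, then up (a gap in the second
sequence), then left, making every alignment deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_NEG = -1e30


class AlignmentError(ValueError):
    """Bad alignment input (unknown residue, empty sequence)."""


@lru_cache(maxsize=8)
def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _matrix_arrays(name: str) -> tuple[str, np.ndarray]:
    mat = load_matrix(name)
    return str(mat.alphabet), np.asarray(mat, dtype=float)


def _encode(seq: str, alphabet: str, which: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(alphabet)}
    out = np.empty(len(seq), dtype=np.intp)
    for i, ch in enumerate(seq):
        j = lut.get(ch)
        if j is None:
            raise AlignmentError(
                f"unknown residue {ch!r} at position {i + 1} of {which}"
            )
        out[i] = j
    return out


def pair_score_matrix(a: str, b: str, matrix_name: str = "BLOSUM62") -> np.ndarray:
    """Residue-pair score matrix S[i, j] = M[a[i], b[j]]."""
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    alphabet, M = _matrix_arrays(matrix_name)
    ia = _encode(a, alphabet, "first sequence")
    ib = _encode(b, alphabet, "second sequence")
    return M[np.ix_(ia, ib)]


def gotoh_global(S: np.ndarray, gap_open: float, gap_extend: float
                 ) -> tuple[float, str]:
    """Optimal global alignment over a column-score matrix.

    Returns (score, ops) where ops is a string over {'D','U','L'} read from
    the start of the alignment: D consumes one row and one column, U one row
    (gap in the second axis), L one column.
    """
    n, m = S.shape
    go = gap_open + gap_extend
    ge = gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)   # gap in columns (op 'U')
    Y = np.full((n + 1, m + 1), _NEG)   # gap in rows (op 'L')
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * ge)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * ge)
        pY[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        Si = S[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        pMi, pXi, pYi = pM[i], pX[i], pY[i]
        for j in range(1, m + 1):
            # match state: predecessor preference M > X > Y
            a, b, c = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            best, p = a, 0
            if b > best:
                best, p = b, 1
            if c > best:
                best, p = c, 2
            Mi[j] = best + Si[j - 1]
            pMi[j] = p
            # vertical gap (consumes row i)
            a, b, c = Mp[j] - go, Xp[j] - ge, Yp[j] - go
            best, p = a, 0
            if b > best:
                best, p = b, 1
            if c > best:
                best, p = c, 2
            Xi[j] = best
            pXi[j] = p
            # horizontal gap (consumes column j)
            a, b, c = Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge
            best, p = a, 0
            if b > best:
                best, p = b, 1
            if c > best:
                best, p = c, 2
            Yi[j] = best
            pYi[j] = p

    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2

    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            state = pM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("U")
            state = pX[i, j]
            i -= 1
        else:
            ops.append("L")
            state = pY[i, j]
            j -= 1
    return float(score), "".join(reversed(ops))


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment region; coordinates are 1-based inclusive and all
    zero for an empty alignment."""

    score: float
    ops: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def is_empty(self) -> bool:
        return not self.ops


def gotoh_local(S: np.ndarray, gap_open: float, gap_extend: float
                ) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment (affine gaps, score floor 0)."""
    n, m = S.shape
    go = gap_open + gap_extend
    ge = gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    # pointer 3 means "alignment starts here"
    pM = np.full((n + 1, m + 1), 3, np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    best_score = 0.0
    best_cell = (0, 0)
    for i in range(1, n + 1):
        Si = S[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        pMi, pXi, pYi = pM[i], pX[i], pY[i]
        for j in range(1, m + 1):
            a, b, c = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            best, p = a, 0
            if b > best:
                best, p = b, 1
            if c > best:
                best, p = c, 2
            if best <= 0.0:
                best, p = 0.0, 3
            Mi[j] = best + Si[j - 1]
            pMi[j] = p
            if Mi[j] > best_score:
                best_score = Mi[j]
                best_cell = (i, j)

            a, b, c = Mp[j] - go, Xp[j] - ge, Yp[j] - go
            best, p = a, 0
            if b > best:
                best, p = b, 1
            if c > best:
                best, p = c, 2
            Xi[j] = best
            pXi[j] = p

            a, b, c = Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge
            best, p = a, 0
            if b > best:
                best, p = b, 1
            if c > best:
                best, p = c, 2
            Yi[j] = best
            pYi[j] = p

    if best_score <= 0.0:
        return LocalAlignment(0.0, "", 0, 0, 0, 0)

    ops: list[str] = []
    i, j = best_cell
    state = 0
    while True:
        if state == 0:
            nxt = pM[i, j]
            ops.append("D")
            i, j = i - 1, j - 1
            if nxt == 3:
                break
            state = nxt
        elif state == 1:
            nxt = pX[i, j]
            ops.append("U")
            i -= 1
            state = nxt
        else:
            nxt = pY[i, j]
            ops.append("L")
            j -= 1
            state = nxt
    ops.reverse()
    return LocalAlignment(
        score=float(best_score), ops="".join(ops),
        a_start=i + 1, a_end=best_cell[0],
        b_start=j + 1, b_end=best_cell[1],
    )


def render_alignment(a: str, b: str, ops: str, a_offset: int = 0,
                     b_offset: int = 0) -> tuple[str, str]:
    """Expand an ops string into two gapped rows over a and b."""
    ra: list[str] = []
    rb: list[str] = []
    i, j = a_offset, b_offset
    for op in ops:
        if op == "D":
            ra.append(a[i]); rb.append(b[j])
            i += 1; j += 1
        elif op == "U":
            ra.append(a[i]); rb.append("-")
            i += 1
        else:
            ra.append("-"); rb.append(b[j])
            j += 1
    return "".join(ra), "".join(rb)


def align_global(a: str, b: str, matrix_name: str = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0
                 ) -> tuple[float, str, str]:
    """Global (Needleman-Wunsch) alignment of two residue strings."""
    S = pair_score_matrix(a, b, matrix_name)
    score, ops = gotoh_global(S, gap_open, gap_extend)
    ra, rb = render_alignment(a, b, ops)
    return score, ra, rb


def align_local(a: str, b: str, matrix_name: str = "BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0
                ) -> tuple[LocalAlignment, str, str]:
    """Local (Smith-Waterman) alignment; returns the region plus gapped rows."""
    S = pair_score_matrix(a, b, matrix_name)
    aln = gotoh_local(S, gap_open, gap_extend)
    if aln.is_empty:
        return aln, "", ""
    ra, rb = render_alignment(a, b, aln.ops, aln.a_start - 1, aln.b_start - 1)
    return aln, ra, rb
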