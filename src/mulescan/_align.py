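"""Shared pairwise-alignment kernels.

Three DP flavours back the whole pipeline:

* :func:`sw_local` — Smith–Waterman local alignment with affine gaps
  (gap of length k costs ``gap_open + k * gap_extend``), used for the
  translated DDE-domain search and for nucleotide homology steps.
* :func:`nw_global` — Needleman–Wunsch global alignment with a linear
  gap penalty, used by the center-star aligner, family identity and
  boundary detection.
* :func:`extend_align` — anchored extension: the alignment must start at
  position (0, 0) of both inputs but may end anywhere (maximum-scoring
  prefix pair), used for TIR detection from the element termini.

All tracebacks are deterministic: ties are broken diagonal first, then
up (consume query / first sequence), then left.  ``N`` in DNA and
``X``/``*`` in protein never score positively against anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# alphabets and substitution matrices

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_PROT_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}
_X_INDEX = _PROT_INDEX["X"]

DNA_ALPHABET = "ACGTN"
_DNA_INDEX = {c: i for i, c in enumerate(DNA_ALPHABET)}


def _load_blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    raw = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            mat[i, j] = int(raw[a, b])
    # unknown / stop residues: flat -4 against everything (BLAST-like)
    for sym in ("X", "*"):
        k = _PROT_INDEX[sym]
        mat[k, :] = -4
        mat[:, k] = -4
    return mat


BLOSUM62: np.ndarray = _load_blosum62()


def dna_matrix(match: int = 1, mismatch: int = -1) -> np.ndarray:
    """5x5 scoring matrix over ACGTN; N scores `mismatch` vs everything."""
    mat = np.full((5, 5), mismatch, dtype=np.int32)
    for i in range(4):
        mat[i, i] = match
    mat[4, :] = mismatch
    mat[:, 4] = mismatch
    return mat


DNA_MATRIX = dna_matrix()


def encode_protein(seq: str) -> np.ndarray:
    return np.array([_PROT_INDEX.get(c, _X_INDEX) for c in seq.upper()], dtype=np.int8)


def encode_dna(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        out[i] = _DNA_INDEX.get(c, 4)
    return out


# ---------------------------------------------------------------------------
# kernels

_DIAG, _UP, _LEFT = 0, 1, 2  # traceback op codes


@njit(cache=True)
def _sw_kernel(q, s, sub, go, ge):  # pragma: no cover - numba
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -10**8, dtype=np.int32)
    F = np.full((m + 1, n + 1), -10**8, dtype=np.int32)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 open, 1 extend
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo = H[i, j - 1] - go - ge
            ee = E[i, j - 1] - ge
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 0
            else:
                E[i, j] = ee
                ptrE[i, j] = 1
            fo = H[i - 1, j] - go - ge
            fe = F[i - 1, j] - ge
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 0
            else:
                F[i, j] = fe
                ptrF[i, j] = 1
            d = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            # tie-break: diagonal, then up (F), then left (E); 0-floor last
            v = d
            p = 1
            if F[i, j] > v:
                v = F[i, j]
                p = 2
            if E[i, j] > v:
                v = E[i, j]
                p = 3
            if v <= 0:
                v = 0
                p = 0
            H[i, j] = v
            ptrH[i, j] = p
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


@njit(cache=True)
def _sw_traceback(bi, bj, ptrH, ptrE, ptrF):  # pragma: no cover - numba
    ops = np.empty(bi + bj, dtype=np.int8)
    k = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=F(up), 2=E(left)
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                ops[k] = _DIAG
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = ptrF[i, j] == 0
            ops[k] = _UP
            k += 1
            i -= 1
            if opened:
                state = 0
        else:
            opened = ptrE[i, j] == 0
            ops[k] = _LEFT
            k += 1
            j -= 1
            if opened:
                state = 0
    return ops[:k][::-1], i, j


@njit(cache=True)
def _nw_kernel(a, b, sub, gap):  # pragma: no cover - numba
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 diag, 2 up, 3 left
    for i in range(1, m + 1):
        H[i, 0] = -gap * i
        ptr[i, 0] = 2
    for j in range(1, n + 1):
        H[0, j] = -gap * j
        ptr[0, j] = 3
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            u = H[i - 1, j] - gap
            l = H[i, j - 1] - gap
            v = d
            p = 1
            if u > v:
                v = u
                p = 2
            if l > v:
                v = l
                p = 3
            H[i, j] = v
            ptr[i, j] = p
    ops = np.empty(m + n, dtype=np.int8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 1:
            ops[k] = _DIAG
            i -= 1
            j -= 1
        elif p == 2:
            ops[k] = _UP
            i -= 1
        else:
            ops[k] = _LEFT
            j -= 1
        k += 1
    return H[m, n], ops[:k][::-1]


@njit(cache=True)
def _extend_kernel(a, b, sub, gap):  # pragma: no cover - numba
    """Global start at (0,0), free end: best-scoring aligned prefix pair."""
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for i in range(1, m + 1):
        H[i, 0] = -gap * i
        ptr[i, 0] = 2
    for j in range(1, n + 1):
        H[0, j] = -gap * j
        ptr[0, j] = 3
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            u = H[i - 1, j] - gap
            l = H[i, j - 1] - gap
            v = d
            p = 1
            if u > v:
                v = u
                p = 2
            if l > v:
                v = l
                p = 3
            H[i, j] = v
            ptr[i, j] = p
            if v > best:
                best = v
                bi = i
                bj = j
    ops = np.empty(bi + bj, dtype=np.int8)
    k = 0
    i, j = bi, bj
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 1:
            ops[k] = _DIAG
            i -= 1
            j -= 1
        elif p == 2:
            ops[k] = _UP
            i -= 1
        else:
            ops[k] = _LEFT
            j -= 1
        k += 1
    return best, bi, bj, ops[:k][::-1]


# ---------------------------------------------------------------------------
# wrappers

@dataclass(frozen=True)
class LocalAlignment:
    """Result of a local (or anchored) pairwise alignment."""

    score: int
    query_span: tuple[int, int]     # 0-based half-open in the query
    subject_span: tuple[int, int]   # 0-based half-open in the subject
    aligned_query: str
    aligned_subject: str

    @property
    def length(self) -> int:
        return len(self.aligned_query)

    @property
    def n_matches(self) -> int:
        return sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_subject)
            if a == b and a not in "-Nn"
        )

    @property
    def identity(self) -> float:
        return self.n_matches / self.length if self.length else 0.0


def _decode(q: str, s: str, ops: np.ndarray, qi: int, sj: int) -> tuple[str, str]:
    aq, as_ = [], []
    i, j = qi, sj
    for op in ops:
        if op == _DIAG:
            aq.append(q[i])
            as_.append(s[j])
            i += 1
            j += 1
        elif op == _UP:
            aq.append(q[i])
            as_.append("-")
            i += 1
        else:
            aq.append("-")
            as_.append(s[j])
            j += 1
    return "".join(aq), "".join(as_)


def _sw(q: str, s: str, qi: np.ndarray, si: np.ndarray, sub: np.ndarray,
        gap_open: int, gap_extend: int) -> LocalAlignment:
    if len(q) == 0 or len(s) == 0:
        raise ValueError("empty sequence in local alignment")
    score, bi, bj, ptrH, ptrE, ptrF = _sw_kernel(qi, si, sub, gap_open, gap_extend)
    if score <= 0:
        return LocalAlignment(0, (0, 0), (0, 0), "", "")
    ops, i0, j0 = _sw_traceback(bi, bj, ptrH, ptrE, ptrF)
    aq, as_ = _decode(q, s, ops, i0, j0)
    return LocalAlignment(int(score), (int(i0), int(bi)), (int(j0), int(bj)), aq, as_)


def local_align_protein(query: str, subject: str, matrix: np.ndarray | None = None,
                        gap_open: int = 11, gap_extend: int = 1) -> LocalAlignment:
    """Optimal local affine-gap alignment of two peptides (BLOSUM62 default).

    A gap of length k costs ``gap_open + k * gap_extend``.  Unknown
    residues (anything outside the BLOSUM62 alphabet, plus X and *)
    score -4 against everything.
    """
    sub = BLOSUM62 if matrix is None else matrix
    return _sw(query, subject, encode_protein(query), encode_protein(subject),
               sub, gap_open, gap_extend)


def local_align_dna(query: str, subject: str, match: int = 1, mismatch: int = -1,
                    gap_open: int = 2, gap_extend: int = 1) -> LocalAlignment:
    sub = dna_matrix(match, mismatch)
    return _sw(query, subject, encode_dna(query), encode_dna(subject),
               sub, gap_open, gap_extend)


def global_align(a: str, b: str, sub: np.ndarray, enc, gap: int) -> tuple[int, str, str]:
    if len(a) == 0 and len(b) == 0:
        return 0, "", ""
    score, ops = _nw_kernel(enc(a), enc(b), sub, gap)
    aa, ab = _decode(a, b, ops, 0, 0)
    return int(score), aa, ab


def global_align_dna(a: str, b: str, match: int = 1, mismatch: int = -1,
                     gap: int = 2) -> tuple[int, str, str]:
    """Global NW alignment of two DNA strings with a linear gap penalty."""
    return global_align(a, b, dna_matrix(match, mismatch), encode_dna, gap)


def global_align_protein(a: str, b: str, gap: int = 8) -> tuple[int, str, str]:
    return global_align(a, b, BLOSUM62, encode_protein, gap)


def extend_align_dna(a: str, b: str, match: int = 1, mismatch: int = -1,
                     gap: int = 2) -> LocalAlignment:
    """Anchored extension: alignment pinned to start at (0,0), free to end
    anywhere; returns the maximum-scoring aligned prefix pair."""
    if len(a) == 0 or len(b) == 0:
        return LocalAlignment(0, (0, 0), (0, 0), "", "")
    score, bi, bj, ops = _extend_kernel(
        encode_dna(a), encode_dna(b), dna_matrix(match, mismatch), gap)
    aa, ab = _decode(a, b, ops, 0, 0)
    return LocalAlignment(int(score), (0, int(bi)), (0, int(bj)), aa, ab)
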