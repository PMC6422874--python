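"""Exact Smith-Waterman local alignment with affine gaps, and Karlin-Altschul
E-values.

This is the screening stand-in for a BLASTN search: nucleotide local
alignment under a BLASTN-like scheme (match +2, mismatch -3, gap open -5,
gap extend -2, where a gap of length L costs ``open + L * extend``), with
percent identity computed over alignment columns (gaps count as columns)
and E = K * m * n * exp(-lambda * S).

The dynamic programming kernels are numba-compiled; both strands of the
query are evaluated by :func:`local_align` and the better kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

# base encoding: A,C,G,T -> 0..3, N (and anything else) -> 4.
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme. Gap of length L costs open + L * extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a query against a subject.

    Spans are 1-based inclusive; the query span refers to the plus-strand
    query when ``strand`` is '+' and to the reverse complement when '-'.
    Identity is 100 * matched columns / alignment columns, gap columns
    included; N never counts as a match.
    """

    score: int
    identity: float
    aligned_query_span: tuple[int, int]
    aligned_subject_span: tuple[int, int]
    strand: str
    matches: int = 0
    columns: int = 0

    @property
    def query_span_length(self) -> int:
        return self.aligned_query_span[1] - self.aligned_query_span[0] + 1


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@njit(cache=True)
def _sw_score(q, s, match, mismatch, gap_open, gap_extend):
    """Score-only affine Smith-Waterman (linear memory)."""
    n, m = q.shape[0], s.shape[0]
    H = np.zeros(m + 1, np.int32)
    E = np.zeros(m + 1, np.int32)
    best = 0
    first = gap_open + gap_extend  # opening a gap costs open + extend for base 1
    for i in range(1, n + 1):
        diag = 0
        F = 0
        qi = q[i - 1]
        for j in range(1, m + 1):
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            h = diag + sub
            e = E[j] + gap_extend
            eo = H[j] + first
            if eo > e:
                e = eo
            E[j] = e
            f = F + gap_extend
            fo = H[j - 1] + first
            if fo > f:
                f = fo
            F = f
            diag = H[j]
            v = h
            if e > v:
                v = e
            if f > v:
                v = f
            if v < 0:
                v = 0
            H[j] = v
            if v > best:
                best = v
    return best


@njit(cache=True)
def _sw_full(q, s, match, mismatch, gap_open, gap_extend):
    """Full-matrix affine Smith-Waterman with traceback.

    Returns (score, q_start, q_end, s_start, s_end, matches, columns) with
    0-based half-open coordinates.
    """
    n, m = q.shape[0], s.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.zeros((n + 1, m + 1), np.int32)
    F = np.zeros((n + 1, m + 1), np.int32)
    # traceback pointers: 0 stop, 1 diag, 2 up(E, gap in subject), 3 left(F, gap in query)
    ptr_h = np.zeros((n + 1, m + 1), np.int8)
    ptr_e = np.zeros((n + 1, m + 1), np.int8)  # 1 if E opened here (came from H)
    ptr_f = np.zeros((n + 1, m + 1), np.int8)
    first = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    NEG = -1 << 30
    for i in range(n + 1):
        E[i, 0] = NEG
        F[i, 0] = NEG
    for j in range(m + 1):
        E[0, j] = NEG
        F[0, j] = NEG
    for i in range(1, n + 1):
        qi = q[i - 1]
        E[i, 0] = NEG
        F[i, 0] = NEG
        for j in range(1, m + 1):
            e_ext = E[i - 1, j] + gap_extend
            e_open = H[i - 1, j] + first
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_ext
            f_ext = F[i, j - 1] + gap_extend
            f_open = H[i, j - 1] + first
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_ext
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            h = H[i - 1, j - 1] + sub
            v = h
            p = 1
            if E[i, j] > v:
                v = E[i, j]
                p = 2
            if F[i, j] > v:
                v = F[i, j]
                p = 3
            if v <= 0:
                v = 0
                p = 0
            H[i, j] = v
            ptr_h[i, j] = p
            if v > best:
                best = v
                bi = i
                bj = j
    # traceback from (bi, bj)
    i, j = bi, bj
    matches = 0
    columns = 0
    state = 0  # 0 in H, 2 in E, 3 in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            columns += 1
            opened = ptr_e[i, j]
            i -= 1
            if opened:
                state = 0
        else:
            columns += 1
            opened = ptr_f[i, j]
            j -= 1
            if opened:
                state = 0
    return best, i, bi, j, bj, matches, columns


def sw_score(query: str | np.ndarray, subject: str | np.ndarray,
             scoring: Scoring = DEFAULT_SCORING) -> int:
    """Optimal local alignment score (plus strand only)."""
    q = encode(query) if isinstance(query, str) else query
    s = encode(subject) if isinstance(subject, str) else subject
    if q.size == 0 or s.size == 0:
        raise ValueError("empty sequence")
    return int(_sw_score(q, s, scoring.match, scoring.mismatch,
                         scoring.gap_open, scoring.gap_extend))


def sw_align(query: str | np.ndarray, subject: str | np.ndarray,
             scoring: Scoring = DEFAULT_SCORING, strand: str = "+") -> AlignmentResult:
    """Optimal local alignment with coordinates and identity (one strand)."""
    q = encode(query) if isinstance(query, str) else query
    s = encode(subject) if isinstance(subject, str) else subject
    if q.size == 0 or s.size == 0:
        raise ValueError("empty sequence")
    score, qs, qe, ss, se, matches, columns = _sw_full(
        q, s, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if score == 0 or columns == 0:
        return AlignmentResult(0, 0.0, (1, 1), (1, 1), strand, 0, 0)
    identity = 100.0 * matches / columns
    return AlignmentResult(
        score=int(score),
        identity=identity,
        aligned_query_span=(qs + 1, qe),
        aligned_subject_span=(ss + 1, se),
        strand=strand,
        matches=int(matches),
        columns=int(columns),
    )


def local_align(query: str, subject: str,
                scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Best local alignment of query vs subject over both query strands.

    Ties between strands go to '+'.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    fwd = sw_align(query, subject, scoring, strand="+")
    rev = sw_align(reverse_complement(query), subject, scoring, strand="-")
    return fwd if fwd.score >= rev.score else rev


def evalue(score: float, query_len: int, db_len: int,
           karlin_lambda: float = 0.625, karlin_K: float = 0.41) -> float:
    """Karlin-Altschul expected number of chance alignments at >= score.

    E = K * m * n * exp(-lambda * S). Strictly decreasing in score and
    linear in the search-space lengths.
    """
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if karlin_lambda <= 0 or karlin_K <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return karlin_K * query_len * db_len * math.exp(-karlin_lambda * score)
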