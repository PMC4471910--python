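"""Dynamic-programming alignment kernels.

Two kernels cover every alignment need in the package:

* :func:`sw_affine` — local (Smith–Waterman) alignment with affine gaps,
  used by the seed-and-extend scanner, the locus genotyper and fragment
  placement.  A gap of length k scores ``gap_open + k * gap_extend``.
* :func:`nw_matrix` — global (Needleman–Wunsch) alignment with linear gaps
  over an arbitrary precomputed column-score matrix, used for pairwise and
  profile–profile steps of the progressive aligner and for conversion-aware
  bisulfite clone alignment.

Rows are vectorized with numpy; the in-row (left-neighbour) dependency is
resolved with a prefix-max scan, so both kernels run in O(n·m) numpy work.
N never scores as a match anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG_INF = np.int32(-(10**8))

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def substitution_matrix(match: int, mismatch: int) -> np.ndarray:
    """5x5 base-pair scores over (A,C,G,T,N); N scores mismatch against all."""
    w = np.full((5, 5), mismatch, dtype=np.int32)
    for i in range(4):
        w[i, i] = match
    w[4, :] = mismatch
    w[:, 4] = mismatch
    return w


@dataclass
class LocalAlignment:
    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_matches(self) -> int:
        return sum(
            x == y and x != "N" and x != "-"
            for x, y in zip(self.aligned_a, self.aligned_b)
        )

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.n_matches / self.n_columns if self.n_columns else 0.0


def sw_affine(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> LocalAlignment:
    """Optimal local alignment of a vs b under affine gap scoring."""
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    ea, eb = encode(a), encode(b)
    w = substitution_matrix(match, mismatch)
    go_ge = gap_open + gap_extend

    M = np.full((n + 1, m + 1), 0, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap in a (consumes b)
    js = np.arange(m + 1, dtype=np.int32)

    best_prev = np.zeros(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        s = w[ea[i - 1], eb]
        M[i, 1:] = np.maximum(0, best_prev[:-1] + s)
        X[i, 1:] = np.maximum(M[i - 1, 1:] + go_ge, X[i - 1, 1:] + gap_extend)
        # Y[i,j] = go + ge*j + max_{k<j}(M[i,k] - ge*k): prefix-max scan
        cand = M[i] - gap_extend * js
        pref = np.maximum.accumulate(cand)
        Y[i, 1:] = gap_open + gap_extend * js[1:] + pref[:-1]
        best_prev = np.maximum(np.maximum(M[i], X[i]), Y[i])

    best = np.maximum(np.maximum(M, X), Y)
    flat = int(np.argmax(best))
    i, j = divmod(flat, m + 1)
    score = int(best[i, j])
    if score <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")

    # traceback
    state = "M" if M[i, j] == score else ("X" if X[i, j] == score else "Y")
    ra, rb = [], []
    while True:
        if state == "M":
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            pb = int(M[i, j]) - int(w[ea[i - 1], eb[j - 1]])
            i, j = i - 1, j - 1
            if pb <= 0:
                break
            if M[i, j] == pb:
                state = "M"
            elif X[i, j] == pb:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            ra.append(a[i - 1])
            rb.append("-")
            if M[i - 1, j] + go_ge == X[i, j]:
                state = "M"
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            # Y chains derive from M via the scan; find the chain start
            if M[i, j - 1] + go_ge == Y[i, j]:
                state = "M"
            j -= 1
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    a_start, b_start = i, j
    a_end = a_start + sum(c != "-" for c in aligned_a)
    b_end = b_start + sum(c != "-" for c in aligned_b)
    return LocalAlignment(score, a_start, a_end, b_start, b_end, aligned_a, aligned_b)


def nw_matrix(S: np.ndarray, gap: int) -> tuple[int, list[tuple[int | None, int | None]]]:
    """Global alignment over score matrix S (n x m) with linear gap penalty.

    Returns (score, path) where path is a list of (i, j) column pairs; None
    marks a gap on that side.  Ties prefer diagonal, then gap-in-b (up),
    then gap-in-a (left) — fixed for determinism.
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    js = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        A = np.empty(m + 1, dtype=np.int64)
        A[0] = H[i - 1, 0] + gap
        A[1:] = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] + gap)
        # H[i,j] = max_{k<=j} A[k] + gap*(j-k)
        H[i] = gap * js + np.maximum.accumulate(A - gap * js)
    score = int(H[n, m])

    path: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            path.append((i - 1, None))
            i -= 1
        else:
            path.append((None, j - 1))
            j -= 1
    path.reverse()
    return score, path


def nw_align(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, str, str]:
    """Global alignment of two sequences with linear gaps."""
    w = substitution_matrix(match, mismatch)
    S = w[np.ix_(encode(a), encode(b))] if a and b else np.zeros((len(a), len(b)), int)
    score, path = nw_matrix(S.astype(np.int64), gap)
    ra = "".join(a[i] if i is not None else "-" for i, _ in path)
    rb = "".join(b[j] if j is not None else "-" for _, j in path)
    return score, ra, rb
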