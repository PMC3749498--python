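"""Low-level alignment kernels (numba-compiled).

Smith-Waterman local alignment with affine gaps, in two flavours: a batch
score-only scan of one query against many subjects, and a full traceback
for a single pair.  Gap costs follow the BLAST convention: a gap of length
k costs ``gap_open + (k-1) * gap_extend``.

Also provides the ungapped sliding-window scorer used for position-specific
marker-profile scans.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def sw_score_batch(query, subjects_flat, starts, lengths, submat, gap_open, gap_extend):
    """Best local-alignment score of ``query`` against each subject.

    ``subjects_flat`` concatenates integer-encoded subjects; subject *k*
    occupies ``subjects_flat[starts[k]:starts[k]+lengths[k]]``.
    """
    n_sub = starts.shape[0]
    m = query.shape[0]
    n_sym = submat.shape[1]
    # per-symbol query profile, contiguous along the query axis
    prof = np.empty((n_sym, m), dtype=np.float64)
    for c in range(n_sym):
        for i in range(m):
            prof[c, i] = submat[query[i], c]
    scores = np.zeros(n_sub, dtype=np.float64)
    H = np.zeros(m + 1, dtype=np.float64)
    E = np.zeros(m + 1, dtype=np.float64)
    for k in range(n_sub):
        best = 0.0
        for i in range(m + 1):
            H[i] = 0.0
            E[i] = 0.0
        s0 = starts[k]
        n = lengths[k]
        for j in range(n):
            row = prof[subjects_flat[s0 + j]]
            diag = 0.0  # H[i-1][j-1], starts as H[0][j-1] = 0
            f = 0.0  # F[i][j]: gap in subject (vertical)
            for i in range(1, m + 1):
                e = max(E[i] - gap_extend, H[i] - gap_open)
                E[i] = e
                f = max(f - gap_extend, H[i - 1] - gap_open)
                h = diag + row[i - 1]
                h = max(h, e)
                h = max(h, f)
                h = max(h, 0.0)
                diag = H[i]
                H[i] = h
                best = max(best, h)
        scores[k] = best
    return scores


@njit(cache=True, fastmath=True)
def sw_traceback(query, subject, submat, gap_open, gap_extend):
    """Full Smith-Waterman DP with traceback for one pair.

    Returns (score, q_start, q_end, s_start, s_end, matches, aln_len) with
    0-based half-open ranges on query and subject.
    """
    m = query.shape[0]
    n = subject.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), -1e30, dtype=np.float64)
    F = np.full((m + 1, n + 1), -1e30, dtype=np.float64)
    # pointers for H: 0 stop, 1 diag, 2 from E (gap in query/horizontal), 3 from F
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    e_open = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 if E came from H
    f_open = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_extend
            t = H[i, j - 1] - gap_open
            if t >= e:
                E[i, j] = t
                e_open[i, j] = 1
            else:
                E[i, j] = e
            f = F[i - 1, j] - gap_extend
            t = H[i - 1, j] - gap_open
            if t >= f:
                F[i, j] = t
                f_open[i, j] = 1
            else:
                F[i, j] = f
            h = H[i - 1, j - 1] + submat[query[i - 1], subject[j - 1]]
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # walk back from (bi, bj)
    i = bi
    j = bj
    matches = 0
    aln_len = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            aln_len += 1
            if query[i - 1] == subject[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            # gap in query: consume subject residues
            while True:
                aln_len += 1
                opened = e_open[i, j]
                j -= 1
                if opened == 1:
                    break
        else:
            while True:
                aln_len += 1
                opened = f_open[i, j]
                i -= 1
                if opened == 1:
                    break
    return best, i, bi, j, bj, matches, aln_len


@njit(cache=True, fastmath=True)
def pssm_best_window(pep, pssm):
    """Best ungapped alignment score of a peptide against a position-score
    matrix, over all offsets (partial overlaps allowed)."""
    P = pep.shape[0]
    L = pssm.shape[0]
    best = -1e30
    for off in range(-(P - 1), L):
        s = 0.0
        lo = 0 if off >= 0 else -off
        hi = P if off + P <= L else L - off
        for i in range(lo, hi):
            s += pssm[i + off, pep[i]]
        if s > best:
            best = s
    return best
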