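"""Numba kernels for affine-gap local alignment of sequences to profiles.

Gap cost convention: a gap run of length g costs ``gap_open + g * gap_extend``.
Sequence codes are 0..19 (alphabet order of :data:`phyloscreen.pssm.ALPHABET`);
any code >= 20 is an unknown residue and scores 0 in every column.
"""

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def sw_fill(scores, seq, gap_open, gap_ext):
    """Full DP with pointers. Returns matrices and the best match cell.

    States: M (residue aligned to a profile column), X (profile column
    skipped), Y (sequence residue skipped).  Local alignments start and end
    in M; ties prefer diagonal-M > diagonal-X > diagonal-Y > fresh start.
    """
    L = scores.shape[0]
    n = seq.shape[0]
    M = np.full((L + 1, n + 1), NEG)
    X = np.full((L + 1, n + 1), NEG)
    Y = np.full((L + 1, n + 1), NEG)
    pM = np.zeros((L + 1, n + 1), dtype=np.int8)
    pX = np.zeros((L + 1, n + 1), dtype=np.int8)
    pY = np.zeros((L + 1, n + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            c = seq[j - 1]
            s = 0.0 if c >= 20 else scores[i - 1, c]
            prev = M[i - 1, j - 1]
            bp = 1
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                bp = 2
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                bp = 3
            if prev < 0.0:
                prev = 0.0
                bp = 0
            M[i, j] = s + prev
            pM[i, j] = bp
            a = M[i - 1, j] - gap_open - gap_ext
            b = X[i - 1, j] - gap_ext
            if a >= b:
                X[i, j] = a
                pX[i, j] = 1
            else:
                X[i, j] = b
                pX[i, j] = 2
            a = M[i, j - 1] - gap_open - gap_ext
            b = Y[i, j - 1] - gap_ext
            if a >= b:
                Y[i, j] = a
                pY[i, j] = 1
            else:
                Y[i, j] = b
                pY[i, j] = 2
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return pM, pX, pY, best, bi, bj


@njit(cache=True)
def sw_score_only(scores, seq, gap_open, gap_ext):
    """Best local score only, O(n) memory."""
    L = scores.shape[0]
    n = seq.shape[0]
    Mp = np.full(n + 1, NEG)
    Xp = np.full(n + 1, NEG)
    Yp = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, L + 1):
        Mc = np.full(n + 1, NEG)
        Xc = np.full(n + 1, NEG)
        Yc = np.full(n + 1, NEG)
        for j in range(1, n + 1):
            c = seq[j - 1]
            s = 0.0 if c >= 20 else scores[i - 1, c]
            prev = Mp[j - 1]
            if Xp[j - 1] > prev:
                prev = Xp[j - 1]
            if Yp[j - 1] > prev:
                prev = Yp[j - 1]
            if prev < 0.0:
                prev = 0.0
            Mc[j] = s + prev
            a = Mp[j] - gap_open - gap_ext
            b = Xp[j] - gap_ext
            Xc[j] = a if a >= b else b
            a = Mc[j - 1] - gap_open - gap_ext
            b = Yc[j - 1] - gap_ext
            Yc[j] = a if a >= b else b
            if Mc[j] > best:
                best = Mc[j]
        Mp, Xp, Yp = Mc, Xc, Yc
    return best


@njit(cache=True)
def sw_score_batch(scores, seqs, gap_open, gap_ext):
    """Best local scores for a batch of equal-length sequences (rows)."""
    out = np.empty(seqs.shape[0])
    for r in range(seqs.shape[0]):
        out[r] = sw_score_only(scores, seqs[r], gap_open, gap_ext)
    return out
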