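"""Compiled inner loops for sequence comparison.

Words are encoded as int32 symbol indices; batched variants take padded 2D
arrays with an explicit length vector.  The affine-gap aligner is the
three-state (match / gap-in-x / gap-in-y) dynamic program with transitions
between the two gap states forbidden, which enforces the licit-alignment
constraint: a gap in one string is never immediately followed by a gap in
the other.  A gap run is charged ``gap_open`` for its first column and
``gap_extend`` for each subsequent column.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


@njit(cache=False)
def affine_score(x, y, S, gap_open, gap_extend):
    """Maximal aggregate score over all licit alignments of x and y."""
    m, n = len(x), len(y)
    M = np.full((m + 1, n + 1), NEG_INF)
    GX = np.full((m + 1, n + 1), NEG_INF)  # gap in y (consuming x)
    GY = np.full((m + 1, n + 1), NEG_INF)  # gap in x (consuming y)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        GX[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, n + 1):
        GY[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best = M[i - 1, j - 1]
            if GX[i - 1, j - 1] > best:
                best = GX[i - 1, j - 1]
            if GY[i - 1, j - 1] > best:
                best = GY[i - 1, j - 1]
            M[i, j] = best + S[x[i - 1], y[j - 1]]
            a = M[i - 1, j] + gap_open
            b = GX[i - 1, j] + gap_extend
            GX[i, j] = a if a > b else b
            a = M[i, j - 1] + gap_open
            b = GY[i, j - 1] + gap_extend
            GY[i, j] = a if a > b else b
    best = M[m, n]
    if GX[m, n] > best:
        best = GX[m, n]
    if GY[m, n] > best:
        best = GY[m, n]
    return best


@njit(cache=False)
def affine_align_pairs(x, y, S, gap_open, gap_extend, out):
    """Affine alignment with traceback; fills ``out`` with aligned index pairs.

    ``out`` must be an int32 array of shape (len(x)+len(y), 2).  Gap positions
    are encoded as -1.  Tie preference in traceback: match > gap-in-x >
    gap-in-y.  Returns (number of columns, score).
    """
    m, n = len(x), len(y)
    M = np.full((m + 1, n + 1), NEG_INF)
    GX = np.full((m + 1, n + 1), NEG_INF)
    GY = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        GX[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, n + 1):
        GY[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best = M[i - 1, j - 1]
            if GX[i - 1, j - 1] > best:
                best = GX[i - 1, j - 1]
            if GY[i - 1, j - 1] > best:
                best = GY[i - 1, j - 1]
            M[i, j] = best + S[x[i - 1], y[j - 1]]
            a = M[i - 1, j] + gap_open
            b = GX[i - 1, j] + gap_extend
            GX[i, j] = a if a > b else b
            a = M[i, j - 1] + gap_open
            b = GY[i, j - 1] + gap_extend
            GY[i, j] = a if a > b else b
    # traceback from the best final state, preference M > GX > GY
    i, j = m, n
    score = M[m, n]
    state = 0
    if GX[m, n] > score:
        score, state = GX[m, n], 1
    if GY[m, n] > score:
        score, state = GY[m, n], 2
    k = 0
    while i > 0 or j > 0:
        if state == 0:
            out[k, 0] = i - 1
            out[k, 1] = j - 1
            prev = M[i - 1, j - 1]
            nstate = 0
            if GX[i - 1, j - 1] > prev:
                prev, nstate = GX[i - 1, j - 1], 1
            if GY[i - 1, j - 1] > prev:
                prev, nstate = GY[i - 1, j - 1], 2
            i -= 1
            j -= 1
            state = nstate
        elif state == 1:
            out[k, 0] = i - 1
            out[k, 1] = -1
            # open (from M) preferred over extend on ties
            if M[i - 1, j] + gap_open >= GX[i - 1, j] + gap_extend:
                state = 0
            else:
                state = 1
            i -= 1
        else:
            out[k, 0] = -1
            out[k, 1] = j - 1
            if M[i, j - 1] + gap_open >= GY[i, j - 1] + gap_extend:
                state = 0
            else:
                state = 2
            j -= 1
        k += 1
    # columns were written tail-first; reverse in place
    for a_ in range(k // 2):
        b_ = k - 1 - a_
        t0, t1 = out[a_, 0], out[a_, 1]
        out[a_, 0], out[a_, 1] = out[b_, 0], out[b_, 1]
        out[b_, 0], out[b_, 1] = t0, t1
    return k, score


@njit(cache=False)
def affine_score_matrix(wx, lx, wy, ly, S, gap_open, gap_extend):
    """All-pairs alignment scores between two padded word batches."""
    na, nb = wx.shape[0], wy.shape[0]
    out = np.empty((na, nb))
    for i in range(na):
        xi = wx[i, :lx[i]]
        for j in range(nb):
            out[i, j] = affine_score(xi, wy[j, :ly[j]], S, gap_open, gap_extend)
    return out


@njit(cache=False)
def edit_distance(x, y):
    """Plain unit-cost Levenshtein distance."""
    m, n = len(x), len(y)
    prev = np.empty(n + 1, dtype=np.int32)
    cur = np.empty(n + 1, dtype=np.int32)
    for j in range(n + 1):
        prev[j] = j
    for i in range(1, m + 1):
        cur[0] = i
        for j in range(1, n + 1):
            c = prev[j - 1]
            if x[i - 1] != y[j - 1]:
                c += 1
            d = prev[j] + 1
            if d < c:
                c = d
            d = cur[j - 1] + 1
            if d < c:
                c = d
            cur[j] = c
        prev, cur = cur, prev
    return prev[n]


@njit(cache=False)
def ldn_similarity_matrix(wx, lx, wy, ly):
    """All-pairs 1 - LDN similarity between two padded word batches."""
    na, nb = wx.shape[0], wy.shape[0]
    out = np.empty((na, nb))
    for i in range(na):
        xi = wx[i, :lx[i]]
        for j in range(nb):
            d = edit_distance(xi, wy[j, :ly[j]])
            longer = lx[i] if lx[i] > ly[j] else ly[j]
            out[i, j] = 1.0 - d / longer
    return out


def pad_words(encoded_words) -> tuple:
    """Stack variable-length int32 code arrays into a padded batch."""
    n = len(encoded_words)
    lens = np.fromiter((len(w) for w in encoded_words), dtype=np.int32, count=n)
    wmax = int(lens.max()) if n else 1
    out = np.zeros((n, max(wmax, 1)), dtype=np.int32)
    for i, w in enumerate(encoded_words):
        out[i, :len(w)] = w
    return out, lens
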