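"""Numba dynamic-programming kernels for seed extension.

Two kernels: a banded Smith-Waterman local aligner with affine gaps (used for
seed ranking and local extension) and a semi-global edit-distance aligner
(whole read against a reference window, free leading/trailing reference gaps)
used for the rescue stages.  Both return explicit tracebacks as op-code
arrays (0 = M, 1 = I consuming read, 2 = D consuming reference) so the caller
can build CIGAR strings.

A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
``N`` is encoded as 4 and never matches, not even another ``N``.

All tie-breaks are fixed (first-best end cell in row-major order; traceback
prefers M, then D, then I) so alignment output is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes (A,C,G,T -> 0..3, anything else -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def sw_affine_banded(read, ref, match, mismatch, gap_open, gap_extend, lo, hi):
    """Banded local alignment; cells with ``lo <= j - i <= hi`` are computed.

    Returns (score, read_start, read_end, ref_start, ref_end, ops, n_ops)
    with half-open 0-based coordinates into read and ref.  A score of 0 means
    no positive-scoring alignment exists (empty traceback).
    """
    m = read.shape[0]
    n = ref.shape[0]
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    tb_h = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_e = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_f = np.zeros((m + 1, n + 1), dtype=np.int8)

    for j in range(n + 1):
        if lo <= j <= hi:
            H[0, j] = 0
    for i in range(m + 1):
        if lo <= -i <= hi:
            H[i, 0] = 0

    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        jlo = i + lo
        if jlo < 1:
            jlo = 1
        jhi = i + hi
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            # gap in read (consume ref, op D)
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                tb_e[i, j] = 1
            else:
                E[i, j] = e_open
                tb_e[i, j] = 0
            # gap in ref (consume read, op I)
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                tb_f[i, j] = 1
            else:
                F[i, j] = f_open
                tb_f[i, j] = 0
            a = read[i - 1]
            b = ref[j - 1]
            if a == b and a != 4:
                sub = match
            else:
                sub = mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0
            t = 0
            if diag > h:
                h = diag
                t = 1
            if E[i, j] > h:
                h = E[i, j]
                t = 2
            if F[i, j] > h:
                h = F[i, j]
                t = 3
            H[i, j] = h
            tb_h[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j

    ops = np.empty(m + n, dtype=np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0: in H, 1: in E, 2: in F
    while True:
        if state == 0:
            t = tb_h[i, j]
            if t == 0:
                break
            if t == 1:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif t == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 2
            k += 1
            came_ext = tb_e[i, j]
            j -= 1
            if came_ext == 0:
                state = 0
        else:
            ops[k] = 1
            k += 1
            came_ext = tb_f[i, j]
            i -= 1
            if came_ext == 0:
                state = 0
    # ops were collected end-to-start; reverse in place
    for t in range(k // 2):
        tmp = ops[t]
        ops[t] = ops[k - 1 - t]
        ops[k - 1 - t] = tmp
    return best, i, bi, j, bj, ops, k


@njit(cache=True)
def semiglobal_edit(read, ref):
    """Whole-read alignment in a window, minimizing edit distance.

    Leading and trailing reference positions are free; the read is consumed
    end to end.  Returns (edits, ref_start, ref_end, ops, n_ops), choosing the
    leftmost minimal end column and a deterministic traceback (M > I > D).
    """
    m = read.shape[0]
    n = ref.shape[0]
    D = np.empty((m + 1, n + 1), dtype=np.int64)
    for j in range(n + 1):
        D[0, j] = 0
    for i in range(1, m + 1):
        D[i, 0] = i
        for j in range(1, n + 1):
            a = read[i - 1]
            b = ref[j - 1]
            if a == b and a != 4:
                cost = 0
            else:
                cost = 1
            v = D[i - 1, j - 1] + cost
            up = D[i - 1, j] + 1
            if up < v:
                v = up
            left = D[i, j - 1] + 1
            if left < v:
                v = left
            D[i, j] = v

    bj = 0
    best = D[m, 0]
    for j in range(1, n + 1):
        if D[m, j] < best:
            best = D[m, j]
            bj = j

    ops = np.empty(m + n, dtype=np.int8)
    k = 0
    i = m
    j = bj
    while i > 0:
        if j > 0:
            a = read[i - 1]
            b = ref[j - 1]
            if a == b and a != 4:
                cost = 0
            else:
                cost = 1
            if D[i, j] == D[i - 1, j - 1] + cost:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
                continue
        if D[i, j] == D[i - 1, j] + 1:
            ops[k] = 1
            k += 1
            i -= 1
            continue
        ops[k] = 2
        k += 1
        j -= 1
    for t in range(k // 2):
        tmp = ops[t]
        ops[t] = ops[k - 1 - t]
        ops[k - 1 - t] = tmp
    return best, j, bj, ops, k


def warmup() -> None:
    """Trigger JIT compilation once (called before forking workers)."""
    r = encode("ACGT")
    sw_affine_banded(r, r, 1, -3, -5, -2, -8, 8)
    semiglobal_edit(r, r)
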