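"""Independent brute-force oracles used by the tests.

These deliberately avoid every code path of the package under test: maximal
exact matches are found by run-length analysis of per-diagonal equality
vectors, local alignment by a textbook full-matrix Smith-Waterman (score
only), and semi-global edit counts by edlib's infix (HW) mode.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_mems(genome: str, read: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal exact matches (read_offset, genome_pos, length), one strand.

    Scans every diagonal of the read x genome comparison matrix and extracts
    maximal runs of equality; N never matches.
    """
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    n_char = ord("N")
    out: set[tuple[int, int, int]] = set()
    for d in range(-(len(r) - 1), len(g)):
        i0 = max(0, -d)
        i1 = min(len(r), len(g) - d)
        if i1 - i0 < min_len:
            continue
        seg_r = r[i0:i1]
        seg_g = g[i0 + d : i1 + d]
        eq = ((seg_r == seg_g) & (seg_r != n_char)).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_len:
                out.add((int(i0 + s), int(i0 + s + d), int(e - s)))
    return out


def brute_mems_both_strands(genome: str, read: str, min_len: int):
    """(strand, read_offset, genome_pos, length) tuples, offsets in the
    oriented read (reverse complement for '-')."""
    fwd = {("+",) + t for t in brute_mems(genome, read, min_len)}
    rev = {("-",) + t for t in brute_mems(genome, rc(read), min_len)}
    return fwd | rev


def brute_kmer_hits(genome: str, read: str, k: int):
    """Exhaustive window scan for the read's non-overlapping k-mers, one strand."""
    out = set()
    for i in range(0, len(read) - k + 1, k):
        pat = read[i : i + k]
        if "N" in pat:
            continue
        for p in range(len(genome) - k + 1):
            win = genome[p : p + k]
            if win == pat and "N" not in win:
                out.add((i, p))
    return out


def sw_score(a: str, b: str, match: int, mismatch: int, gap_open: int,
             gap_extend: int) -> int:
    """Unbanded affine-gap local alignment score, full DP matrix.

    Gap of length L costs gap_open + L * gap_extend.
    """
    m, n = len(a), len(b)
    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        E[i, 1:] = NEG
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            ai, bj = a[i - 1], b[j - 1]
            sub = match if (ai == bj and ai != "N") else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    return int(H.max())


def sliding_edit_distance(read: str, window: str) -> int:
    """Minimal edit distance of the read over all placements in the window."""
    import edlib

    res = edlib.align(read, window, mode="HW", task="distance")
    return res["editDistance"]
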