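"""Genome index and exact-match seeding.

The index holds the genome once, as a single concatenated string (multi-record
FASTA records are joined with an ``N`` spacer so no exact match can span a
record boundary), together with a suffix array and a k-mer position table.
Seeding works on this concatenated coordinate system; per-record offsets are
kept for translating hits back to (reference name, local position).

Two seed kinds are produced, mirroring the hybrid seeding of sensitive
seed-and-extend aligners:

* **MEM seeds** — maximal exact matches between read and genome: exact matches
  that cannot be extended on either side without a mismatch, an ambiguous
  base, or a boundary.
* **k-mer seeds** — exact occurrences of the read's non-overlapping k-mers,
  used as a fallback when MEM seeding fails to produce a qualified alignment.

Reverse-strand matches are found by seeding the reverse complement of the
read; the genome is stored once.  For a ``-`` seed, ``read_offset`` indexes
into the reverse-complemented (oriented) read, which is also the orientation
in which downstream extension and SAM emission operate.

``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "Seed",
    "ReferenceIndex",
    "build_index",
    "build_suffix_array",
    "find_mem_seeds",
    "find_kmer_seeds",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Seed:
    """Exact-match anchor between a read offset and a genome position.

    ``read_offset`` is 0-based into the oriented read (the read itself for
    strand ``+``, its reverse complement for strand ``-``); ``genome_pos`` is
    0-based into the concatenated genome.  ``rank_score`` is filled in by seed
    ranking (the banded local-alignment score of the read around the seed).
    """

    read_offset: int
    genome_pos: int
    length: int
    kind: str  # "MEM" | "KMER"
    strand: str  # "+" | "-"
    rank_score: int = 0
    # extension cache, populated by alignment_core.rank_seeds
    _ext: object = field(default=None, repr=False, compare=False)

    def sort_key(self) -> tuple:
        return (self.read_offset, self.genome_pos, 0 if self.strand == "+" else 1)


def build_suffix_array(seq: str) -> np.ndarray:
    """Suffix array of ``seq + sentinel`` by prefix doubling (lexsort-based).

    Returns a permutation of ``[0, len(seq)]``; index ``len(seq)`` is the
    empty suffix (the sentinel sorts before every base).
    """
    data = np.frombuffer(seq.encode("ascii") + b"\x00", dtype=np.uint8)
    n = data.size
    rank = data.astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        new_rank = np.zeros(n, dtype=np.int64)
        r = rank[order]
        s = second[order]
        boundary = np.empty(n, dtype=bool)
        boundary[0] = False
        boundary[1:] = (r[1:] != r[:-1]) | (s[1:] != s[:-1])
        new_rank[order] = np.cumsum(boundary)
        rank = new_rank
        sa = order
        if rank[order[-1]] == n - 1:
            break
        k *= 2
    return sa


@dataclass
class ReferenceIndex:
    """In-memory genome plus suffix array and k-mer lookup table."""

    name: str
    sequence: str  # concatenated records, 'N' spacer between records
    suffix_array: np.ndarray
    kmer_table: dict[str, np.ndarray]
    k: int
    record_names: list[str]
    record_offsets: list[int]  # start of each record in `sequence`
    record_lengths: list[int]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def references(self) -> list[tuple[str, int]]:
        return list(zip(self.record_names, self.record_lengths))

    def ref_lengths(self) -> dict[str, int]:
        return dict(self.references())

    def locate(self, genome_pos: int) -> tuple[str, int]:
        """Translate a concatenated coordinate to (record name, local 0-based pos)."""
        i = bisect_right(self.record_offsets, genome_pos) - 1
        off = genome_pos - self.record_offsets[i]
        if off >= self.record_lengths[i]:
            raise ValueError(f"position {genome_pos} falls in a record spacer")
        return self.record_names[i], off

    def record_bounds(self, genome_pos: int) -> tuple[int, int]:
        """Concatenated-coordinate [start, end) of the record containing pos."""
        i = bisect_right(self.record_offsets, genome_pos) - 1
        start = self.record_offsets[i]
        return start, start + self.record_lengths[i]

    # -- suffix-array pattern search ---------------------------------------

    def sa_find(self, pattern: str) -> np.ndarray:
        """Sorted genome positions of all exact occurrences of ``pattern``."""
        if not pattern or "N" in pattern:
            return np.empty(0, dtype=np.int64)
        sa, seq = self.suffix_array, self.sequence
        m = len(pattern)

        lo, hi = 0, sa.size
        while lo < hi:  # first suffix >= pattern
            mid = (lo + hi) // 2
            if seq[sa[mid] : sa[mid] + m] < pattern:
                lo = mid + 1
            else:
                hi = mid
        start = lo
        hi = sa.size
        while lo < hi:  # first suffix with prefix > pattern
            mid = (lo + hi) // 2
            if seq[sa[mid] : sa[mid] + m] <= pattern:
                lo = mid + 1
            else:
                hi = mid
        hits = np.sort(sa[start:lo])
        # exclude matches overlapping an ambiguous base (N never matches)
        if hits.size:
            keep = [p for p in hits if "N" not in seq[p : p + m]]
            hits = np.asarray(keep, dtype=np.int64)
        return hits


def build_index(fasta_path: str | os.PathLike, k: int = 13) -> ReferenceIndex:
    """Load a FASTA reference and build suffix array plus k-mer table.

    Multiple records are concatenated with a single ``N`` spacer, which no
    seed can cross because ``N`` never matches.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = list(SeqIO.parse(os.fspath(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {fasta_path}")
    names: list[str] = []
    offsets: list[int] = []
    lengths: list[int] = []
    parts: list[str] = []
    pos = 0
    for rec in records:
        seq = str(rec.seq).upper()
        if parts:
            parts.append("N")
            pos += 1
        names.append(rec.id)
        offsets.append(pos)
        lengths.append(len(seq))
        parts.append(seq)
        pos += len(seq)
    sequence = "".join(parts)
    if len(sequence) < k:
        raise ValueError(f"reference length {len(sequence)} shorter than k={k}")
    sa = build_suffix_array(sequence)

    table: dict[str, list[int]] = {}
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if "N" in kmer:
            continue
        table.setdefault(kmer, []).append(i)
    kmer_table = {km: np.asarray(v, dtype=np.int64) for km, v in table.items()}
    return ReferenceIndex(
        name=os.path.basename(os.fspath(fasta_path)),
        sequence=sequence,
        suffix_array=sa,
        kmer_table=kmer_table,
        k=k,
        record_names=names,
        record_offsets=offsets,
        record_lengths=lengths,
    )


def _extend_maximal(
    genome: str, read: str, i: int, p: int
) -> tuple[int, int, int] | None:
    """Maximal exact extension of the anchor (read[i] vs genome[p]).

    Returns (read_start, genome_start, length) or None when the anchor itself
    mismatches (e.g. on an N).
    """
    a, b = read[i], genome[p]
    if a != b or a == "N":
        return None
    lo = 0
    while i - lo - 1 >= 0 and p - lo - 1 >= 0:
        c = read[i - lo - 1]
        if c != genome[p - lo - 1] or c == "N":
            break
        lo += 1
    hi = 1
    while i + hi < len(read) and p + hi < len(genome):
        c = read[i + hi]
        if c != genome[p + hi] or c == "N":
            break
        hi += 1
    return i - lo, p - lo, lo + hi


def _covered(intervals: list[tuple[int, int]], i: int) -> bool:
    idx = bisect_right(intervals, (i, float("inf"))) - 1
    return idx >= 0 and intervals[idx][1] > i


def _mem_seeds_one_strand(
    index: ReferenceIndex, oriented: str, min_mem_length: int, strand: str
) -> list[Seed]:
    """Enumerate MEMs of length >= min_mem_length for one read orientation.

    Candidate anchors come from exact matches of length ``s = min(k,
    min_mem_length)`` at every read offset (k-mer table when s == k, suffix
    array otherwise); every MEM of length >= min_mem_length contains such an
    anchor, so the enumeration is exhaustive.  Each candidate is extended
    maximally and de-duplicated per diagonal.
    """
    genome = index.sequence
    L = len(oriented)
    s = min(index.k, min_mem_length)
    seen: dict[int, list[tuple[int, int]]] = {}  # diagonal -> covered read intervals
    seeds: list[Seed] = []
    for i in range(L - s + 1):
        probe = oriented[i : i + s]
        if "N" in probe:
            continue
        if s == index.k:
            positions = index.kmer_table.get(probe)
            if positions is None:
                continue
        else:
            positions = index.sa_find(probe)
        for p in positions:
            d = int(p) - i
            ivals = seen.setdefault(d, [])
            if _covered(ivals, i):
                continue
            ext = _extend_maximal(genome, oriented, i, int(p))
            if ext is None:
                continue
            ri, gp, ln = ext
            ivals.insert(bisect_left(ivals, (ri, ri + ln)), (ri, ri + ln))
            if ln >= min_mem_length:
                seeds.append(Seed(ri, gp, ln, "MEM", strand))
    return seeds


def find_mem_seeds(
    index: ReferenceIndex, read_sequence: str, min_mem_length: int = 19
) -> list[Seed]:
    """All maximal exact matches of length >= ``min_mem_length``, both strands.

    Deterministically ordered by (read_offset, genome_pos, strand with ``+``
    first); no duplicates.
    """
    read = read_sequence.upper()
    if len(read) < min_mem_length:
        raise ValueError(
            f"read length {len(read)} < min_mem_length {min_mem_length}"
        )
    seeds = _mem_seeds_one_strand(index, read, min_mem_length, "+")
    seeds += _mem_seeds_one_strand(index, revcomp(read), min_mem_length, "-")
    seeds.sort(key=Seed.sort_key)
    return seeds


def _kmer_seeds_one_strand(
    index: ReferenceIndex, oriented: str, k: int, strand: str
) -> list[Seed]:
    seeds: list[Seed] = []
    for i in range(0, len(oriented) - k + 1, k):  # non-overlapping sampling
        probe = oriented[i : i + k]
        if "N" in probe:
            continue
        if k == index.k:
            positions = index.kmer_table.get(probe)
            if positions is None:
                continue
        else:
            positions = index.sa_find(probe)
        for p in positions:
            seeds.append(Seed(i, int(p), k, "KMER", strand))
    return seeds


def find_kmer_seeds(index: ReferenceIndex, read_sequence: str, k: int | None = None) -> list[Seed]:
    """Exact occurrences of the read's non-overlapping k-mers, both strands."""
    if k is None:
        k = index.k
    read = read_sequence.upper()
    if k > len(read):
        raise ValueError(f"k={k} exceeds read length {len(read)}")
    seeds = _kmer_seeds_one_strand(index, read, k, "+")
    seeds += _kmer_seeds_one_strand(index, revcomp(read), k, "-")
    seeds.sort(key=Seed.sort_key)
    return seeds
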