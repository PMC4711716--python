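"""Seed-and-extend alignment pipelines (single-end and paired-end).

The single-end cascade mirrors a sensitive hybrid-seeding aligner:

1. enumerate MEM seeds, rank them by banded local-alignment score, extend the
   top seeds and report the best *qualified* local alignment;
2. otherwise attempt a semi-global rescue from the same ranked seeds;
3. otherwise repeat both steps from exact-match k-mer seeds;
4. otherwise report the read as unaligned.

The paired-end cascade ranks MEM seeds of both mates, pairs top-ranked seeds
under the insert-size constraint with a weighted seed-pairing heuristic
(weight = sum of the two seeds' rank scores), extends qualified seed pairs,
and falls back to independent single-end alignment plus mate rescue — a
semi-global search of the unqualified mate inside the reference window
implied by its partner's position and the insert bounds.

Qualification is threshold-based: local alignments qualify on score and read
coverage, semi-global and rescue alignments on edit fraction.  All
comparisons are >= / <= so a boundary value passes.  Every tie-break is total
(score descending, then position ascending, then forward strand first), so
the pipeline is deterministic and serial/parallel runs produce identical
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import _kernels
from .io_formats import ReadRecord
from .reference_index import (
    ReferenceIndex,
    Seed,
    find_kmer_seeds,
    find_mem_seeds,
    revcomp,
)

__all__ = [
    "ScoringParams",
    "QualificationParams",
    "AlignmentRecord",
    "SeedPair",
    "local_align",
    "semiglobal_align",
    "rank_seeds",
    "is_qualified",
    "align_single",
    "pair_seeds",
    "rescue_mate",
    "align_paired",
    "STAGES",
]

STAGES = (
    "LOCAL",
    "SEMIGLOBAL",
    "KMER_LOCAL",
    "KMER_SEMIGLOBAL",
    "MATE_RESCUE",
    "UNALIGNED",
)
_LOCAL_STAGES = {"LOCAL", "KMER_LOCAL"}
_EDIT_STAGES = {"SEMIGLOBAL", "KMER_SEMIGLOBAL", "MATE_RESCUE"}

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap scoring for seed extension.

    A gap of length L costs ``gap_open + L * gap_extend``.  ``band_width``
    bounds how far the DP may wander off the seed diagonal; extension windows
    are sized so the band always covers the seed.
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    band_width: int = 32

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 \
                or self.gap_extend >= 0 or self.band_width < 1:
            raise ValueError("invalid scoring parameters")


@dataclass(frozen=True)
class QualificationParams:
    """Thresholds deciding whether a candidate alignment is reported.

    Local stages qualify when ``score >= min_score_fraction * match *
    read_len`` and the aligned read bases (CIGAR M+I) cover at least
    ``min_coverage_fraction`` of the read.  Semi-global and mate-rescue
    stages qualify when the edit count is at most ``max_edit_fraction *
    read_len``.  ``top_n_seeds`` limits how many ranked seeds are extended;
    ``insert_min``/``insert_max`` bound the outer fragment span in paired
    mode.
    """

    min_score_fraction: float = 0.30
    min_coverage_fraction: float = 0.80
    max_edit_fraction: float = 0.10
    top_n_seeds: int = 8
    insert_min: int = 100
    insert_max: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.min_score_fraction <= 1):
            raise ValueError("min_score_fraction must be in (0, 1]")
        if not (0 < self.min_coverage_fraction <= 1):
            raise ValueError("min_coverage_fraction must be in (0, 1]")
        if not (0 <= self.max_edit_fraction < 1):
            raise ValueError("max_edit_fraction must be in [0, 1)")
        if self.top_n_seeds < 1:
            raise ValueError("top_n_seeds must be >= 1")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")


@dataclass
class AlignmentRecord:
    """One read's mapping result, ready for SAM serialization.

    ``pos`` is the 0-based leftmost position on ``ref_name`` (None when
    unaligned).  ``seq``/``qual`` are stored in alignment orientation (reverse
    complemented for ``-`` strand records), matching SAM conventions.  The
    private ``g_start``/``g_end`` keep concatenated genome coordinates for
    insert-size arithmetic.
    """

    read_id: str
    ref_name: str | None
    pos: int | None
    strand: str
    cigar: str | None
    score: int
    stage: str
    qualified: bool
    mapq: int
    seq: str
    qual: str
    edits: int | None = None
    flag: int = 0
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    g_start: int = field(default=-1, repr=False)
    g_end: int = field(default=-1, repr=False)

    @property
    def aligned(self) -> bool:
        return self.stage != "UNALIGNED"


@dataclass
class SeedPair:
    """Two seeds, one per mate, in FR orientation with an in-range insert."""

    seed1: Seed
    seed2: Seed
    pair_weight: int
    implied_insert: int


# ---------------------------------------------------------------------------
# pairwise alignment primitives


def _ops_to_cigar(ops, n_ops: int, clip_left: int = 0, clip_right: int = 0) -> str:
    parts: list[str] = []
    if clip_left:
        parts.append(f"{clip_left}S")
    letters = "MID"
    run_op = -1
    run_len = 0
    for t in range(n_ops):
        op = ops[t]
        if op == run_op:
            run_len += 1
        else:
            if run_len:
                parts.append(f"{run_len}{letters[run_op]}")
            run_op = op
            run_len = 1
    if run_len:
        parts.append(f"{run_len}{letters[run_op]}")
    if clip_right:
        parts.append(f"{clip_right}S")
    return "".join(parts)


def _alignment_stats(ops, n_ops: int, read: str, ref: str, i0: int, j0: int):
    """(matches, mismatches, gap_bases, aligned_read_bases) along a traceback."""
    i, j = i0, j0
    matches = mismatches = gaps = read_bases = 0
    for t in range(n_ops):
        op = ops[t]
        if op == 0:
            a, b = read[i], ref[j]
            if a == b and a != "N":
                matches += 1
            else:
                mismatches += 1
            i += 1
            j += 1
            read_bases += 1
        elif op == 1:
            gaps += 1
            i += 1
            read_bases += 1
        else:
            gaps += 1
            j += 1
    return matches, mismatches, gaps, read_bases


def local_align(read_seq: str, ref_window: str, scoring: ScoringParams):
    """Banded Smith-Waterman local alignment with affine gaps.

    Returns ``(score, pos_in_window, cigar)``; the CIGAR soft-clips the
    unaligned read prefix/suffix.  The band spans ``band_width`` diagonals on
    either side of the corridor between the sequence starts and ends, so a
    band at least as wide as the longer sequence reproduces unbanded DP.
    """
    if not read_seq or not ref_window:
        raise ValueError("local_align requires non-empty sequences")
    m, n = len(read_seq), len(ref_window)
    lo = -scoring.band_width + min(0, n - m)
    hi = scoring.band_width + max(0, n - m)
    score, i0, i1, j0, j1, ops, k = _kernels.sw_affine_banded(
        _kernels.encode(read_seq),
        _kernels.encode(ref_window),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
        lo,
        hi,
    )
    if k == 0:
        return 0, 0, f"{m}S"
    cigar = _ops_to_cigar(ops, k, clip_left=i0, clip_right=m - i1)
    return int(score), int(j0), cigar


def semiglobal_align(read_seq: str, ref_window: str, scoring: ScoringParams):
    """End-to-end alignment of the read inside a window, minimizing edits.

    Leading/trailing gaps are free on the reference only.  Returns
    ``(score, pos_in_window, cigar, edits)`` where ``edits`` is the minimal
    edit count (mismatches plus gap bases) and ``score`` re-scores that
    alignment with the affine scoring parameters.
    """
    if not read_seq:
        raise ValueError("semiglobal_align requires a non-empty read")
    if len(ref_window) < len(read_seq):
        raise ValueError(
            f"window length {len(ref_window)} shorter than read "
            f"length {len(read_seq)}"
        )
    edits, j0, j1, ops, k = _kernels.semiglobal_edit(
        _kernels.encode(read_seq), _kernels.encode(ref_window)
    )
    matches, mismatches, _, _ = _alignment_stats(
        ops, k, read_seq, ref_window, 0, int(j0)
    )
    score = matches * scoring.match + mismatches * scoring.mismatch
    run = 0
    for t in range(k):
        if ops[t] != 0:
            run += 1
        elif run:
            score += scoring.gap_open + run * scoring.gap_extend
            run = 0
    if run:
        score += scoring.gap_open + run * scoring.gap_extend
    cigar = _ops_to_cigar(ops, k)
    return int(score), int(j0), cigar, int(edits)


# ---------------------------------------------------------------------------
# seed ranking and extension


@dataclass
class _Extension:
    """Cached banded local extension of one seed's window."""

    score: int
    g_start: int
    g_end: int
    strand: str
    cigar: str
    aligned_read_bases: int
    edits: int
    window_start: int
    window_end: int


def _seed_window(index: ReferenceIndex, seed: Seed, read_len: int,
                 band: int) -> tuple[int, int]:
    """Extension window around the seed diagonal, clipped to record bounds."""
    lo, hi = index.record_bounds(seed.genome_pos)
    start = seed.genome_pos - seed.read_offset - band
    end = seed.genome_pos - seed.read_offset + read_len + 2 * band
    return max(start, lo), min(end, hi)


def _extend_seed(
    index: ReferenceIndex, read_seq: str, seed: Seed, scoring: ScoringParams
) -> _Extension:
    oriented = read_seq if seed.strand == "+" else revcomp(read_seq)
    ws, we = _seed_window(index, seed, len(oriented), scoring.band_width)
    window = index.sequence[ws:we]
    if not window:
        return _Extension(0, ws, ws, seed.strand, f"{len(oriented)}S",
                          0, len(oriented), ws, we)
    m = len(oriented)
    score, j0, cigar = local_align(oriented, window, scoring)
    if score == 0:
        return _Extension(0, ws, ws, seed.strand, cigar, 0, m, ws, we)
    # recover traceback stats for coverage / edit bookkeeping
    read_bases = ref_bases = clip_left = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "MI":
            read_bases += n
        if ch in "MD":
            ref_bases += n
        if ch == "S" and read_bases == 0:
            clip_left = n
    i0 = clip_left
    # walk for mismatch/gap counts
    matches = mismatches = gaps = 0
    i, j = i0, j0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "M":
            for t in range(n):
                a, b = oriented[i + t], window[j + t]
                if a == b and a != "N":
                    matches += 1
                else:
                    mismatches += 1
            i += n
            j += n
        elif ch == "I":
            gaps += n
            i += n
        elif ch == "D":
            gaps += n
            j += n
    return _Extension(
        score=score,
        g_start=ws + j0,
        g_end=ws + j0 + ref_bases,
        strand=seed.strand,
        cigar=cigar,
        aligned_read_bases=read_bases,
        edits=mismatches + gaps,
        window_start=ws,
        window_end=we,
    )


def rank_seeds(
    index: ReferenceIndex,
    read_seq: str,
    seeds: list[Seed],
    scoring: ScoringParams,
    top_n: int,
) -> list[Seed]:
    """Rank seeds by banded local-alignment score of their windows.

    Each seed's ``rank_score`` is set to the local alignment score of the
    (oriented) read against the seed's reference window.  Seeds are returned
    sorted by score descending — ties broken by (genome_pos, read_offset)
    ascending — and truncated to ``top_n``.  The extension itself is cached
    on the seed so later pipeline stages do not recompute the DP.
    """
    ranked = []
    for seed in seeds:
        ext = _extend_seed(index, read_seq, seed, scoring)
        ranked.append(replace(seed, rank_score=ext.score, _ext=ext))
    ranked.sort(key=lambda s: (-s.rank_score, s.genome_pos, s.read_offset))
    return ranked[:top_n]


def is_qualified(record: AlignmentRecord, read_len: int,
                 qual_params: QualificationParams, match: int = 1) -> bool:
    """Threshold test for reporting a candidate alignment.

    Local stages: score >= min_score_fraction * match * read_len AND aligned
    read bases >= min_coverage_fraction * read_len.  Semi-global and rescue
    stages: edits <= max_edit_fraction * read_len.  Boundary values pass.
    """
    if record.stage == "UNALIGNED":
        raise ValueError("is_qualified is undefined for UNALIGNED records")
    if record.stage in _LOCAL_STAGES:
        if record.score < qual_params.min_score_fraction * match * read_len:
            return False
        read_bases = 0
        num = ""
        for ch in record.cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch in "MI":
                    read_bases += int(num)
                num = ""
        return read_bases >= qual_params.min_coverage_fraction * read_len
    return record.edits <= qual_params.max_edit_fraction * read_len


# ---------------------------------------------------------------------------
# record construction


def _oriented_seq_qual(read: ReadRecord, strand: str) -> tuple[str, str]:
    if strand == "+":
        return read.sequence, read.quality or ""
    return revcomp(read.sequence), (read.quality or "")[::-1]


def _record_from_extension(
    read: ReadRecord, index: ReferenceIndex, ext: _Extension, stage: str
) -> AlignmentRecord:
    seq, qual = _oriented_seq_qual(read, ext.strand)
    ref_name, pos = index.locate(ext.g_start)
    return AlignmentRecord(
        read_id=read.id,
        ref_name=ref_name,
        pos=pos,
        strand=ext.strand,
        cigar=ext.cigar,
        score=ext.score,
        stage=stage,
        qualified=False,
        mapq=0,
        seq=seq,
        qual=qual,
        edits=ext.edits,
        flag=FLAG_REVERSE if ext.strand == "-" else 0,
        g_start=ext.g_start,
        g_end=ext.g_end,
    )


def _unaligned(read: ReadRecord) -> AlignmentRecord:
    return AlignmentRecord(
        read_id=read.id,
        ref_name=None,
        pos=None,
        strand="+",
        cigar=None,
        score=0,
        stage="UNALIGNED",
        qualified=False,
        mapq=0,
        seq=read.sequence,
        qual=read.quality or "",
        edits=None,
        flag=FLAG_UNMAPPED,
    )


def _mapq(candidates: list[AlignmentRecord], best_score: int) -> int:
    ties = sum(1 for c in candidates if c.score == best_score)
    return max(0, 60 - 10 * (ties - 1))


def _cand_sort_key(rec: AlignmentRecord):
    return (-rec.score, rec.g_start, 0 if rec.strand == "+" else 1)


def _dedupe(cands: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse candidates sharing a window (same start/strand), keeping the best."""
    best: dict[tuple[int, str], AlignmentRecord] = {}
    for c in cands:
        key = (c.g_start, c.strand)
        cur = best.get(key)
        if cur is None or _cand_sort_key(c) < _cand_sort_key(cur):
            best[key] = c
    return sorted(best.values(), key=_cand_sort_key)


def _local_candidates(
    read: ReadRecord, index: ReferenceIndex, ranked: list[Seed], stage: str
) -> list[AlignmentRecord]:
    cands = [
        _record_from_extension(read, index, s._ext, stage)
        for s in ranked
        if s._ext is not None and s._ext.score > 0
    ]
    return _dedupe(cands)


def _semiglobal_candidates(
    read: ReadRecord,
    index: ReferenceIndex,
    ranked: list[Seed],
    scoring: ScoringParams,
    stage: str,
) -> list[AlignmentRecord]:
    cands: list[AlignmentRecord] = []
    seen: set[tuple[int, str]] = set()
    for seed in ranked:
        ext = seed._ext
        ws, we = (ext.window_start, ext.window_end) if ext is not None else \
            _seed_window(index, seed, len(read.sequence), scoring.band_width)
        if (ws, seed.strand) in seen:
            continue
        seen.add((ws, seed.strand))
        oriented = read.sequence if seed.strand == "+" else revcomp(read.sequence)
        if we - ws < len(oriented):
            continue
        window = index.sequence[ws:we]
        score, j0, cigar, edits = semiglobal_align(oriented, window, scoring)
        ref_span = sum(
            int(n) for n, op in _iter_cigar(cigar) if op in "MD"
        )
        seq, qual = _oriented_seq_qual(read, seed.strand)
        ref_name, pos = index.locate(ws + j0)
        cands.append(
            AlignmentRecord(
                read_id=read.id,
                ref_name=ref_name,
                pos=pos,
                strand=seed.strand,
                cigar=cigar,
                score=score,
                stage=stage,
                qualified=False,
                mapq=0,
                seq=seq,
                qual=qual,
                edits=edits,
                flag=FLAG_REVERSE if seed.strand == "-" else 0,
                g_start=ws + j0,
                g_end=ws + j0 + ref_span,
            )
        )
    return _dedupe(cands)


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _pick_qualified(
    cands: list[AlignmentRecord],
    read_len: int,
    qual_params: QualificationParams,
    match: int,
) -> AlignmentRecord | None:
    qualified = [c for c in cands if is_qualified(c, read_len, qual_params, match)]
    if not qualified:
        return None
    best = qualified[0]  # candidates are pre-sorted by _cand_sort_key
    best.qualified = True
    best.mapq = _mapq(cands, best.score)
    return best


def align_single(
    read: ReadRecord,
    index: ReferenceIndex,
    scoring: ScoringParams,
    qual_params: QualificationParams,
    min_mem_length: int = 19,
    kmer_k: int | None = None,
) -> AlignmentRecord:
    """Single-end cascade: MEM local -> MEM semi-global -> k-mer local ->
    k-mer semi-global -> unaligned.

    Best = highest score; ties broken by smallest position, forward strand
    first.  Unaligned is a value, never an error.
    """
    ranked_mem: list[Seed] = []
    if len(read.sequence) >= min_mem_length:
        seeds = find_mem_seeds(index, read.sequence, min_mem_length)
        ranked_mem = rank_seeds(index, read.sequence, seeds, scoring,
                                qual_params.top_n_seeds)
    if ranked_mem:
        cands = _local_candidates(read, index, ranked_mem, "LOCAL")
        best = _pick_qualified(cands, len(read.sequence), qual_params, scoring.match)
        if best is not None:
            return best
        cands = _semiglobal_candidates(read, index, ranked_mem, scoring, "SEMIGLOBAL")
        best = _pick_qualified(cands, len(read.sequence), qual_params, scoring.match)
        if best is not None:
            return best
    k = kmer_k or index.k
    if len(read.sequence) >= k:
        seeds = find_kmer_seeds(index, read.sequence, k)
        ranked = rank_seeds(index, read.sequence, seeds, scoring,
                            qual_params.top_n_seeds)
        if ranked:
            cands = _local_candidates(read, index, ranked, "KMER_LOCAL")
            best = _pick_qualified(cands, len(read.sequence), qual_params,
                                   scoring.match)
            if best is not None:
                return best
            cands = _semiglobal_candidates(read, index, ranked, scoring,
                                           "KMER_SEMIGLOBAL")
            best = _pick_qualified(cands, len(read.sequence), qual_params,
                                   scoring.match)
            if best is not None:
                return best
    return _unaligned(read)


# ---------------------------------------------------------------------------
# paired-end


def _seed_span(seed: Seed, read_len: int) -> tuple[int, int]:
    """Genome span the oriented read would occupy if the seed were gapless."""
    start = seed.genome_pos - seed.read_offset
    return start, start + read_len


def pair_seeds(
    ranked1: list[Seed],
    ranked2: list[Seed],
    qual_params: QualificationParams,
    read_len1: int,
    read_len2: int,
) -> list[SeedPair]:
    """All FR seed combinations whose implied insert is within bounds.

    ``pair_weight`` is the sum of the two rank scores; pairs are sorted by
    weight descending, ties by distance of the implied insert from the middle
    of the allowed range, then by genome position for full determinism.
    """
    mid = (qual_params.insert_min + qual_params.insert_max) / 2
    pairs: list[SeedPair] = []
    for s1 in ranked1:
        a1, b1 = _seed_span(s1, read_len1)
        for s2 in ranked2:
            if s1.strand == s2.strand:  # FR orientation requires opposite strands
                continue
            a2, b2 = _seed_span(s2, read_len2)
            left = min(a1, a2)
            right = max(b1, b2)
            # the forward-strand mate must be the left one
            fwd_start = a1 if s1.strand == "+" else a2
            rev_start = a2 if s1.strand == "+" else a1
            if fwd_start > rev_start:
                continue
            insert = right - left
            if qual_params.insert_min <= insert <= qual_params.insert_max:
                pairs.append(SeedPair(s1, s2, s1.rank_score + s2.rank_score, insert))
    pairs.sort(
        key=lambda p: (
            -p.pair_weight,
            abs(p.implied_insert - mid),
            p.seed1.genome_pos,
            p.seed2.genome_pos,
        )
    )
    return pairs


def _pair_insert(r1: AlignmentRecord, r2: AlignmentRecord) -> int | None:
    """Outer-edge fragment span; None unless mates are FR on the same reference."""
    if not (r1.aligned and r2.aligned) or r1.ref_name != r2.ref_name:
        return None
    if r1.strand == r2.strand:
        return None
    fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
    if fwd.g_start > rev.g_start:
        return None
    return max(r1.g_end, r2.g_end) - min(r1.g_start, r2.g_start)


def rescue_mate(
    anchor_record: AlignmentRecord,
    mate_read: ReadRecord,
    index: ReferenceIndex,
    scoring: ScoringParams,
    qual_params: QualificationParams,
) -> AlignmentRecord:
    """Semi-global search for a mate inside the window implied by its anchor.

    The window is derived from the anchor position, FR orientation, and the
    insert bounds, clipped to the reference record; an empty window yields an
    unaligned mate.  The rescued record carries stage MATE_RESCUE, inherits
    the anchor's MAPQ, and is qualified per the edit-fraction rule.
    """
    if not anchor_record.aligned:
        raise ValueError("rescue_mate requires an aligned anchor")
    mlen = len(mate_read.sequence)
    lo, hi = index.record_bounds(anchor_record.g_start)
    if anchor_record.strand == "+":
        mate_strand = "-"
        ws = anchor_record.g_start + qual_params.insert_min - mlen
        we = anchor_record.g_start + qual_params.insert_max
    else:
        mate_strand = "+"
        ws = anchor_record.g_end - qual_params.insert_max
        we = anchor_record.g_end - qual_params.insert_min + mlen
    ws, we = max(ws, lo), min(we, hi)
    if we - ws < mlen:
        return _unaligned(mate_read)
    oriented = mate_read.sequence if mate_strand == "+" else revcomp(mate_read.sequence)
    window = index.sequence[ws:we]
    score, j0, cigar, edits = semiglobal_align(oriented, window, scoring)
    ref_span = sum(n for n, op in _iter_cigar(cigar) if op in "MD")
    seq, qual = _oriented_seq_qual(mate_read, mate_strand)
    ref_name, pos = index.locate(ws + j0)
    rec = AlignmentRecord(
        read_id=mate_read.id,
        ref_name=ref_name,
        pos=pos,
        strand=mate_strand,
        cigar=cigar,
        score=score,
        stage="MATE_RESCUE",
        qualified=False,
        mapq=anchor_record.mapq,
        seq=seq,
        qual=qual,
        edits=edits,
        flag=FLAG_REVERSE if mate_strand == "-" else 0,
        g_start=ws + j0,
        g_end=ws + j0 + ref_span,
    )
    rec.qualified = is_qualified(rec, mlen, qual_params, scoring.match)
    return rec


def _finalize_pair(
    r1: AlignmentRecord, r2: AlignmentRecord, qual_params: QualificationParams
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Fill SAM pairing fields (FLAG, RNEXT, PNEXT, TLEN) on both mates."""
    insert = _pair_insert(r1, r2)
    proper = (
        insert is not None
        and r1.qualified
        and r2.qualified
        and qual_params.insert_min <= insert <= qual_params.insert_max
    )
    for rec, mate, first in ((r1, r2, True), (r2, r1, False)):
        flag = FLAG_PAIRED | (FLAG_FIRST if first else FLAG_SECOND)
        if not rec.aligned:
            flag |= FLAG_UNMAPPED
        elif rec.strand == "-":
            flag |= FLAG_REVERSE
        if not mate.aligned:
            flag |= FLAG_MATE_UNMAPPED
        elif mate.strand == "-":
            flag |= FLAG_MATE_REVERSE
        if proper:
            flag |= FLAG_PROPER
        rec.flag = flag
        if mate.aligned:
            rec.rnext = "=" if rec.ref_name == mate.ref_name and rec.aligned \
                else (mate.ref_name or "*")
            rec.pnext = (mate.pos or 0) + 1
        else:
            rec.rnext = "*"
            rec.pnext = 0
        if insert is not None:
            if rec.g_start < mate.g_start or (
                rec.g_start == mate.g_start and first
            ):
                rec.tlen = insert
            else:
                rec.tlen = -insert
        else:
            rec.tlen = 0
    return r1, r2


def align_paired(
    read1: ReadRecord,
    read2: ReadRecord,
    index: ReferenceIndex,
    scoring: ScoringParams,
    qual_params: QualificationParams,
    min_mem_length: int = 19,
    kmer_k: int | None = None,
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Paired-end cascade with seed pairing and mate rescue.

    1. MEM seeds of both ends are ranked as in the single-end pipeline.
    2. Top-ranked seeds are paired under the insert-size constraint.
    3. If no pair exists the pairing is retried with exact-match k-mer seeds.
    4. Seed pairs are extended (best weight first); the first pair whose two
       local alignments both qualify and whose realized insert stays in range
       is reported as a proper pair.
    5. Otherwise each mate is aligned independently; a qualified mate anchors
       a semi-global rescue of the other.
    6. Otherwise both mates are unaligned.
    """
    len1, len2 = len(read1.sequence), len(read2.sequence)

    def ranked_seeds(read, finder, *args):
        try:
            seeds = finder(index, read.sequence, *args)
        except ValueError:
            return []
        return rank_seeds(index, read.sequence, seeds, scoring,
                          qual_params.top_n_seeds)

    ranked1 = ranked_seeds(read1, find_mem_seeds, min_mem_length)
    ranked2 = ranked_seeds(read2, find_mem_seeds, min_mem_length)
    pairs = pair_seeds(ranked1, ranked2, qual_params, len1, len2)
    stage = "LOCAL"
    if not pairs:
        k = kmer_k or index.k
        kranked1 = ranked_seeds(read1, find_kmer_seeds, k)
        kranked2 = ranked_seeds(read2, find_kmer_seeds, k)
        pairs = pair_seeds(kranked1, kranked2, qual_params, len1, len2)
        stage = "KMER_LOCAL"

    if pairs:
        all1 = _dedupe(
            [_record_from_extension(read1, index, p.seed1._ext, stage)
             for p in pairs if p.seed1._ext.score > 0]
        )
        all2 = _dedupe(
            [_record_from_extension(read2, index, p.seed2._ext, stage)
             for p in pairs if p.seed2._ext.score > 0]
        )
        for p in pairs:
            if p.seed1._ext.score == 0 or p.seed2._ext.score == 0:
                continue
            r1 = _record_from_extension(read1, index, p.seed1._ext, stage)
            r2 = _record_from_extension(read2, index, p.seed2._ext, stage)
            if not (
                is_qualified(r1, len1, qual_params, scoring.match)
                and is_qualified(r2, len2, qual_params, scoring.match)
            ):
                continue
            insert = _pair_insert(r1, r2)
            if insert is None or not (
                qual_params.insert_min <= insert <= qual_params.insert_max
            ):
                continue
            r1.qualified = r2.qualified = True
            r1.mapq = _mapq(all1, r1.score)
            r2.mapq = _mapq(all2, r2.score)
            return _finalize_pair(r1, r2, qual_params)

    # fallback: independent single-end alignment, then mate rescue
    s1 = align_single(read1, index, scoring, qual_params, min_mem_length, kmer_k)
    s2 = align_single(read2, index, scoring, qual_params, min_mem_length, kmer_k)
    if s1.aligned and s2.aligned:
        return _finalize_pair(s1, s2, qual_params)
    if s1.aligned and not s2.aligned:
        rescued = rescue_mate(s1, read2, index, scoring, qual_params)
        return _finalize_pair(s1, rescued, qual_params)
    if s2.aligned and not s1.aligned:
        rescued = rescue_mate(s2, read1, index, scoring, qual_params)
        return _finalize_pair(rescued, s2, qual_params)
    return _finalize_pair(s1, s2, qual_params)
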