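"""Sequence and alignment I/O: block-wise FASTQ/FASTA streams, SAM emission, merging.

Workers in the parallel pipeline never share a file handle.  Each worker owns a
forward-only :class:`ReadStream` over the input file and fetches work in units
of *blocks* — contiguous groups of ``block_size`` records addressed by a block
index.  Fetching block ``i`` on a fresh stream skips the ``i * block_size``
records that other workers own; streams never seek backwards.

Alignment output is plain SAM.  Workers append headerless SAM body lines to a
private intermediate file; the gatherer concatenates finished intermediates
under a single header, which makes the merge order-free and byte-safe.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "ReadRecord",
    "ReadStream",
    "Block",
    "PairedBlock",
    "ParseError",
    "BackwardSeekError",
    "DesynchronizedPairError",
    "SamValidationError",
    "open_read_stream",
    "read_block",
    "read_pair_block",
    "write_alignments",
    "merge_intermediate",
    "count_records",
    "build_sam_header",
    "sam_line",
]


class ParseError(ValueError):
    """Malformed FASTQ/FASTA input; message names the offending line."""


class BackwardSeekError(RuntimeError):
    """A block before the stream cursor was requested (streams move forward only)."""


class DesynchronizedPairError(RuntimeError):
    """Paired FASTQ files yielded blocks of unequal length."""


class SamValidationError(ValueError):
    """An alignment record would produce an invalid SAM line."""


@dataclass
class ReadRecord:
    """One sequencing read: identifier, bases over {A,C,G,T,N}, optional quality."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("read record with empty id")
        if not self.sequence:
            raise ParseError(f"read {self.id!r} has empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class Block:
    """Records ``[index*block_size, index*block_size + len(reads))`` of a file."""

    index: int
    reads: list[ReadRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def empty(self) -> bool:
        return not self.reads


@dataclass
class PairedBlock:
    """Positionally synchronized blocks from two mate files."""

    index: int
    mates1: list[ReadRecord] = field(default_factory=list)
    mates2: list[ReadRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mates1)

    @property
    def empty(self) -> bool:
        return not self.mates1


class ReadStream:
    """Forward-only cursor over a FASTQ or FASTA file.

    ``cursor`` counts records already consumed (read or skipped).  The stream
    keeps its file handle open between block requests so that block-size-1
    scheduling does not pay a reopen per record.
    """

    def __init__(self, path: str | os.PathLike, format: str = "fastq"):
        if format not in ("fastq", "fasta"):
            raise ValueError(f"unsupported read format {format!r}")
        self.path = os.fspath(path)
        self.format = format
        self.cursor = 0
        self._line_no = 0
        self._fh: IO[str] = open(self.path, "r")
        self._pending_header: str | None = None  # fasta lookahead

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "ReadStream":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- record-level primitives -------------------------------------------

    def _next_fastq(self, parse: bool) -> ReadRecord | None:
        header = self._fh.readline()
        if not header:
            return None
        self._line_no += 1
        if not header.startswith("@"):
            raise ParseError(
                f"{self.path}:{self._line_no}: expected '@' header, got {header[:30]!r}"
            )
        seq = self._fh.readline()
        plus = self._fh.readline()
        qual = self._fh.readline()
        if not qual:
            raise ParseError(
                f"{self.path}:{self._line_no}: truncated FASTQ record "
                f"starting at line {self._line_no}"
            )
        self._line_no += 3
        self.cursor += 1
        if not parse:
            return ReadRecord("skipped", "N")  # placeholder, never returned
        if not plus.startswith("+"):
            raise ParseError(f"{self.path}:{self._line_no - 1}: expected '+' separator")
        seq = seq.rstrip("\n")
        qual = qual.rstrip("\n")
        if len(seq) != len(qual):
            raise ParseError(
                f"{self.path}:{self._line_no}: quality length {len(qual)} "
                f"!= sequence length {len(seq)}"
            )
        rid = header[1:].split()[0] if len(header) > 1 else ""
        return ReadRecord(rid, seq, qual)

    def _next_fasta(self, parse: bool) -> ReadRecord | None:
        if self._pending_header is None:
            while True:
                line = self._fh.readline()
                if not line:
                    return None
                self._line_no += 1
                if line.startswith(">"):
                    self._pending_header = line
                    break
                if line.strip():
                    raise ParseError(
                        f"{self.path}:{self._line_no}: expected '>' header, "
                        f"got {line[:30]!r}"
                    )
        header = self._pending_header
        self._pending_header = None
        chunks: list[str] = []
        while True:
            line = self._fh.readline()
            if not line:
                break
            self._line_no += 1
            if line.startswith(">"):
                self._pending_header = line
                break
            chunks.append(line.strip())
        self.cursor += 1
        if not parse:
            return ReadRecord("skipped", "N")
        rid = header[1:].split()[0] if len(header) > 1 else ""
        return ReadRecord(rid, "".join(chunks).upper())

    def _next(self, parse: bool = True) -> ReadRecord | None:
        if self.format == "fastq":
            return self._next_fastq(parse)
        return self._next_fasta(parse)

    def skip(self, n: int) -> int:
        """Skip up to ``n`` records; returns the number actually skipped."""
        skipped = 0
        for _ in range(n):
            if self._next(parse=False) is None:
                break
            skipped += 1
        return skipped


def open_read_stream(path: str | os.PathLike, format: str = "fastq") -> ReadStream:
    """Open ``path`` as a forward-only read stream with cursor at 0."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return ReadStream(path, format)


def read_block(stream: ReadStream, target_index: int, block_size: int) -> Block:
    """Skip ahead to block ``target_index`` and return its records.

    Returns a partial block at end of file and an empty block when the file is
    exhausted before the block begins — the scheduler discovers termination by
    observing an empty block.  Requesting a block behind the cursor raises
    :class:`BackwardSeekError`.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    start = target_index * block_size
    if start < stream.cursor:
        raise BackwardSeekError(
            f"block {target_index} starts at record {start} but stream cursor "
            f"is already at {stream.cursor}"
        )
    stream.skip(start - stream.cursor)
    reads: list[ReadRecord] = []
    while len(reads) < block_size:
        rec = stream._next()
        if rec is None:
            break
        reads.append(rec)
    return Block(index=target_index, reads=reads)


def read_pair_block(
    stream1: ReadStream, stream2: ReadStream, target_index: int, block_size: int
) -> PairedBlock:
    """Fetch block ``target_index`` from two synchronized mate files.

    Raises :class:`DesynchronizedPairError` at the first block where the files
    yield different record counts (detected streamingly, no pre-scan).
    """
    b1 = read_block(stream1, target_index, block_size)
    b2 = read_block(stream2, target_index, block_size)
    if len(b1) != len(b2):
        raise DesynchronizedPairError(
            f"mate files desynchronized at block {target_index}: "
            f"{stream1.path} yielded {len(b1)} records, {stream2.path} {len(b2)}"
        )
    return PairedBlock(index=target_index, mates1=b1.reads, mates2=b2.reads)


def count_records(path: str | os.PathLike, format: str = "fastq") -> int:
    """Total records in a file (used by the static planner)."""
    n = 0
    with open_read_stream(path, format) as s:
        while s._next(parse=False) is not None:
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM emission

_CIGAR_REF_OPS = frozenset("MD")


def _cigar_lengths(cigar: str) -> tuple[int, int]:
    """(read_consumed, ref_consumed) lengths of a CIGAR over {M,I,D,S}."""
    read_len = ref_len = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        if not num or ch not in "MIDS":
            raise SamValidationError(f"bad CIGAR {cigar!r}")
        n = int(num)
        num = ""
        if ch in "MIS":
            read_len += n
        if ch in _CIGAR_REF_OPS:
            ref_len += n
    if num:
        raise SamValidationError(f"bad CIGAR {cigar!r}")
    return read_len, ref_len


def build_sam_header(
    references: Sequence[tuple[str, int]], program: str = "blockalign"
) -> str:
    """SAM header text: @HD, one @SQ per reference sequence, @PG."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in references:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append(f"@PG\tID:{program}\tPN:{program}")
    return "\n".join(lines) + "\n"


def sam_line(rec, ref_lengths: Mapping[str, int] | None = None) -> str:
    """Render one AlignmentRecord-like object as a SAM body line.

    The record must expose ``read_id, flag, ref_name, pos, mapq, cigar, rnext,
    pnext, tlen, seq, qual``.  ``pos`` is 0-based internally; SAM POS is
    1-based.  Unmapped records use RNAME '*', POS 0, CIGAR '*'.
    """
    if rec.pos is None or rec.ref_name is None:
        rname, pos1, cigar, mapq = "*", 0, "*", 0
    else:
        rname = rec.ref_name
        pos1 = rec.pos + 1
        cigar = rec.cigar
        mapq = rec.mapq
        rlen, ref_span = _cigar_lengths(cigar)
        if rlen != len(rec.seq):
            raise SamValidationError(
                f"{rec.read_id}: CIGAR {cigar} consumes {rlen} read bases, "
                f"sequence has {len(rec.seq)}"
            )
        if ref_lengths is not None:
            limit = ref_lengths.get(rname)
            if limit is None:
                raise SamValidationError(f"{rec.read_id}: unknown reference {rname!r}")
            if rec.pos < 0 or rec.pos + ref_span > limit:
                raise SamValidationError(
                    f"{rec.read_id}: alignment [{rec.pos}, {rec.pos + ref_span}) "
                    f"exceeds reference {rname!r} of length {limit}"
                )
    qual = rec.qual if rec.qual else "*"
    return "\t".join(
        (
            rec.read_id,
            str(rec.flag),
            rname,
            str(pos1),
            str(mapq),
            cigar,
            rec.rnext,
            str(rec.pnext),
            str(rec.tlen),
            rec.seq,
            qual,
        )
    )


def write_alignments(
    intermediate_path: str | os.PathLike,
    records: Iterable,
    ref_lengths: Mapping[str, int] | None = None,
) -> int:
    """Append SAM body lines for ``records`` to a worker's intermediate file.

    Returns the number of lines appended.  Records whose coordinates fall
    outside the reference are refused with :class:`SamValidationError` before
    anything is written.
    """
    lines = [sam_line(r, ref_lengths) for r in records]
    with open(intermediate_path, "a") as fh:
        for line in lines:
            fh.write(line)
            fh.write("\n")
    return len(lines)


def merge_intermediate(
    output_path: str | os.PathLike,
    intermediate_paths_in_completion_order: Sequence[str | os.PathLike],
    header: str,
) -> int:
    """Concatenate finished intermediate files under ``header``; delete sources.

    Bodies are appended in the completion order given, so the final record
    order depends on worker timing — only the record multiset is invariant.
    Returns the total number of body lines written.
    """
    total = 0
    with open(output_path, "w") as out:
        out.write(header)
        for path in intermediate_paths_in_completion_order:
            with open(path, "r") as fh:
                for line in fh:
                    out.write(line)
                    total += 1
            os.remove(path)
    return total


def append_intermediate(out_fh: IO[str], intermediate_path: str | os.PathLike) -> int:
    """Append one intermediate body to an open output handle and delete it."""
    n = 0
    with open(intermediate_path, "r") as fh:
        for line in fh:
            out_fh.write(line)
            n += 1
    out_fh.flush()
    os.remove(intermediate_path)
    return n
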