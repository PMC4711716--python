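"""On-demand block distribution across worker processes.

Work is distributed in blocks of ``block_size`` reads.  A shared integer
holds the index of the first block nobody has claimed yet; a worker finishing
a block atomically reads-and-increments it under a lock held only for that
read-modify-write.  Worker rank ``r`` (ranks 1..P-1) starts with block
``r - 1`` and the counter is initialized to ``P - 1``, so the first P-1
blocks need no synchronization at all.  Each worker appends its alignments to
a private headerless intermediate SAM file and raises a completion flag when
the input is exhausted; rank 0 never aligns — it polls the flags, appends
each finished intermediate file to the final output (header first) and
deletes it.

The static baseline gives each worker exactly one contiguous, equal-count
share of the reads up front; it reuses the same intermediate-file and
gatherer machinery, so the two policies differ only in distribution.  Because
per-read alignment cost varies (seed counts, rescue stages), on-demand
distribution balances load better; :func:`simulate_makespan` quantifies this
without hardware by list-scheduling synthetic block costs.

Output guarantee: the multiset of alignment records is invariant to the
number of processes, threads, block size, distribution policy, and worker
completion order — only the record order in the file may change.
"""

from __future__ import annotations

import heapq
import math
import multiprocessing as mp
import os
import tempfile
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from . import _kernels, io_formats
from .alignment_core import (
    QualificationParams,
    ScoringParams,
    align_paired,
    align_single,
)
from .io_formats import (
    build_sam_header,
    open_read_stream,
    read_block,
    read_pair_block,
    sam_line,
)
from .reference_index import ReferenceIndex, build_index

__all__ = [
    "SchedulerConfig",
    "SharedSchedulerState",
    "WorkerReport",
    "GatherReport",
    "RunReport",
    "StaticPlan",
    "GatherTimeoutError",
    "OrchestrationError",
    "claim_next_block",
    "run_worker",
    "run_gatherer",
    "static_plan",
    "run_parallel",
    "simulate_makespan",
]


class GatherTimeoutError(RuntimeError):
    """A worker never raised its end flag within the liveness timeout."""


class OrchestrationError(RuntimeError):
    """A child process failed; intermediate output has been cleaned up."""


@dataclass(frozen=True)
class SchedulerConfig:
    """Run-shape parameters: process/thread counts, block size, policy."""

    P: int = 2
    T: int = 1
    block_size: int = 5000
    mode: str = "single"
    distribution: str = "ondemand"
    poll_interval: float = 0.05
    liveness_timeout: float | None = 300.0

    def __post_init__(self) -> None:
        if self.P < 2:
            raise ValueError("P must be >= 2 (rank 0 is the gatherer)")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.mode not in ("single", "paired"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.distribution not in ("ondemand", "static"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.poll_interval <= 0:
            raise ValueError("poll_interval must be > 0")

    @property
    def workers(self) -> int:
        return self.P - 1


@dataclass
class AlignmentParams:
    """Bundle of alignment parameters shipped to every worker."""

    scoring: ScoringParams = field(default_factory=ScoringParams)
    qual: QualificationParams = field(default_factory=QualificationParams)
    min_mem_length: int = 19
    kmer_k: int | None = None


class SharedSchedulerState:
    """Lock-protected shared next-block counter plus per-worker end flags.

    ``next_block`` is non-decreasing; the lock is held only for the
    read-modify-write in :func:`claim_next_block`.  End flags are written
    once by their worker and read by the single gatherer, so flag reads need
    no lock.
    """

    def __init__(self, P: int, initial: int | None = None):
        ctx = mp.get_context("fork")
        self.P = P
        self.next_block = ctx.Value("q", P - 1 if initial is None else initial,
                                    lock=False)
        self.lock = ctx.Lock()
        self.end_flags = ctx.Array("b", P, lock=False)


def claim_next_block(shared: SharedSchedulerState) -> int:
    """Atomically return the current next-block index and increment it."""
    with shared.lock:
        block = shared.next_block.value
        shared.next_block.value = block + 1
    return block


@dataclass
class WorkerReport:
    rank: int
    blocks_done: list[int]
    records_aligned: int
    intermediate_path: str


@dataclass
class GatherReport:
    completion_order: list[int]
    records_merged: int


@dataclass
class RunReport:
    output_path: str
    total_records: int
    worker_reports: list[WorkerReport]
    gather_report: GatherReport


@dataclass
class StaticPlan:
    """Contiguous half-open record ranges, one per worker."""

    ranges: list[tuple[int, int]]


def static_plan(total_records: int, P: int) -> StaticPlan:
    """Partition [0, M) into P-1 contiguous ranges of ceil(M/(P-1)) records."""
    if P < 2:
        raise ValueError("P must be >= 2")
    workers = P - 1
    chunk = math.ceil(total_records / workers) if total_records else 0
    ranges = []
    for w in range(workers):
        start = min(w * chunk, total_records)
        end = min(start + chunk, total_records)
        ranges.append((start, end))
    return StaticPlan(ranges=ranges)


def _align_block(reads, index, params, mode, n_threads):
    """Align the records of one block, preserving input order."""
    if mode == "single":
        def work(read):
            return [
                align_single(read, index, params.scoring, params.qual,
                             params.min_mem_length, params.kmer_k)
            ]
        items = reads.reads
    else:
        def work(pair):
            return list(
                align_paired(pair[0], pair[1], index, params.scoring,
                             params.qual, params.min_mem_length, params.kmer_k)
            )
        items = list(zip(reads.mates1, reads.mates2))
    if n_threads > 1:
        with ThreadPoolExecutor(max_workers=n_threads) as pool:
            results = list(pool.map(work, items))
    else:
        results = [work(item) for item in items]
    return [rec for group in results for rec in group]


def run_worker(
    rank: int,
    config: SchedulerConfig,
    index: ReferenceIndex,
    params: AlignmentParams,
    shared: SharedSchedulerState,
    input_paths: list[str],
    intermediate_path: str,
    static_range: tuple[int, int] | None = None,
) -> WorkerReport:
    """Worker loop: claim blocks, align them, append to the intermediate file.

    On-demand mode starts at block ``rank - 1`` and then claims from the
    shared counter until an empty block signals end of input.  Static mode
    processes exactly the worker's pre-assigned record range as one block.
    The end flag is raised exactly once, after the intermediate file is
    complete.
    """
    if not (1 <= rank < config.P):
        raise ValueError(f"worker rank {rank} outside [1, {config.P})")
    ref_lengths = index.ref_lengths()
    blocks_done: list[int] = []
    records = 0
    # the intermediate file must exist even for an empty share
    open(intermediate_path, "a").close()
    streams = [open_read_stream(p, _guess_format(p)) for p in input_paths]
    try:
        with open(intermediate_path, "a") as out:
            def emit(recs):
                for rec in recs:
                    out.write(sam_line(rec, ref_lengths))
                    out.write("\n")

            if config.distribution == "static":
                start, end = static_range
                if end > start:
                    if config.mode == "single":
                        block = _read_range_single(streams[0], start, end)
                    else:
                        block = _read_range_paired(streams, start, end)
                    recs = _align_block(block, index, params, config.mode, config.T)
                    emit(recs)
                    records += len(block)
                    blocks_done.append(rank - 1)
            else:
                my_block = rank - 1  # the first block to align
                while True:
                    if config.mode == "single":
                        block = read_block(streams[0], my_block, config.block_size)
                    else:
                        block = read_pair_block(streams[0], streams[1], my_block,
                                                config.block_size)
                    if block.empty:
                        break
                    recs = _align_block(block, index, params, config.mode, config.T)
                    emit(recs)
                    records += len(block)
                    blocks_done.append(my_block)
                    my_block = claim_next_block(shared)
    finally:
        for s in streams:
            s.close()
    shared.end_flags[rank] = 1
    return WorkerReport(rank, blocks_done, records, intermediate_path)


def _guess_format(path: str) -> str:
    low = path.lower()
    if low.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    return "fastq"


def _read_range_single(stream, start, end):
    from .io_formats import Block

    stream.skip(start - stream.cursor)
    reads = []
    while len(reads) < end - start:
        rec = stream._next()
        if rec is None:
            break
        reads.append(rec)
    return Block(index=0, reads=reads)


def _read_range_paired(streams, start, end):
    from .io_formats import DesynchronizedPairError, PairedBlock

    b1 = _read_range_single(streams[0], start, end)
    b2 = _read_range_single(streams[1], start, end)
    if len(b1) != len(b2):
        raise DesynchronizedPairError(
            f"mate files desynchronized in range [{start}, {end}): "
            f"{len(b1)} vs {len(b2)} records"
        )
    return PairedBlock(index=0, mates1=b1.reads, mates2=b2.reads)


def run_gatherer(
    shared: SharedSchedulerState,
    config: SchedulerConfig,
    intermediate_paths: dict[int, str],
    output_path: str,
    header: str,
    timeout: float | None = None,
    abort_check=None,
) -> GatherReport:
    """Rank-0 loop: poll end flags, merge finished intermediates, delete them.

    Polls every ``poll_interval`` seconds until all P-1 workers have
    completed.  ``timeout`` bounds the wait since the last completion; on
    expiry a :class:`GatherTimeoutError` names the missing ranks.
    ``abort_check`` is an optional callable polled alongside the flags so an
    orchestrator can cancel the gather when a worker dies.
    """
    completed: list[int] = []
    merged = 0
    last_progress = time.monotonic()
    with open(output_path, "w") as out:
        out.write(header)
        while len(completed) < config.P - 1:
            progressed = False
            for rank in range(1, config.P):
                if shared.end_flags[rank] == 1:
                    merged += io_formats.append_intermediate(
                        out, intermediate_paths[rank]
                    )
                    shared.end_flags[rank] = 0
                    completed.append(rank)
                    progressed = True
            if len(completed) >= config.P - 1:
                break
            if progressed:
                last_progress = time.monotonic()
            if abort_check is not None and abort_check():
                raise OrchestrationError("gather aborted: a worker failed")
            if timeout is not None and time.monotonic() - last_progress > timeout:
                missing = sorted(set(range(1, config.P)) - set(completed))
                raise GatherTimeoutError(
                    f"workers {missing} never signalled completion "
                    f"within {timeout} s; partial output at {output_path}"
                )
            time.sleep(config.poll_interval)
    return GatherReport(completion_order=completed, records_merged=merged)


def _worker_entry(rank, config, index, params, shared, input_paths,
                  intermediate_path, static_range, queue):
    try:
        report = run_worker(rank, config, index, params, shared, input_paths,
                            intermediate_path, static_range)
        queue.put((rank, report.blocks_done, report.records_aligned))
    except Exception as exc:  # propagate with rank context via exit code
        queue.put((rank, None, repr(exc)))
        raise SystemExit(1)


def run_parallel(
    config: SchedulerConfig,
    genome_path: str,
    read_paths: list[str],
    output_path: str,
    params: AlignmentParams | None = None,
    index: ReferenceIndex | None = None,
    workdir: str | None = None,
) -> RunReport:
    """Full parallel run: spawn P-1 workers plus the rank-0 gatherer.

    The reference index is built once in the parent; worker processes are
    forked so each holds its own in-memory copy.  Every worker opens private
    streams over the input file(s).  The final output is a single valid SAM
    file containing every input read exactly once (paired mode: once per
    mate).  Any child failure aborts the run, removes intermediates and the
    partial output, and raises :class:`OrchestrationError`.
    """
    if params is None:
        params = AlignmentParams()
    if index is None:
        index = build_index(genome_path)
    if config.mode == "paired" and len(read_paths) != 2:
        raise ValueError("paired mode requires exactly two read files")
    if config.mode == "single" and len(read_paths) != 1:
        raise ValueError("single mode requires exactly one read file")
    _kernels.warmup()  # compile DP kernels before forking

    ctx = mp.get_context("fork")
    shared = SharedSchedulerState(config.P)
    tmpdir = tempfile.mkdtemp(prefix="blockalign_", dir=workdir)
    inter = {r: os.path.join(tmpdir, f"inter_{r}.sam") for r in range(1, config.P)}
    header = build_sam_header(index.references())

    plan = None
    if config.distribution == "static":
        total = io_formats.count_records(read_paths[0],
                                         _guess_format(read_paths[0]))
        if config.mode == "paired":
            total2 = io_formats.count_records(read_paths[1],
                                              _guess_format(read_paths[1]))
            if total2 != total:
                raise io_formats.DesynchronizedPairError(
                    f"mate files hold {total} and {total2} records"
                )
        plan = static_plan(total, config.P)

    queue = ctx.Queue()
    procs: list[mp.Process] = []
    for rank in range(1, config.P):
        srange = plan.ranges[rank - 1] if plan is not None else None
        p = ctx.Process(
            target=_worker_entry,
            args=(rank, config, index, params, shared, list(read_paths),
                  inter[rank], srange, queue),
        )
        p.start()
        procs.append(p)

    def worker_failed() -> bool:
        return any(p.exitcode not in (None, 0) for p in procs)

    try:
        gather = run_gatherer(
            shared, config, inter, output_path, header,
            timeout=config.liveness_timeout, abort_check=worker_failed,
        )
    except (OrchestrationError, GatherTimeoutError):
        for p in procs:
            if p.is_alive():
                p.terminate()
        for p in procs:
            p.join()
        _cleanup(inter.values(), output_path, tmpdir)
        details = _drain_failures(queue)
        raise OrchestrationError(
            "parallel run failed" + (f": {details}" if details else "")
        ) from None
    for p in procs:
        p.join()
    if worker_failed():
        _cleanup(inter.values(), output_path, tmpdir)
        raise OrchestrationError(f"worker failure: {_drain_failures(queue)}")

    reports = []
    while len(reports) < config.P - 1:
        rank, blocks, recs = queue.get()
        reports.append(WorkerReport(rank, blocks, recs, inter[rank]))
    reports.sort(key=lambda r: r.rank)
    os.rmdir(tmpdir)
    return RunReport(
        output_path=output_path,
        total_records=gather.records_merged,
        worker_reports=reports,
        gather_report=gather,
    )


def _drain_failures(queue) -> str:
    msgs = []
    try:
        while True:
            rank, blocks, payload = queue.get_nowait()
            if blocks is None:
                msgs.append(f"rank {rank}: {payload}")
    except Exception:
        pass
    return "; ".join(msgs)


def _cleanup(inter_paths, output_path, tmpdir) -> None:
    for path in inter_paths:
        if os.path.exists(path):
            os.remove(path)
    if os.path.exists(output_path):
        os.remove(output_path)
    if os.path.isdir(tmpdir):
        try:
            os.rmdir(tmpdir)
        except OSError:
            pass


# ---------------------------------------------------------------------------
# makespan simulation


def simulate_makespan(block_costs, workers: int, policy: str) -> float:
    """Completion time of the slowest worker under a distribution policy.

    ``ondemand`` is list scheduling: blocks are claimed in index order, the
    next block going to whichever worker frees up first (worker rank breaks
    ties), exactly matching the shared-counter protocol where worker r starts
    on block r-1.  ``static`` gives each worker one contiguous share of
    ceil(B/workers) blocks.  Costs must be positive.
    """
    costs = list(block_costs)
    if any(c <= 0 for c in costs):
        raise ValueError("block costs must be positive")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if policy == "ondemand":
        heap = [(0.0, r) for r in range(1, workers + 1)]
        heapq.heapify(heap)
        makespan = 0.0
        for cost in costs:
            t, r = heapq.heappop(heap)
            t += cost
            makespan = max(makespan, t)
            heapq.heappush(heap, (t, r))
        return makespan
    if policy == "static":
        chunk = math.ceil(len(costs) / workers)
        makespan = 0.0
        for w in range(workers):
            makespan = max(makespan, sum(costs[w * chunk : (w + 1) * chunk]))
        return makespan
    raise ValueError(f"unknown policy {policy!r}")
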