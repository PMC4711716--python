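"""Synthetic genomes, reads with planted truth, and block-cost models.

Everything here is seed-deterministic: the same seed yields bit-identical
FASTA/FASTQ text and truth tables.  The read simulator emulates Illumina-like
base-space data at desk scale — uniform sampling of loci on both strands,
per-base substitutions and single-base indels at configurable rates, and
FR-oriented mate pairs with a truncated-normal insert-size distribution.  It
does not model platform-specific quality profiles or coverage biases; quality
strings are constant.

The truth table (one row per mate) records where each read was planted, which
is sufficient to score mapping accuracy.  The scorer allows a ±5 bp
positional tolerance to absorb ambiguity in indel placement.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CostModel",
    "simulate_genome",
    "write_genome",
    "simulate_reads",
    "sample_block_costs",
    "score_alignments",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CostModel:
    """Per-block cost distribution feeding the makespan simulator.

    ``distribution`` is one of ``constant`` (params: value), ``lognormal``
    (params: mu, sigma) or ``bimodal`` (params: p_slow, c_fast, c_slow).
    All sampled costs are positive.
    """

    distribution: str = "lognormal"
    params: dict = field(default_factory=lambda: {"mu": 0.0, "sigma": 2.0})
    seed: int = 0


def simulate_genome(length: int, gc_content: float = 0.5, seed: int = 0) -> str:
    """Random genome as FASTA text with the requested GC fraction in expectation."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc_content <= 1.0):
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    seq = "".join(rng.choice(_BASES, size=length, p=[at, gc, gc, at]))
    lines = [f">synthetic_genome length={length} gc={gc_content} seed={seed}"]
    for i in range(0, length, 70):
        lines.append(seq[i : i + 70])
    return "\n".join(lines) + "\n"


def write_genome(path: str | os.PathLike, length: int, gc_content: float = 0.5,
                 seed: int = 0) -> str:
    """Write a simulated genome FASTA to ``path`` and return the bare sequence."""
    text = simulate_genome(length, gc_content, seed)
    with open(path, "w") as fh:
        fh.write(text)
    return "".join(text.split("\n")[1:])


def _mutate(rng, seq: str, subst_rate: float, indel_rate: float) -> tuple[str, int]:
    """Apply per-base substitutions and single-base indels; returns (seq, count)."""
    out: list[str] = []
    mutations = 0
    for base in seq:
        r = rng.random()
        if r < indel_rate / 2:  # deletion
            mutations += 1
            continue
        if r < indel_rate:  # insertion before the base
            out.append(str(rng.choice(_BASES)))
            mutations += 1
        if rng.random() < subst_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(3))])
            mutations += 1
        else:
            out.append(base)
    mutated = "".join(out)
    if not mutated:
        mutated = seq[:1]
    return mutated, mutations


def _is_unique_locus(genome: str, fragment: str) -> bool:
    return genome.count(fragment) == 1 and _revcomp(fragment) not in genome


def _sample_insert(rng, mean: float, sd: float, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    for _ in range(1000):
        v = int(round(rng.normal(mean, sd)))
        if lo <= v <= hi:
            return v
    raise ValueError(
        f"insert bounds [{lo}, {hi}] infeasible for mean={mean}, sd={sd}"
    )


def simulate_reads(
    genome: str,
    n: int,
    read_len: int = 100,
    subst_rate: float = 0.0,
    indel_rate: float = 0.0,
    mode: str = "single",
    insert_mean: float = 300.0,
    insert_sd: float = 50.0,
    insert_bounds: tuple[int, int] = (100, 500),
    seed: int = 0,
    out_prefix: str | os.PathLike = "reads",
    unique_loci: bool = False,
    quality_char: str = "I",
) -> tuple[list[str], pd.DataFrame]:
    """Simulate reads with planted truth; writes FASTQ file(s) and a truth table.

    Single mode writes ``<out_prefix>.fastq``; paired mode writes
    ``<out_prefix>_1.fastq`` / ``<out_prefix>_2.fastq`` with FR mates and a
    truncated-normal insert.  ``unique_loci`` rejects loci whose error-free
    read is not a unique genome substring (for exact-recovery assertions).

    Returns (paths, truth table).  The truth table has one row per mate:
    read_id, mate (0 for single), pos (0-based leftmost), strand, mutations,
    insert (-1 for single).  It is also written as ``<out_prefix>.truth.tsv``.
    """
    if read_len > len(genome):
        raise ValueError("read_len exceeds genome length")
    if not (0 <= subst_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    if mode not in ("single", "paired"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "paired":
        lo, hi = insert_bounds
        if lo > hi or hi > len(genome) or lo < read_len:
            raise ValueError(
                f"infeasible insert bounds {insert_bounds} for read_len "
                f"{read_len} and genome length {len(genome)}"
            )
    rng = np.random.default_rng(seed)
    genome = genome.upper()
    rows: list[dict] = []
    out_prefix = os.fspath(out_prefix)

    def sample_locus(span: int) -> tuple[int, str]:
        for _ in range(10000):
            pos = int(rng.integers(0, len(genome) - span + 1))
            frag = genome[pos : pos + span]
            if "N" in frag:
                continue
            if unique_loci and not _is_unique_locus(genome, frag):
                continue
            return pos, frag
        raise RuntimeError("could not sample a valid locus")

    if mode == "single":
        paths = [f"{out_prefix}.fastq"]
        with open(paths[0], "w") as fh:
            for i in range(n):
                rid = f"read{i:06d}"
                pos, frag = sample_locus(read_len)
                strand = "+" if rng.random() < 0.5 else "-"
                template = frag if strand == "+" else _revcomp(frag)
                seq, muts = _mutate(rng, template, subst_rate, indel_rate)
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
                rows.append(
                    dict(read_id=rid, mate=0, pos=pos, strand=strand,
                         mutations=muts, insert=-1)
                )
    else:
        paths = [f"{out_prefix}_1.fastq", f"{out_prefix}_2.fastq"]
        with open(paths[0], "w") as f1, open(paths[1], "w") as f2:
            for i in range(n):
                rid = f"pair{i:06d}"
                insert = _sample_insert(rng, insert_mean, insert_sd, insert_bounds)
                pos, frag = sample_locus(insert)
                fwd = frag[:read_len]
                rev = _revcomp(frag[insert - read_len :])
                # which mate is the forward one is random, as on a sequencer
                if rng.random() < 0.5:
                    m1, m2 = (fwd, "+", pos), (rev, "-", pos + insert - read_len)
                else:
                    m1, m2 = (rev, "-", pos + insert - read_len), (fwd, "+", pos)
                for mate_no, fh, (template, strand, tpos) in (
                    (1, f1, m1), (2, f2, m2)
                ):
                    seq, muts = _mutate(rng, template, subst_rate, indel_rate)
                    fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
                    rows.append(
                        dict(read_id=rid, mate=mate_no, pos=tpos, strand=strand,
                             mutations=muts, insert=insert)
                    )
    truth = pd.DataFrame(
        rows, columns=["read_id", "mate", "pos", "strand", "mutations", "insert"]
    )
    truth.to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
    return paths, truth


def sample_block_costs(model: CostModel, n_blocks: int) -> np.ndarray:
    """Draw one positive cost per block from the model, deterministically."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(model.seed)
    d, p = model.distribution, model.params
    if d == "constant":
        value = float(p.get("value", 1.0))
        if value <= 0:
            raise ValueError("constant cost must be positive")
        return np.full(n_blocks, value)
    if d == "lognormal":
        return rng.lognormal(p.get("mu", 0.0), p.get("sigma", 2.0), n_blocks)
    if d == "bimodal":
        p_slow = p.get("p_slow", 0.2)
        c_fast = p.get("c_fast", 1.0)
        c_slow = p.get("c_slow", 10.0)
        if c_fast <= 0 or c_slow <= 0:
            raise ValueError("costs must be positive")
        slow = rng.random(n_blocks) < p_slow
        return np.where(slow, c_slow, c_fast).astype(float)
    raise ValueError(f"unknown cost distribution {d!r}")


def score_alignments(records, truth: pd.DataFrame, tolerance: int = 5) -> pd.DataFrame:
    """Compare alignment records against the planted truth.

    ``records`` are AlignmentRecord-like objects; paired records are matched
    to truth rows via the SAM first/second-mate flag bits.  Returns one row
    per record with boolean columns ``mapped``, ``correct_pos`` (within
    ``tolerance`` bp and matching strand) and ``qualified``.
    """
    key = {(r.read_id, r.mate): r for r in truth.itertuples()}
    rows = []
    for rec in records:
        mate = 0
        if rec.flag & 0x1:
            mate = 1 if rec.flag & 0x40 else 2
        t = key.get((rec.read_id, mate))
        if t is None:
            raise KeyError(f"no truth row for {rec.read_id!r} mate {mate}")
        mapped = rec.pos is not None
        correct = bool(
            mapped
            and rec.strand == t.strand
            and abs(rec.g_start - t.pos) <= tolerance
        )
        rows.append(
            dict(read_id=rec.read_id, mate=mate, mapped=mapped,
                 correct_pos=correct, qualified=rec.qualified, stage=rec.stage)
        )
    return pd.DataFrame(rows)
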