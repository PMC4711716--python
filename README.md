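# blockalign

A seed-and-extend short-read aligner wrapped in an on-demand
block-distribution scheduler, at desk scale.

Mapping hundreds of millions of sequencing reads with a sensitive
seed-and-extend aligner is dominated by per-read work that varies widely:
reads differ in how many seeds they generate and in whether the cheap local
extension suffices or the expensive rescue stages fire.  Splitting the input
into equal static shares therefore balances *records*, not *work*.
`blockalign` implements the alternative: reads are consumed in blocks of
`block_size` records, and worker processes repeatedly claim the next
unprocessed block from a single lock-protected shared counter, so fast
workers simply claim more blocks.  A dedicated gatherer process (rank 0)
polls per-worker completion flags and concatenates the workers' private
intermediate SAM files into the final output.  A static equal-share baseline
and a makespan simulator are included so the two policies can be compared
like-for-like.

The package is for people studying the *mechanics* of parallel read mapping
— scheduling, exactly-once block accounting, output equivalence — with a
real aligner in the loop, on inputs that fit on a laptop.

## The aligner

Single-end reads go through a hybrid-seeding cascade:

1. **MEM seeds**: all maximal exact matches ≥ `min_mem_length` (default 19)
   between read and genome (both strands, suffix array + k-mer table);
2. seeds are **ranked** by banded affine-gap Smith-Waterman score of their
   windows (match +1, mismatch −3, gap open −5, gap extend −2, band 32);
3. the top seeds are extended; the best alignment passing the
   **qualification** test (score ≥ 0.30·match·len and M+I coverage ≥ 0.80·len)
   is reported;
4. otherwise a **semi-global rescue** aligns the whole read in each seed
   window, qualifying on edit fraction (≤ 0.10·len);
5. otherwise the same two steps run from exact-match **k-mer seeds**
   (k = 13, non-overlapping);
6. otherwise the read is reported unaligned.

Paired-end reads additionally use weighted **seed pairing** under an
insert-size constraint (outer-edge span in [100, 500] by default) and
**mate rescue**: a mate that fails on its own is searched for
semi-globally inside the window implied by its partner's position and the
insert bounds.  Scheduling guarantees and alignment determinism combine to
one invariant: the output record multiset is identical for every
(processes, threads, block size, policy) combination.

All constants above are defaults, not truths; see `docs/methods.md`.

## Worked example

Simulate a 50 kb genome with 2,000 reads (1 % substitutions), inspect the
index, and align with four processes:

```text
$ blockalign simulate --out-prefix demo --genome-length 50000 \
      --n-reads 2000 --subst-rate 0.01 --seed 4
genome: demo.fasta (50000 bp)
reads:  demo.fastq
truth:  demo.truth.tsv (2000 rows)

$ blockalign index demo.fasta
reference:      demo.fasta
records:        1
total length:   50000
suffix array:   50001 entries
distinct 13-mers: 49975

$ blockalign align --ref demo.fasta --reads demo.fastq --out demo.sam \
      --procs 4 --block-size 250 --dist ondemand
wrote 2000 records to demo.sam
distribution=ondemand  rank 1: 3 blocks / 750 reads, rank 2: 3 blocks / 750 reads, rank 3: 2 blocks / 500 reads
```

The three workers split the eight 250-read blocks 3/3/2 — whichever worker
finished a block first claimed the next one from the shared counter.  The
output is plain SAM:

```text
@HD	VN:1.6	SO:unsorted
@SQ	SN:synthetic_genome	LN:50000
@PG	ID:blockalign	PN:blockalign
read000500	0	synthetic_genome	47823	60	96M4S	*	0	0	GTCCTGTTGA...
```

`read000500` mapped forward (FLAG 0) at 1-based position 47823 with MAPQ 60
(uniquely best window); its CIGAR soft-clips 4 bases the local alignment
did not extend over.  `demo.truth.tsv` records where every read was
planted, so mapping accuracy can be scored with
`blockalign.fixtures.score_alignments`.

Re-running with `--procs 8`, `--block-size 1`, or `--dist static` changes
the order of the records in `demo.sam` but never their multiset.

Paired-end mode takes two synchronized FASTQ files:

```sh
blockalign align --ref demo.fasta --reads pe_1.fastq --reads2 pe_2.fastq \
    --out pe.sam --procs 4
```

The same machinery is available as a library (`blockalign.run_parallel`,
`blockalign.align_single`, `blockalign.align_paired`,
`blockalign.simulate_makespan`, ...).

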