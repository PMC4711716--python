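# Methods

`blockalign` is a desk-scale re-implementation of a parallel short-read
alignment system: a sensitive seed-and-extend aligner wrapped in an
on-demand block-distribution scheduler.  This note documents the model, its
parameters, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Alignment model

### Seeding

The reference genome is held in memory once per worker process as a single
concatenated string (multi-record FASTA inputs are joined with an `N`
spacer, which no exact match can cross because `N` never matches anything,
including another `N`).  Two indexes are built over it:

* a **suffix array** over `sequence + sentinel`, built by numpy prefix
  doubling (O(G log² G)); at the genome sizes this package targets
  (≲ 10⁶ bp) a compressed FM-index would buy nothing, so the simpler
  structure is used deliberately;
* a **k-mer table** mapping every k-mer (default `k = 13`) to its sorted
  occurrence positions.

Seeds come in two kinds:

* **MEM seeds** — maximal exact matches of length ≥ `min_mem_length`
  (default 19): exact read/genome matches extendable in neither direction.
  Enumeration anchors on exact matches of length `s = min(k,
  min_mem_length)` at *every* read offset (k-mer table when `s == k`,
  suffix-array search otherwise), extends each anchor maximally, and
  de-duplicates per diagonal.  Every MEM of length ≥ `min_mem_length`
  contains such an anchor, so the enumeration is exhaustive; the test suite
  checks it against a brute-force diagonal-run oracle.
* **k-mer seeds** — exact occurrences of the read's non-overlapping k-mers
  (stride k), used as a fallback seed source.  Overlapping sampling would be
  more sensitive but triples the candidate load; stride-k is the package's
  choice and is exposed through the `k` argument.

Reverse-strand matches are found by seeding the reverse complement of the
read; the genome is stored once.  For `-` seeds, read offsets index into the
oriented (reverse-complemented) read, which is also the orientation in which
extension and SAM emission operate.

### Extension and qualification

Seed extension is banded Smith-Waterman with affine gaps (gap of length L
costs `gap_open + L·gap_extend`).  Defaults: match +1, mismatch −3,
gap_open −5, gap_extend −2, band_width 32 — standard short-read constants,
all configurable.  The extension window for a seed spans
`genome_pos − read_offset − band_width` to
`genome_pos − read_offset + read_len + 2·band_width`, clipped to the
containing reference record, which guarantees the band covers the seed
diagonal.  Seeds are ranked by this local score and only the `top_n_seeds`
(default 8) best are pursued; the extension computed during ranking is
cached so later stages never redo the DP.

The **semi-global rescue** aligns the whole read inside a seed window with
free leading/trailing reference gaps.  It minimizes *edit count* (unit-cost
DP) and then re-scores the traceback with the affine parameters.  Minimizing
edits rather than affine score makes the reported edit count exactly the
infix edit distance of the read in the window — directly comparable to an
independent edit-distance oracle — and is the natural objective for a stage
whose acceptance test is an edit-fraction threshold.

Qualification thresholds (all `≥`/`≤`, so boundary values pass):

| parameter | default | applies to |
|---|---|---|
| `min_score_fraction` | 0.30 | local stages: score ≥ frac·match·read_len |
| `min_coverage_fraction` | 0.80 | local stages: CIGAR M+I bases ≥ frac·read_len |
| `max_edit_fraction` | 0.10 | semi-global and mate-rescue stages |
| `top_n_seeds` | 8 | seeds extended per stage |
| `insert_min`, `insert_max` | 100, 500 | paired fragment span (outer edges) |

The score/coverage/edit fractions are not canonical constants of any
published aligner; they were chosen so that every branch of the cascade
(local accept, semi-global rescue, k-mer fallback, unaligned) is reachable
on synthetic data, and they are first-class configuration.

### Single-end cascade

1. MEM seeds → rank → local extension of top seeds; report the best
   qualified alignment (stage `LOCAL`).
2. Otherwise semi-global rescue from the same ranked seeds (`SEMIGLOBAL`).
3. Otherwise repeat both steps from k-mer seeds (`KMER_LOCAL`,
   `KMER_SEMIGLOBAL`).
4. Otherwise the read is reported unaligned — a value, not an error.

"Best" is always: highest score, then smallest position, then forward
strand.  Candidates sharing a window (same start and strand) are collapsed
before comparison.  Because every tie-break is total, the pipeline is
deterministic and serial/parallel runs emit byte-identical records.

**MAPQ** is not defined by the alignment model here; the package uses a
monotone surrogate: 60 for a uniquely best window, else
`max(0, 60 − 10·(co-optimal windows − 1))`, counted over the windows
actually extended (not genome-wide).  A rescued mate inherits its anchor's
MAPQ, since its placement confidence derives from the anchor.

### Paired-end cascade

1. MEM seeds of both mates are ranked exactly as in the single-end path.
2. Top seeds are paired: all FR-orientation combinations (opposite strands,
   forward mate leftmost) whose implied outer-edge insert lies in
   `[insert_min, insert_max]`.  Pair weight is the sum of the two rank
   scores — the simplest monotone choice for a weighted seed-pairing
   heuristic; ties break by distance of the implied insert from the middle
   of the allowed range, then by position.
3. If no pair exists, pairing is retried with k-mer seeds.
4. Pairs are realized best-weight-first from the cached extensions; the
   first pair whose two local alignments both qualify and whose realized
   insert is in range is reported, with the SAM proper-pair flag set.
5. Otherwise each mate is aligned independently; if exactly one qualifies,
   it anchors a **mate rescue**: a semi-global search of the other mate
   restricted to the window implied by the anchor position, FR orientation
   and the insert bounds (clipped to the reference; an empty window means an
   unaligned mate).  A rescued record keeps its position and stage
   (`MATE_RESCUE`) even when its edit count fails the qualification
   threshold — reporting the implied placement of a heavily corrupted mate
   is the point of rescue; `qualified` records whether it met the threshold.
6. Otherwise both mates are unaligned.

Insert size is measured outer edge to outer edge (leftmost aligned base of
the left mate to rightmost aligned base of the right mate).  TLEN follows
SAM conventions (+insert on the leftmost mate).

## Parallel execution model

Work is distributed in **blocks** of `block_size` reads (default 5,000).
The scheduler state shared by all processes is one integer — the index of
the first unclaimed block — a lock, and one end flag per process:

* Worker rank r (of ranks 1..P−1) starts on block r−1 without any
  synchronization; the counter is initialized to P−1.
* After each block the worker atomically reads-and-increments the counter;
  the lock is held only for that read-modify-write.
* Each worker owns a private forward-only stream over the input file(s) and
  skips records belonging to other workers' blocks; streams never reopen or
  seek backwards.  Termination is discovered by reading an empty block.
* Workers append headerless SAM body lines to a private intermediate file
  and raise their end flag once, when done.
* Rank 0 never aligns: it polls the end flags every `poll_interval`
  (default 50 ms; flag reads need no lock since they have a single reader),
  appends each finished intermediate file to the output (header first),
  and deletes it.  A liveness timeout bounds the wait for a silent worker;
  the orchestrator additionally watches child exit codes so a crashed
  worker aborts the run quickly, with intermediates and partial output
  removed.

Keeping rank 0 as a pure gatherer preserves the end-flag protocol and makes
the merge trivially order-free; with P−1 ≥ 1 workers nothing is lost at
desk scale.

The **static baseline** pre-assigns each worker one contiguous share of
⌈M/(P−1)⌉ records ("one block per process") and reuses the same
intermediate-file and gatherer machinery, so the two policies differ only
in distribution.  In static paired mode the record counts of both mate
files are compared up front, because a pre-assigned range cannot detect an
over-long second file streamingly.

Within a worker, `T > 1` threads parallelize over the records of the held
block only, and results are restored to block order before writing — the
output multiset is invariant to T.  The threads are Python threads; the
contract tested is ordering and equivalence, not wall-clock speedup.

`simulate_makespan` quantifies the scheduling difference without hardware:
on-demand is list scheduling (blocks claimed in index order by whichever
worker frees first — exactly the shared-counter protocol), static is the
max over workers of their contiguous share.  List scheduling obeys the
Graham bound `makespan ≤ Σcosts/workers + max(cost)`; on skewed
(lognormal σ=2) costs the on-demand mean makespan is strictly below the
static mean.

## Synthetic data

The generator emulates Illumina-like base-space data at desk scale: uniform
loci on both strands, per-base substitutions and single-base indels at
configured rates, FR mate pairs with truncated-normal inserts, constant
quality strings.  It does **not** model platform quality profiles,
coverage bias, chimeras, adapters or color space — so passing tests
demonstrate the mechanics of seeding, extension, pairing and scheduling on
clean error models, not performance on real libraries.  All generators are
seed-deterministic (bit-identical reruns).  The truth table records each
mate's planted position; the accuracy scorer accepts ±5 bp to absorb indel
left-shift ambiguity, since indel placement is not canonicalized.
`unique_loci` mode rejects loci whose read is not a unique genome
substring, making 100 %-recovery assertions exact rather than statistical.

## Problem sizes

The default verification workload is a 100 kb random genome with 10,000
simulated 100 bp reads at 1 % substitutions, run across
{P = 2, 4, 8} × {block_size = 1, 7, 5000} × {on-demand, static}; oracle
comparisons use a 2 kb genome and 100+ random instances per primitive;
paired-end checks use 200 planted pairs and 500 mate-rescue trials.  These
sizes exercise every code path (partial blocks, block-per-read scheduling,
idle workers) while a full run of the test suite plus the acceptance script
stays in the minutes range on one core.

## Degenerate inputs and edge conventions

* Past-EOF block requests return an empty block (the scheduler's
  termination signal); backward seeks are contract violations.
* FASTQ is strict 4-line; malformed records fail loudly with a line number.
* Desynchronized mate files are detected at the first unequal-length block.
* A read of all `N` produces no seeds and comes out unaligned.
* Alignment windows are clipped to reference-record bounds; a mate-rescue
  window that clips to shorter than the mate yields an unaligned mate.
* DP tie-breaks: first-best end cell in row-major order; traceback prefers
  M, then D, then I.  Local alignments with score 0 have an empty traceback
  (fully soft-clipped CIGAR).

## Known limitations

* MEM candidate anchoring requires `min_mem_length ≥ 1`; when it is below
  the table k the suffix array is searched per offset, which is slower but
  exact.
* The aligner reports one best record per read; secondary/multi-mapping
  output is out of scope.
* Base qualities are passed through, never used in scoring.
* Gzip inputs, BAM/CRAM output, and sorting/indexing are out of scope.
* The scheduler is single-machine (processes + shared memory); the
  multi-node runtime it models is reduced to the shared-counter + lock
  contract.
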