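# Methods

## The execution model

`shardalign` reproduces, on a single machine, the map/reduce structure of
distributed read-alignment tools: a *preparation* stage turns raw FASTQ
input into a keyed record stream; a *partition* stage slices that stream
into mapper work units; a *map* stage hands each partition to an aligner
backend under a concurrency budget; an optional *reduce* stage merges the
per-partition SAM fragments into one file. Mappers contain no alignment
logic of their own — they only invoke the backend — so the pipeline is
agnostic to the aligner version and algorithm.

Preparation is lazy: constructing `RunOptions` reads nothing; the first
input byte is read inside `run_alignment`. Any stage failure aborts the
run with a stage-tagged error and removes an incomplete merged output.

## Pair preparation

The read identifier is the pairing key. `normalize_key` takes the
identifier line, drops any whitespace-delimited comment, and strips one
trailing `/1` or `/2` mate designator; this covers both legacy
(`name/1`) and modern Casava (`name 1:N:0:...`) Illumina conventions and
is idempotent. Since no single dialect is universal, this rule is a
documented package choice.

Two strategies produce the same logical pair stream:

* **Join** (`pair_join`): a hash join of the two files on the normalized
  key. Order of the unsorted variant is fixed to file 1's insertion
  order — a join has no inherent order, and pinning it keeps runs
  reproducible without paying for a sort. `sort=True` orders pairs by
  key (nondecreasing, lexicographic). Duplicate keys within one file
  violate the key-value model and are always an error. Orphans (keys in
  only one file) fail the run by default; `orphan_policy="drop"` counts
  and skips them. Conservation holds per file:
  `pairs_emitted + orphans_fileK == n_records_fileK`.
* **Interleave** (`pair_interleave`): a streaming co-iteration of the two
  files that relies on the paired-FASTQ positional convention (mates at
  the same relative position). It verifies key equality at every
  position rather than trusting positions, holds O(1) records in memory,
  and writes one line per pair to an intermediate file. Each line joins
  the four FASTQ fields of each mate with tabs and separates the mates
  with the token `TAB GS TAB` (GS = ASCII 0x1D); fields are validated to
  contain no tab, newline, CR or GS, so the token occurs exactly once
  per line by construction. The token is a versioned module constant.

The two strategies are tested to yield identical pair multisets; the
join additionally handles files whose relative order differs.

## Partitioning

Partitions are contiguous slices, so concatenating them in index order
reproduces the prepared stream and a pair (one stream record) can never
straddle two partitions. `make_partitions(records, p)` gives
`min(p, n)` non-empty slices whose sizes differ by at most one.
`make_partitions_by_bytes` (the default path when no count is given)
packs greedily against a target byte size — default 128 MiB, the
customary distributed-filesystem block size — measured on the serialized
(FASTQ/interleaved) byte length of each record *after* preparation. An
oversized single record still forms its own partition, so packing always
terminates. Empty input yields zero partitions and, downstream, a valid
header-only SAM.

## Backends

A backend maps a `BackendRequest` (algorithm, pairedness, thread count,
reference, partition, scratch dir) to a `SamFragment` (header lines,
alignment lines). `run_backend` also persists each fragment as
`part-<index 5-digit>.sam`, one SAM file per map process.

**External backend.** Drives an unmodified `bwa` through its public
command line only: `mem` and `bwasw` as single invocations, and
backtrack as its three phases — `aln` per input file, then
`sampe`/`samse` — hidden behind one call. Subprocesses run with a
timeout and captured stderr; a nonzero exit surfaces the status and
diagnostics. The index prefix is validated (`.bwt/.pac/.sa/.ann/.amb`)
before launching. The request's thread count is passed verbatim as
`-t`, which is what makes hybrid mode work with a real aligner.

**Toy aligner.** A deliberately simple deterministic test double, never
presented as equivalent to a production aligner: exact-match the first
`seed_len` bases (default 20) at every reference offset on both strands
(the read and its reverse complement — the fixture's mate 2 is
reverse-complemented, so single-strand search could not recover it),
extend each seed hit by whole-read Hamming comparison, and keep the
minimum of `(mismatches, ref_name, pos, strand)` with the forward strand
preferred on ties. A read is unmapped when no seed matches or the best
hit exceeds a 25% mismatch fraction. Mapped reads get a fixed mapq of
37, a full-length `M` CIGAR and an `NM` tag; SAM flags encode
paired/mate-number/strand/unmapped bits, and reverse-strand records
store the reverse-complemented sequence per SAM convention. Pure
Hamming scoring was chosen so an exhaustive scan can serve as an exact
independent oracle in the tests (implemented there with vectorised
sliding windows, sharing no code with the seed-and-extend path).

## Concurrency model

The contract is observable behaviour, not mechanism: at most
`max_concurrent_mappers` backend invocations in flight (thread pool; the
external backend's subprocesses genuinely run in parallel), each
carrying `threads_per_mapper` aligner threads, fragments collected in
partition-index order regardless of completion order, and a failed
partition retried once before aborting — a bounded stand-in for the
lineage-based fault tolerance a cluster scheduler would provide.
Regular mode (1 thread/mapper) is the default; hybrid mode is worth
enabling mainly when per-mapper memory limits prevent using all cores
with independent mappers, since extra threads inside one aligner pay a
synchronization cost.

## Reduce

The merged header is the first fragment's header with every fragment's
`@PG` lines appended, deduplicated, order-preserved; alignment lines
follow in partition-index order (global read order across partitions is
defined by this, and only this). Fragments with differing `@SQ`
dictionaries refuse to merge. Zero fragments produce a minimal
`@HD`-only file.

## Synthetic data

`FixtureSpec` fully determines a dataset; a fixed seed reproduces
byte-identical files. The generator emulates just enough structure to
exercise the pipeline: a uniform-random reference (default 5 kb), pairs
drawn as the two ends of a fixed-length fragment (default 70 bp reads,
40 bp inner gap) with mate 2 reverse-complemented, independent per-base
substitutions (default 1%, drawn via geometric inter-arrival jumps —
distributionally identical to per-base Bernoulli trials), constant
qualities, and exact fault injection (orphans, duplicate keys, shuffled
file-2 order). A TSV truth table records each pair's true coordinates
and strand. Not modelled: indels, quality profiles, read-length or
insert-size distributions, adapters, repetitive references. Passing
tests therefore demonstrate the orchestration's correctness properties
(conservation, invariance, concordance), not aligner accuracy on real
genomes.

## Numerical and design choices

* Strict FASTQ parsing: malformed quartets and length mismatches are
  hard errors naming the offending line — silent record loss upstream of
  pairing would corrupt results invisibly. Parsing is lossless
  (`+`-line payload, case, qualities verbatim), so write∘parse is the
  identity on bytes. Gzip input is detected by magic bytes.
* Problem sizes in the test and acceptance runs (datasets up to 2,000
  pairs on 5 kb references) are chosen so every check is exhaustive or
  near-exhaustive at desk scale while the full suite stays fast; all
  the verified properties are size-invariant by construction.
* Exit codes: 0 success, 2 usage error, 1 runtime failure. Flag
  precedence is explicit flag > config file > built-in default.

## Known limitations

Single-machine only (no distributed filesystem or scheduler); the join
strategy holds both files' records in memory (use the interleave path
for bounded memory, which then requires mate-synchronized files); the
toy aligner has no indels, no split alignments and a trivial mapq model;
BAM output, duplicate marking and downstream variant calling are out of
scope.
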