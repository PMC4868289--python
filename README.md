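# shardalign

Cluster-free map/reduce orchestration of short-read alignment.

Mapping sequencing reads onto a reference genome is typically the most
time-consuming stage of an NGS analysis, and the standard way to scale it
is embarrassingly parallel: split the input FASTQ reads into partitions,
run an unmodified aligner (such as `bwa`) on each partition, and merge
the per-partition SAM outputs. Doing this correctly has two subtle
requirements that `shardalign` takes care of:

* **Paired-end reads must stay together.** The two mates of a DNA
  fragment live in two FASTQ files at the same relative position under
  the same identifier; a naive split can send them to different workers.
  `shardalign` first builds a stream of *pairs* — either by an in-memory
  **join** on the normalized read identifier (robust to reordered files,
  optionally key-sorted), or by a **streaming interleave** that merges the
  two files positionally with bounded memory — and only then partitions,
  so a pair can never be split.
* **Splitting must not change the result.** The per-partition SAM
  fragments are collected in partition-index order and merged with a
  single deduplicated header. With a deterministic aligner the merged
  alignment-line multiset is invariant to the partition count, the
  concurrency budget, and the per-mapper thread count (*hybrid mode*:
  several aligner threads inside each of several concurrent mappers).
  With real `bwa`, mapping coordinates are invariant; only mapq scores
  may drift, because their estimation depends on insert-size statistics
  computed over windows of the input stream.

The aligner itself is pluggable behind a one-method contract
(partition in, SAM fragment out): an **external backend** drives any
`bwa` executable through its public command line (`mem`, the three-phase
`aln`/`sampe`/`samse` backtrack flow, `bwasw`), and a built-in
deterministic **toy aligner** (seed-and-extend by Hamming distance over a
FASTA reference) makes the whole pipeline testable with no external tool
or data. A synthetic-data module generates paired FASTQ with known
ground-truth placements for the same purpose.

## Worked example

```python
from shardalign import (FixtureSpec, RunOptions, ToyBackend,
                        generate_dataset, run_alignment)

dataset = generate_dataset(FixtureSpec(n_pairs=100, seed=2), "demo")
options = RunOptions(
    index_path=str(dataset.reference_path),
    input_path=str(dataset.fastq1), input_path2=str(dataset.fastq2),
    output_path="demo/merged.sam", use_reducer=True, partition_count=4,
)
result = run_alignment(options, ToyBackend(dataset.reference_path))
print(result.pairs_aligned, result.fragments_written)
```

prints `100 4`: all 100 synthetic pairs were prepared, aligned across 4
partitions (each persisted as `part-0000N.sam`), and merged into
`demo/merged.sam`, which holds 200 alignment lines — exactly two per
pair. Re-running with `partition_count=7, threads_per_mapper=4` produces
the identical merged multiset. The scripts in `examples/` walk through
pairing/partitioning, the full toy run, and driving a real `bwa`
(`examples/03_external_bwa.py` prints
`identical mapping coordinates: 300 (100.0%)` for a 5-partition run
versus a sequential one).

The same workflow is available from the shell:

```bash
shardalign -r -partitions 4 -threads 2 -index ref_prefix \
           reads_1.fastq reads_2.fastq merged.sam
```

Flags: `-r` (merge with a reducer), `-partitions N`, `-sort | -sorthdfs`
(key-sorted join / streaming interleave preparation), `-threads N`
(hybrid mode when N > 1), `-mem | -aln | -bwasw` (algorithm, default
MEM), `-paired | -single`, `-mappers N` (concurrency budget, default =
available processors), mandatory `-index`, and positional inputs then
output. `-backend toy` runs the built-in aligner, in which case
`-index` names a plain FASTA file.

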