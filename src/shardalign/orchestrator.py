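"""Workflow driver: prepare, partition, map under a concurrency budget, reduce.

The run mirrors a map/reduce alignment job on a single machine.  Input
reads are prepared into a pair stream (by one of the two pairing
strategies), split into contiguous partitions, fanned out to the aligner
backend with at most ``max_concurrent_mappers`` simultaneous invocations
(each itself allowed ``threads_per_mapper`` aligner threads — the hybrid
mode), and the per-partition SAM fragments are optionally merged into one
output file.  Preparation is lazy: no input byte is read before
:func:`run_alignment` is called.

Regular mode (one thread per mapper) and hybrid mode (several) change
resource usage only, never results: with a deterministic backend the
merged output is invariant to partition count, concurrency budget and
thread count.
"""

from __future__ import annotations

import enum
import json
import logging
import os
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .backends import Backend, BackendRequest, SamFragment, Algorithm, run_backend
from .fastq import parse_fastq_path
from .pairing import (
    OrphanPolicy,
    PairingReport,
    pair_interleave,
    pair_join,
    prepare_single_end,
    read_interleaved,
)
from .partitioning import (
    DEFAULT_BLOCK_BYTES,
    PartitionSpec,
    make_partitions,
    make_partitions_by_bytes,
)

logger = logging.getLogger("shardalign")


class SortMode(enum.IntEnum):
    """Pair-preparation strategy selector."""

    JOIN = 0
    JOIN_SORT = 1
    SORTHDFS = 2


class StageError(RuntimeError):
    """A pipeline stage failed; tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


class MergeError(ValueError):
    """SAM fragments disagree on their reference dictionary."""


@dataclass
class RunOptions:
    """Complete option set governing one run.

    Defaults follow the canonical option table: no reducer, automatic
    (block-size) partitioning, plain join preparation, one thread per
    mapper, the MEM algorithm, paired-end input.
    """

    index_path: str = ""
    input_path: str = ""
    input_path2: Optional[str] = None
    output_path: str = ""
    use_reducer: bool = False
    partition_count: Optional[int] = None
    sort_mode: SortMode = SortMode.JOIN
    threads_per_mapper: int = 1
    algorithm: Algorithm = Algorithm.MEM
    paired: bool = True
    max_concurrent_mappers: int = field(default_factory=lambda: os.cpu_count() or 1)
    block_bytes: int = DEFAULT_BLOCK_BYTES
    orphan_policy: OrphanPolicy = "fail"

    def validate(self) -> "RunOptions":
        if not self.index_path:
            raise ValueError("index_path is mandatory")
        if not self.input_path:
            raise ValueError("input_path is mandatory")
        if not self.output_path:
            raise ValueError("output_path is mandatory")
        if self.paired and not self.input_path2:
            raise ValueError("paired-end mode requires a second input path")
        if not self.paired and self.input_path2:
            raise ValueError("single-end mode accepts only one input path")
        if self.threads_per_mapper < 1:
            raise ValueError("threads_per_mapper must be >= 1")
        if self.max_concurrent_mappers < 1:
            raise ValueError("max_concurrent_mappers must be >= 1")
        if self.partition_count is not None and self.partition_count < 1:
            raise ValueError("partition_count must be >= 1 when given")
        self.sort_mode = SortMode(self.sort_mode)
        self.algorithm = Algorithm(self.algorithm)
        return self

    @property
    def hybrid_mode(self) -> bool:
        return self.threads_per_mapper > 1

    def to_manifest(self) -> dict:
        return {
            "index_path": self.index_path,
            "input_path": self.input_path,
            "input_path2": self.input_path2,
            "output_path": self.output_path,
            "use_reducer": self.use_reducer,
            "partition_count": self.partition_count,
            "sort_mode": int(self.sort_mode),
            "threads_per_mapper": self.threads_per_mapper,
            "algorithm": int(self.algorithm),
            "paired": self.paired,
            "max_concurrent_mappers": self.max_concurrent_mappers,
            "block_bytes": self.block_bytes,
            "orphan_policy": self.orphan_policy,
        }


@dataclass
class RunResult:
    fragments_written: int
    pairs_aligned: int
    merged_output: Optional[str]
    elapsed_stage_log: list[tuple[str, float]]
    report: PairingReport
    workdir: str


def prepare_records(options: RunOptions, workdir: Path) -> tuple[list, PairingReport]:
    """Execute the configured pair-preparation strategy."""
    if not options.paired:
        records = prepare_single_end(parse_fastq_path(options.input_path))
        report = PairingReport(pairs_emitted=len(records))
        return records, report
    if options.sort_mode is SortMode.SORTHDFS:
        interleaved = workdir / "interleaved.pairs"
        report = pair_interleave(options.input_path, options.input_path2, interleaved)
        return list(read_interleaved(interleaved)), report
    sort = options.sort_mode is SortMode.JOIN_SORT
    pairs, report = pair_join(
        parse_fastq_path(options.input_path),
        parse_fastq_path(options.input_path2),
        sort=sort,
        orphan_policy=options.orphan_policy,
    )
    return pairs, report


def map_phase(
    partitions: Sequence[PartitionSpec],
    options: RunOptions,
    backend: Backend,
    workdir: Path,
) -> list[SamFragment]:
    """Fan partitions out to the backend under the concurrency budget.

    At most ``max_concurrent_mappers`` backend invocations run at once;
    each receives ``threads_per_mapper`` verbatim.  A failed partition is
    retried once, then the run aborts.  Fragments are returned in
    partition-index order regardless of completion order.
    """

    def task(partition: PartitionSpec) -> SamFragment:
        request = BackendRequest(
            algorithm=options.algorithm,
            paired=options.paired,
            threads=options.threads_per_mapper,
            index_ref=options.index_path,
            partition=partition,
            workdir=workdir,
        )
        try:
            return run_backend(request, backend)
        except Exception as first:
            logger.warning(
                "[map] partition %d failed (%s); retrying once", partition.index, first
            )
            return run_backend(request, backend)

    if not partitions:
        return []
    with ThreadPoolExecutor(max_workers=options.max_concurrent_mappers) as pool:
        futures = [pool.submit(task, p) for p in partitions]
        fragments = [f.result() for f in futures]
    return sorted(fragments, key=lambda fr: fr.partition_index)


FALLBACK_HEADER = ("@HD\tVN:1.6\tSO:unsorted",)


def _sq_lines(fragment: SamFragment) -> tuple[str, ...]:
    return tuple(l for l in fragment.header_lines if l.startswith("@SQ"))


def reduce_phase(
    fragments: Sequence[SamFragment],
    out_path: os.PathLike | str,
) -> Path:
    """Merge fragments into a single SAM file.

    The header is emitted once, taken from the first fragment, with the
    program (``@PG``) lines of every fragment concatenated and
    deduplicated; alignment lines follow in partition-index order.
    Fragments whose reference dictionaries (``@SQ`` lines) differ cannot
    be merged.
    """
    out_path = Path(out_path)
    ordered = sorted(fragments, key=lambda fr: fr.partition_index)
    if not ordered:
        out_path.write_text("".join(l + "\n" for l in FALLBACK_HEADER), encoding="utf-8")
        return out_path
    reference_sq = _sq_lines(ordered[0])
    for fragment in ordered[1:]:
        sq = _sq_lines(fragment)
        if sq != reference_sq:
            raise MergeError(
                "fragments disagree on reference dictionary:\n"
                f"  fragment {ordered[0].partition_index}: {reference_sq}\n"
                f"  fragment {fragment.partition_index}: {sq}"
            )
    header = [l for l in ordered[0].header_lines if not l.startswith("@PG")]
    pg_lines: list[str] = []
    for fragment in ordered:
        for line in fragment.header_lines:
            if line.startswith("@PG") and line not in pg_lines:
                pg_lines.append(line)
    with open(out_path, "w", encoding="utf-8", newline="") as out:
        for line in header + pg_lines:
            out.write(line + "\n")
        for fragment in ordered:
            for line in fragment.alignment_lines:
                out.write(line + "\n")
    return out_path


def run_alignment(options: RunOptions, backend: Backend) -> RunResult:
    """Execute the complete workflow: prepare → partition → map → reduce.

    With ``use_reducer=False`` the output path is a directory receiving
    one ``part-<index 5-digit>.sam`` file per non-empty partition; with
    ``use_reducer=True`` it is the single merged SAM file.  Any stage
    failure aborts with a stage-tagged error and removes the incomplete
    merged output.
    """
    options.validate()
    timings: list[tuple[str, float]] = []
    out = Path(options.output_path)
    if options.use_reducer:
        workdir = out.parent / (out.name + ".work")
    else:
        workdir = out
    workdir.mkdir(parents=True, exist_ok=True)

    def staged(stage: str, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            if options.use_reducer and out.exists():
                out.unlink()
            raise StageError(stage, exc) from exc
        timings.append((stage, time.perf_counter() - t0))
        logger.info("[%s] done in %.3fs", stage, timings[-1][1])
        return result

    records, report = staged("prepare", prepare_records, options, workdir)
    if options.partition_count is not None:
        partitions = staged("partition", make_partitions, records, options.partition_count)
    else:
        partitions = staged("partition", make_partitions_by_bytes, records, options.block_bytes)
    fragments = staged("map", map_phase, partitions, options, backend, workdir)
    merged: Optional[str] = None
    if options.use_reducer:
        merged = str(staged("reduce", reduce_phase, fragments, out))
    manifest = {
        "options": options.to_manifest(),
        "partitions": [
            {"index": p.index, "count": p.count, "bytes": p.byte_size} for p in partitions
        ],
        "timings": {stage: seconds for stage, seconds in timings},
        "report": {
            "pairs_emitted": report.pairs_emitted,
            "orphans_file1": report.orphans_file1,
            "orphans_file2": report.orphans_file2,
            "duplicate_keys": report.duplicate_keys,
        },
    }
    (workdir / "run-manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return RunResult(
        fragments_written=len(fragments),
        pairs_aligned=report.pairs_emitted,
        merged_output=merged,
        elapsed_stage_log=timings,
        report=report,
        workdir=str(workdir),
    )
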