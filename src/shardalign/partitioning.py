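"""Split the prepared record stream into mapper work units.

Partitions are contiguous slices of the input stream, so concatenating
them in index order reproduces the input exactly, and a pair — one
record in the prepared stream — can never be split across partitions.
Two splitting policies mirror the two configuration styles: an explicit
partition count (balanced sizes, differing by at most one) and a target
byte size per partition (greedy packing against the serialised record
length), the latter being the default with a 128 MiB block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

from .fastq import PairedRecord, PairKey, ReadRecord

#: Default byte-based split size (128 MiB, the customary DFS block size).
DEFAULT_BLOCK_BYTES = 128 * 1024 * 1024

Record = Union[PairedRecord, tuple[PairKey, ReadRecord]]


def _record_bytes(record: Record) -> int:
    if isinstance(record, PairedRecord):
        return record.serialized_bytes
    _, read = record
    return read.serialized_bytes


@dataclass(frozen=True)
class PartitionSpec:
    """A contiguous, indexed slice of records destined for one mapper."""

    index: int
    records: tuple[Record, ...] = field(default_factory=tuple)

    @property
    def count(self) -> int:
        return len(self.records)

    @property
    def byte_size(self) -> int:
        return sum(_record_bytes(r) for r in self.records)


def make_partitions(records: Sequence[Record], num_partitions: int) -> list[PartitionSpec]:
    """Split into at most ``num_partitions`` balanced contiguous slices.

    Produces exactly ``min(num_partitions, n)`` non-empty partitions whose
    sizes differ by at most one; empty input yields zero partitions.
    """
    if num_partitions < 1:
        raise ValueError(f"num_partitions must be >= 1, got {num_partitions}")
    records = tuple(records)
    n = len(records)
    if n == 0:
        return []
    p = min(num_partitions, n)
    base, extra = divmod(n, p)
    out: list[PartitionSpec] = []
    start = 0
    for i in range(p):
        size = base + (1 if i < extra else 0)
        out.append(PartitionSpec(index=i, records=records[start : start + size]))
        start += size
    return out


def make_partitions_by_bytes(
    records: Sequence[Record], block_bytes: int = DEFAULT_BLOCK_BYTES
) -> list[PartitionSpec]:
    """Greedy contiguous packing into partitions of at most ``block_bytes``.

    A partition closes when adding the next record would exceed the block
    size, unless it is empty — every record is placed somewhere, so a
    single record larger than the block still forms its own partition.
    """
    if block_bytes < 1:
        raise ValueError(f"block_bytes must be >= 1, got {block_bytes}")
    out: list[PartitionSpec] = []
    current: list[Record] = []
    current_bytes = 0
    for record in records:
        size = _record_bytes(record)
        if current and current_bytes + size > block_bytes:
            out.append(PartitionSpec(index=len(out), records=tuple(current)))
            current, current_bytes = [], 0
        current.append(record)
        current_bytes += size
    if current:
        out.append(PartitionSpec(index=len(out), records=tuple(current)))
    return out
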