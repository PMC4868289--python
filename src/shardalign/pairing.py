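"""Paired-end record preparation: in-memory join and streaming interleave.

Two strategies produce the same logical stream of :class:`PairedRecord`s:

* **Join** — load both mate files keyed by normalised identifier and group
  records sharing a key, optionally sorting the output by key.  Order of
  the unsorted variant is fixed to the insertion order of file 1, which
  keeps runs reproducible without paying the sort cost.
* **Interleave** (streaming merge) — exploit the positional convention of
  paired FASTQ files (mates occupy the same relative position in the two
  files) to co-iterate both files with bounded memory, writing one merged
  line per pair to an intermediate file.  Keys are verified as the files
  are streamed rather than trusted.

Both are alternative implementations of the same preparation stage and are
tested to yield identical pair multisets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Literal

from .fastq import (
    PairedRecord,
    PairKey,
    PathLike,
    ReadRecord,
    normalize_key,
    open_text,
    parse_fastq_path,
)

#: Separates the two mates inside one interleaved line.  The surrounding
#: tabs come from the field joiner; the ASCII group-separator character in
#: the middle cannot occur in any validated FASTQ field, so the token
#: occurs exactly once per line by construction.
MATE_SEPARATOR = "\t\x1d\t"

#: Joins the four FASTQ fields of one mate inside an interleaved line.
FIELD_SEPARATOR = "\t"

_FORBIDDEN = ("\t", "\n", "\r", "\x1d")


class PairingError(ValueError):
    """Raised when mate files cannot be paired under the active policy."""


class InterleaveFormatError(ValueError):
    """Raised for malformed interleaved pair files."""


@dataclass
class PairingReport:
    """Accounting for one pairing pass; all counters are non-negative."""

    pairs_emitted: int = 0
    orphans_file1: int = 0
    orphans_file2: int = 0
    duplicate_keys: int = 0

    @property
    def orphans(self) -> int:
        return self.orphans_file1 + self.orphans_file2


def _mate_fields(record: ReadRecord) -> list[str]:
    fields = [record.raw_id, record.bases, record.plus_line, record.quality]
    for field in fields:
        for bad in _FORBIDDEN:
            if bad in field:
                raise PairingError(
                    f"read {record.raw_id!r}: field contains reserved "
                    f"character {bad!r}, cannot be interleaved"
                )
    return fields


def serialize_pair(pair: PairedRecord) -> str:
    """One interleaved line: mate1 fields TAB-joined, separator, mate2 fields."""
    left = FIELD_SEPARATOR.join(_mate_fields(pair.mate1))
    right = FIELD_SEPARATOR.join(_mate_fields(pair.mate2))
    return left + MATE_SEPARATOR + right


def deserialize_pair(line: str, lineno: int | None = None) -> PairedRecord:
    halves = line.split(MATE_SEPARATOR)
    if len(halves) != 2:
        where = f"line {lineno}: " if lineno is not None else ""
        raise InterleaveFormatError(
            f"{where}expected exactly one mate separator, found {len(halves) - 1}"
        )
    mates = []
    for half in halves:
        fields = half.split(FIELD_SEPARATOR)
        if len(fields) != 4:
            where = f"line {lineno}: " if lineno is not None else ""
            raise InterleaveFormatError(
                f"{where}expected 4 fields per mate, found {len(fields)}"
            )
        mates.append(
            ReadRecord(raw_id=fields[0], bases=fields[1], plus_line=fields[2], quality=fields[3])
        )
    return PairedRecord(key=normalize_key(mates[0].raw_id), mate1=mates[0], mate2=mates[1])


OrphanPolicy = Literal["fail", "drop"]


def pair_join(
    reads1: Iterable[ReadRecord],
    reads2: Iterable[ReadRecord],
    sort: bool = False,
    orphan_policy: OrphanPolicy = "fail",
) -> tuple[list[PairedRecord], PairingReport]:
    """Pair two read sequences by grouping records under a shared key.

    Emits one :class:`PairedRecord` per key present in both inputs.  With
    ``sort=False`` the output follows the insertion order of ``reads1``;
    with ``sort=True`` keys are in nondecreasing lexicographic order.
    Duplicate keys within one file are always an error (the key-value model
    assumes unique keys per file).  Orphan keys — present in only one file
    — are an error under the default ``fail`` policy and are counted and
    dropped under ``drop``.
    """
    by_key: dict[PairKey, ReadRecord] = {}
    report = PairingReport()
    for record in reads1:
        key = normalize_key(record.raw_id)
        if key in by_key:
            report.duplicate_keys += 1
            raise PairingError(f"duplicate key {key.value!r} in first input")
        by_key[key] = record
    pairs: list[PairedRecord] = []
    seen2: set[PairKey] = set()
    pending: dict[PairKey, PairedRecord] = {}
    orphans2: list[PairKey] = []
    for record in reads2:
        key = normalize_key(record.raw_id)
        if key in seen2:
            report.duplicate_keys += 1
            raise PairingError(f"duplicate key {key.value!r} in second input")
        seen2.add(key)
        mate1 = by_key.get(key)
        if mate1 is None:
            orphans2.append(key)
        else:
            pending[key] = PairedRecord(key=key, mate1=mate1, mate2=record)
    orphans1 = [key for key in by_key if key not in pending]
    report.orphans_file1 = len(orphans1)
    report.orphans_file2 = len(orphans2)
    if (orphans1 or orphans2) and orphan_policy == "fail":
        sample = [k.value for k in (orphans1 + orphans2)[:10]]
        raise PairingError(
            f"{len(orphans1) + len(orphans2)} orphan read(s) without a mate "
            f"(first offenders: {sample}); use orphan_policy='drop' to skip them"
        )
    # insertion order of file1 keeps the unsorted variant deterministic
    pairs = [pending[key] for key in by_key if key in pending]
    if sort:
        pairs.sort(key=lambda p: p.key)
    report.pairs_emitted = len(pairs)
    return pairs, report


def pair_interleave(path1: PathLike, path2: PathLike, out_path: PathLike) -> PairingReport:
    """Streaming merge of positionally synchronised mate files.

    Co-iterates both FASTQ files record by record (bounded memory,
    independent of file size), verifies that the normalised keys agree at
    every position, and writes one interleaved line per pair to
    ``out_path`` preserving file order.
    """
    report = PairingReport()
    it1 = parse_fastq_path(path1)
    it2 = parse_fastq_path(path2)
    with open(out_path, "w", encoding="utf-8", newline="") as out:
        index = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                longer = "second" if r1 is None else "first"
                raise PairingError(
                    f"unequal record counts: {longer} file has extra records "
                    f"from index {index}"
                )
            k1, k2 = normalize_key(r1.raw_id), normalize_key(r2.raw_id)
            if k1 != k2:
                raise PairingError(
                    f"record {index}: keys {k1.value!r} and {k2.value!r} differ "
                    "— files are not mate-synchronized (use the join strategy)"
                )
            out.write(serialize_pair(PairedRecord(key=k1, mate1=r1, mate2=r2)))
            out.write("\n")
            index += 1
    report.pairs_emitted = index
    return report


def read_interleaved(path: PathLike) -> Iterator[PairedRecord]:
    """Exact inverse of :func:`pair_interleave` serialisation, order preserved."""
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            yield deserialize_pair(line.rstrip("\n"), lineno)


def prepare_single_end(reads: Iterable[ReadRecord]) -> list[tuple[PairKey, ReadRecord]]:
    """Wrap single-end reads with their keys; no pairing is performed."""
    return [(normalize_key(r.raw_id), r) for r in reads]
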