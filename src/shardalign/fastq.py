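"""Read-record model and exact FASTQ readers/writers.

FASTQ is a plain-text format in which every four lines describe one read:
identifier (prefixed ``@``), bases, a ``+`` separator line whose payload is
optional, and per-base ASCII qualities.  The parser here is deliberately
*strict* and *lossless*: a malformed quartet is a hard error (silent data
loss in a pairing pipeline is worse than failure), and parsing followed by
serialisation reproduces the input byte for byte — the ``+``-line payload,
letter case and quality strings are carried verbatim and never
reinterpreted.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One FASTQ entry.

    Attributes
    ----------
    raw_id:
        Full identifier line without the leading ``@`` marker.
    bases:
        Nucleotide string, case preserved.
    plus_line:
        Text after the ``+`` separator; may be empty and is kept verbatim.
    quality:
        ASCII-encoded per-base quality string, same length as ``bases``.
    """

    raw_id: str
    bases: str
    plus_line: str = ""
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.raw_id or "\n" in self.raw_id:
            raise ValueError("read identifier must be non-empty and single-line")
        if len(self.bases) != len(self.quality):
            raise ValueError(
                f"read {self.raw_id!r}: sequence length {len(self.bases)} "
                f"!= quality length {len(self.quality)}"
            )

    def to_lines(self) -> tuple[str, str, str, str]:
        return (f"@{self.raw_id}", self.bases, f"+{self.plus_line}", self.quality)

    @property
    def serialized_bytes(self) -> int:
        """Byte length of this record as four newline-terminated FASTQ lines."""
        return len(self.raw_id) + len(self.bases) + len(self.plus_line) + len(self.quality) + 6


@dataclass(frozen=True, slots=True, order=True)
class PairKey:
    """Normalised read identifier shared by the two mates of a proper pair."""

    value: str


def normalize_key(raw_id: str) -> PairKey:
    """Derive the pairing key from a raw identifier line.

    Strips any whitespace-delimited comment, then one trailing ``/1`` or
    ``/2`` mate designator if present.  Covers both the legacy
    (``name/1`` ``name/2``) and modern Casava (``name 1:N:0:...``) Illumina
    conventions, and is idempotent.
    """
    if not raw_id:
        raise ValueError("empty read identifier")
    parts = raw_id.split(None, 1)
    if not parts:
        raise ValueError(f"blank read identifier {raw_id!r}")
    head = parts[0]
    if len(head) > 2 and head[-2] == "/" and head[-1] in "12":
        head = head[:-2]
    return PairKey(head)


@dataclass(frozen=True, slots=True)
class PairedRecord:
    """Two mate reads joined under one normalised key."""

    key: PairKey
    mate1: ReadRecord
    mate2: ReadRecord

    def __post_init__(self) -> None:
        k1 = normalize_key(self.mate1.raw_id)
        k2 = normalize_key(self.mate2.raw_id)
        if not (k1 == k2 == self.key):
            raise ValueError(
                f"mates {self.mate1.raw_id!r} / {self.mate2.raw_id!r} do not "
                f"share key {self.key.value!r}"
            )

    @property
    def serialized_bytes(self) -> int:
        return self.mate1.serialized_bytes + self.mate2.serialized_bytes


GZIP_MAGIC = b"\x1f\x8b"

PathLike = Union[str, Path]


def open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing gzip (detected by magic bytes)."""
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == GZIP_MAGIC:
            return gzip.open(path, mode, encoding="utf-8", newline="")
        return open(path, mode, encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


def parse_fastq(stream: Iterable[str]) -> Iterator[ReadRecord]:
    """Parse a FASTQ text stream into :class:`ReadRecord`s, strictly.

    The stream must hold complete four-line quartets: identifier line
    starting ``@``, bases, ``+`` line, qualities.  A truncated quartet or a
    bases/quality length mismatch raises :class:`FastqFormatError` naming
    the offending line.  Records are yielded in file order.
    """
    lines = iter(stream)
    lineno = 0
    while True:
        try:
            id_line = next(lines)
        except StopIteration:
            return
        lineno += 1
        id_line = id_line.rstrip("\n")
        if not id_line.startswith("@"):
            raise FastqFormatError(
                f"expected identifier line starting '@', got {id_line!r}", lineno
            )
        if len(id_line) < 2:
            raise FastqFormatError("empty read identifier", lineno)
        quartet = []
        for offset in range(3):
            try:
                quartet.append(next(lines).rstrip("\n"))
            except StopIteration:
                raise FastqFormatError(
                    f"truncated record {id_line!r}: file ends mid-quartet",
                    lineno + offset,
                ) from None
        bases, plus, quality = quartet
        lineno += 3
        if not plus.startswith("+"):
            raise FastqFormatError(
                f"expected '+' separator line, got {plus!r}", lineno - 1
            )
        if len(bases) != len(quality):
            raise FastqFormatError(
                f"record {id_line!r}: sequence length {len(bases)} != "
                f"quality length {len(quality)}",
                lineno,
            )
        yield ReadRecord(
            raw_id=id_line[1:], bases=bases, plus_line=plus[1:], quality=quality
        )


def parse_fastq_path(path: PathLike) -> Iterator[ReadRecord]:
    """Parse a FASTQ file (gzip accepted transparently)."""
    with open_text(path) as handle:
        yield from parse_fastq(handle)


def write_fastq(records: Iterable[ReadRecord], sink: IO[str]) -> int:
    """Write records as four-line FASTQ; returns the number of lines emitted."""
    n_lines = 0
    for record in records:
        for line in record.to_lines():
            sink.write(line)
            sink.write("\n")
        n_lines += 4
    return n_lines


def write_fastq_path(records: Iterable[ReadRecord], path: PathLike) -> int:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        return write_fastq(records, handle)


def records_to_text(records: Iterable[ReadRecord]) -> str:
    buf = io.StringIO()
    write_fastq(records, buf)
    return buf.getvalue()
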