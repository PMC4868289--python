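"""Aligner-backend contract and its two implementations.

The pipeline's map phase is a thin shell: mappers only hand a partition of
reads to an aligner backend and collect the resulting SAM fragment.  The
contract is deliberately minimal — a :class:`BackendRequest` in, a
:class:`SamFragment` out — so any aligner that speaks FASTQ/SAM can stand
behind it.

Two implementations are provided:

* :class:`ExternalBwaBackend` drives an unmodified ``bwa`` executable as a
  subprocess, using only its public command line (mem, the three-phase
  aln/sampe/samse backtrack flow, and bwasw).  Because no aligner source
  is touched, the backend is version-agnostic with respect to ``bwa``.
* :class:`ToyBackend` is a built-in deterministic seed-and-extend Hamming
  aligner over a plain FASTA reference.  It is a hermetic test double for
  the pipeline — simple enough to verify against an exhaustive scan — and
  is never presented as equivalent to a production aligner.
"""

from __future__ import annotations

import enum
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

from .fastq import PairedRecord, PathLike, ReadRecord, normalize_key, open_text, write_fastq_path
from .partitioning import PartitionSpec


class Algorithm(enum.IntEnum):
    """Alignment algorithm selector; codes follow the option API."""

    MEM = 0
    BACKTRACK = 1
    SW = 2


class BackendError(RuntimeError):
    """An aligner invocation failed; carries captured diagnostics."""

    def __init__(self, message: str, returncode: int | None = None, stderr: str = ""):
        super().__init__(message)
        self.returncode = returncode
        self.stderr = stderr


class ConfigurationError(ValueError):
    """A backend was configured with a missing or invalid reference/index."""


class UnsupportedOperationError(NotImplementedError):
    """The backend cannot execute the requested operation."""


@dataclass(frozen=True)
class BackendRequest:
    """One unit of alignment work: a partition plus run parameters."""

    algorithm: Algorithm
    paired: bool
    threads: int
    index_ref: str
    partition: PartitionSpec
    workdir: Path

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError(f"threads must be >= 1, got {self.threads}")


@dataclass(frozen=True)
class SamFragment:
    """Header plus alignment lines produced by one mapper."""

    partition_index: int
    header_lines: tuple[str, ...]
    alignment_lines: tuple[str, ...]

    def __post_init__(self) -> None:
        for line in self.header_lines:
            if not line.startswith("@"):
                raise ValueError(f"header line must start '@': {line!r}")
        for line in self.alignment_lines:
            if line.count("\t") < 10:
                raise ValueError(f"alignment line has < 11 fields: {line!r}")

    def to_text(self) -> str:
        parts = list(self.header_lines) + list(self.alignment_lines)
        return "".join(line + "\n" for line in parts)

    @classmethod
    def from_text(cls, text: str, partition_index: int) -> "SamFragment":
        header: list[str] = []
        alignments: list[str] = []
        for line in text.splitlines():
            if not line:
                continue
            if line.startswith("@") and not alignments:
                header.append(line)
            else:
                alignments.append(line)
        return cls(
            partition_index=partition_index,
            header_lines=tuple(header),
            alignment_lines=tuple(alignments),
        )


def fragment_filename(partition_index: int) -> str:
    return f"part-{partition_index:05d}.sam"


class Backend(Protocol):
    """Anything that can turn a partition of reads into a SAM fragment."""

    def run(self, request: BackendRequest) -> SamFragment: ...


def run_backend(request: BackendRequest, backend: Backend) -> SamFragment:
    """Execute one request and persist the fragment under the workdir.

    Mirrors the one-output-SAM-file-per-map-process convention: the
    fragment is written to ``workdir/part-<index 5-digit>.sam`` as well as
    returned in memory.
    """
    fragment = backend.run(request)
    request.workdir.mkdir(parents=True, exist_ok=True)
    out = request.workdir / fragment_filename(request.partition.index)
    out.write_text(fragment.to_text(), encoding="utf-8")
    return fragment


# ---------------------------------------------------------------------------
# Toy aligner
# ---------------------------------------------------------------------------

#: Fixed mapping quality reported for every mapped toy alignment.
TOY_MAPQ = 37

#: A hit is rejected when more than this fraction of bases mismatch.
TOY_MAX_MISMATCH_FRACTION = 0.25

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ToyHit:
    """Best placement found by the toy aligner for one read."""

    ref_name: str = ""
    pos: int = 0  # 1-based leftmost mapping coordinate
    mismatches: int = 0
    mapped: bool = False
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.mapped and self.pos < 1:
            raise ValueError("mapped hit requires pos >= 1")
        if self.mismatches < 0:
            raise ValueError("mismatch count must be non-negative")


def _scan_orientation(seq: str, reference: dict[str, str], seed_len: int):
    """Yield (mismatches, ref_name, pos0) for every seed-anchored full overlap."""
    seed = seq[:seed_len]
    read_len = len(seq)
    for ref_name in sorted(reference):
        ref_seq = reference[ref_name]
        limit = len(ref_seq) - read_len
        start = ref_seq.find(seed)
        while 0 <= start <= limit:
            window = ref_seq[start : start + read_len]
            mismatches = sum(a != b for a, b in zip(seq, window))
            yield mismatches, ref_name, start
            start = ref_seq.find(seed, start + 1)


def toy_align(read: ReadRecord, reference: dict[str, str], seed_len: int = 20) -> ToyHit:
    """Seed-and-extend placement of one read by Hamming distance.

    The first ``seed_len`` bases are exact-matched at every reference
    offset (both the read and its reverse complement are tried); each seed
    hit is extended by whole-read Hamming comparison.  The hit with the
    fewest mismatches wins, ties broken by smallest
    ``(ref_name, pos, strand)`` with the forward strand preferred.  A read
    is unmapped when no seed matches or when the best hit's mismatch
    fraction exceeds ``TOY_MAX_MISMATCH_FRACTION``.
    """
    if not reference:
        raise ValueError("reference is empty")
    if len(read.bases) < seed_len:
        raise ValueError(
            f"read {read.raw_id!r} shorter ({len(read.bases)}) than seed length {seed_len}"
        )
    seq_fwd = read.bases.upper()
    reference_upper = reference  # caller supplies uppercase sequences
    best: tuple[int, str, int, int] | None = None
    for is_reverse, seq in ((0, seq_fwd), (1, reverse_complement(seq_fwd))):
        for mismatches, ref_name, pos0 in _scan_orientation(seq, reference_upper, seed_len):
            candidate = (mismatches, ref_name, pos0, is_reverse)
            if best is None or candidate < best:
                best = candidate
    if best is None:
        return ToyHit()
    mismatches, ref_name, pos0, is_reverse = best
    if mismatches > TOY_MAX_MISMATCH_FRACTION * len(read.bases):
        return ToyHit()
    return ToyHit(
        ref_name=ref_name,
        pos=pos0 + 1,
        mismatches=mismatches,
        mapped=True,
        reverse=bool(is_reverse),
    )


@dataclass(frozen=True)
class MateInfo:
    """Pairing context for SAM flag construction."""

    mate_number: int  # 1 or 2
    mate_hit: Optional[ToyHit] = None


# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_MATE = 0x40
FLAG_SECOND_MATE = 0x80


def toy_hit_to_sam(read: ReadRecord, mate_info: Optional[MateInfo], hit: ToyHit) -> str:
    """Render one toy hit as a syntactically valid SAM alignment line."""
    flag = 0
    if mate_info is not None:
        flag |= FLAG_PAIRED
        flag |= FLAG_FIRST_MATE if mate_info.mate_number == 1 else FLAG_SECOND_MATE
        mate_hit = mate_info.mate_hit
        if mate_hit is None or not mate_hit.mapped:
            flag |= FLAG_MATE_UNMAPPED
        elif mate_hit.reverse:
            flag |= FLAG_MATE_REVERSE
    if hit.mapped:
        if hit.reverse:
            flag |= FLAG_REVERSE
        rname, pos, mapq, cigar = hit.ref_name, hit.pos, TOY_MAPQ, f"{len(read.bases)}M"
    else:
        flag |= FLAG_UNMAPPED
        rname, pos, mapq, cigar = "*", 0, 0, "*"
    rnext, pnext = "*", 0
    if mate_info is not None and mate_info.mate_hit is not None and mate_info.mate_hit.mapped:
        rnext = "=" if (hit.mapped and mate_info.mate_hit.ref_name == hit.ref_name) else mate_info.mate_hit.ref_name
        pnext = mate_info.mate_hit.pos
    seq, qual = read.bases, read.quality
    if hit.mapped and hit.reverse:
        seq, qual = reverse_complement(seq), qual[::-1]
    fields = [
        normalize_key(read.raw_id).value,
        str(flag),
        rname,
        str(pos),
        str(mapq),
        cigar,
        rnext,
        str(pnext),
        "0",
        seq if seq else "*",
        qual if qual else "*",
        f"NM:i:{hit.mismatches}" if hit.mapped else "NM:i:0",
    ]
    return "\t".join(fields)


def load_fasta(path: PathLike) -> dict[str, str]:
    """Read a (possibly multi-record, possibly wrapped) FASTA into memory."""
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    with open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise ConfigurationError(f"duplicate FASTA record {record.id!r} in {path}")
            sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ConfigurationError(f"FASTA {path} holds no sequences")
    return sequences


class ToyBackend:
    """Deterministic built-in aligner over a plain FASTA reference.

    Identical requests produce byte-identical fragments.  The algorithm
    selector is accepted (the closed MEM/backtrack/SW set) but does not
    change behaviour — the toy aligner has a single mode; anything outside
    the closed set is an :class:`UnsupportedOperationError`.
    """

    def __init__(self, reference_path: PathLike, seed_len: int = 20):
        self.reference_path = str(reference_path)
        self.seed_len = seed_len
        self._reference: dict[str, str] | None = None

    @property
    def reference(self) -> dict[str, str]:
        if self._reference is None:
            if not Path(self.reference_path).exists():
                raise ConfigurationError(f"reference FASTA not found: {self.reference_path}")
            self._reference = load_fasta(self.reference_path)
        return self._reference

    def header(self) -> tuple[str, ...]:
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        for name in sorted(self.reference):
            lines.append(f"@SQ\tSN:{name}\tLN:{len(self.reference[name])}")
        lines.append("@PG\tID:shardalign-toy\tPN:shardalign-toy\tVN:0.1.0")
        return tuple(lines)

    def run(self, request: BackendRequest) -> SamFragment:
        if request.algorithm not in tuple(Algorithm):
            raise UnsupportedOperationError(
                f"toy backend does not know algorithm {request.algorithm!r}"
            )
        reference = self.reference
        alignments: list[str] = []
        for record in request.partition.records:
            if isinstance(record, PairedRecord):
                hit1 = toy_align(record.mate1, reference, self.seed_len)
                hit2 = toy_align(record.mate2, reference, self.seed_len)
                alignments.append(
                    toy_hit_to_sam(record.mate1, MateInfo(1, hit2), hit1)
                )
                alignments.append(
                    toy_hit_to_sam(record.mate2, MateInfo(2, hit1), hit2)
                )
            else:
                _, read = record
                hit = toy_align(read, reference, self.seed_len)
                alignments.append(toy_hit_to_sam(read, None, hit))
        return SamFragment(
            partition_index=request.partition.index,
            header_lines=self.header(),
            alignment_lines=tuple(alignments),
        )


# ---------------------------------------------------------------------------
# External bwa backend
# ---------------------------------------------------------------------------

#: bwa index file extensions checked before launching the aligner.
BWA_INDEX_EXTENSIONS = (".bwt", ".pac", ".sa", ".ann", ".amb")


class ExternalBwaBackend:
    """Subprocess driver for an unmodified ``bwa`` executable.

    Supports all three algorithms through bwa's public command line:
    ``mem`` and ``bwasw`` as single invocations, and the backtrack flow as
    its three phases (``aln`` per input file, then ``sampe``/``samse``)
    encapsulated behind one call so the multi-step protocol is invisible
    to the caller.  The request's thread count is passed verbatim as
    ``-t``.
    """

    def __init__(
        self,
        executable: str = "bwa",
        timeout: float | None = 3600.0,
        extra_args: Sequence[str] = (),
    ):
        self.executable = executable
        self.timeout = timeout
        self.extra_args = tuple(extra_args)

    # -- command construction (separated for inspectability) ----------------

    def mem_command(self, request: BackendRequest, fastqs: list[Path]) -> list[str]:
        return [
            self.executable, "mem", "-t", str(request.threads),
            *self.extra_args, request.index_ref, *map(str, fastqs),
        ]

    def bwasw_command(self, request: BackendRequest, fastqs: list[Path]) -> list[str]:
        return [
            self.executable, "bwasw", "-t", str(request.threads),
            *self.extra_args, request.index_ref, *map(str, fastqs),
        ]

    def aln_command(self, request: BackendRequest, fastq: Path) -> list[str]:
        return [
            self.executable, "aln", "-t", str(request.threads),
            *self.extra_args, request.index_ref, str(fastq),
        ]

    def _check_index(self, request: BackendRequest) -> None:
        missing = [
            ext for ext in BWA_INDEX_EXTENSIONS
            if not Path(request.index_ref + ext).exists()
        ]
        if missing:
            raise ConfigurationError(
                f"bwa index not found at prefix {request.index_ref!r} "
                f"(missing {', '.join(missing)}); run 'bwa index' first"
            )

    def _run(self, argv: list[str], stdout_path: Path) -> None:
        try:
            with open(stdout_path, "wb") as out:
                proc = subprocess.run(
                    argv, stdout=out, stderr=subprocess.PIPE, timeout=self.timeout
                )
        except FileNotFoundError as exc:
            raise BackendError(f"aligner executable not found: {argv[0]!r}") from exc
        except subprocess.TimeoutExpired as exc:
            raise BackendError(f"aligner timed out after {self.timeout}s: {argv}") from exc
        if proc.returncode != 0:
            stderr = proc.stderr.decode("utf-8", "replace")
            raise BackendError(
                f"aligner exited with status {proc.returncode}: {' '.join(argv)}\n{stderr}",
                returncode=proc.returncode,
                stderr=stderr,
            )

    def _write_partition(self, request: BackendRequest) -> list[Path]:
        request.workdir.mkdir(parents=True, exist_ok=True)
        stem = f"part-{request.partition.index:05d}"
        if request.paired:
            mates1, mates2 = [], []
            for record in request.partition.records:
                if not isinstance(record, PairedRecord):
                    raise ValueError("paired request holds unpaired records")
                mates1.append(record.mate1)
                mates2.append(record.mate2)
            p1 = request.workdir / f"{stem}_1.fastq"
            p2 = request.workdir / f"{stem}_2.fastq"
            write_fastq_path(mates1, p1)
            write_fastq_path(mates2, p2)
            return [p1, p2]
        reads = [r[1] if isinstance(r, tuple) else r for r in request.partition.records]
        p1 = request.workdir / f"{stem}.fastq"
        write_fastq_path(reads, p1)
        return [p1]

    def run(self, request: BackendRequest) -> SamFragment:
        self._check_index(request)
        fastqs = self._write_partition(request)
        stem = f"part-{request.partition.index:05d}"
        sam_path = request.workdir / f"{stem}.raw.sam"
        if request.algorithm is Algorithm.MEM:
            self._run(self.mem_command(request, fastqs), sam_path)
        elif request.algorithm is Algorithm.SW:
            self._run(self.bwasw_command(request, fastqs), sam_path)
        elif request.algorithm is Algorithm.BACKTRACK:
            sais = []
            for fq in fastqs:
                sai = fq.with_suffix(".sai")
                self._run(self.aln_command(request, fq), sai)
                sais.append(sai)
            finisher = "sampe" if request.paired else "samse"
            argv = [
                self.executable, finisher, request.index_ref,
                *map(str, sais), *map(str, fastqs),
            ]
            self._run(argv, sam_path)
        else:  # pragma: no cover - closed enum
            raise UnsupportedOperationError(f"unknown algorithm {request.algorithm!r}")
        text = sam_path.read_text(encoding="utf-8")
        return SamFragment.from_text(text, partition_index=request.partition.index)


def bwa_available(executable: str = "bwa") -> bool:
    return shutil.which(executable) is not None
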