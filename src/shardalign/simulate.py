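"""Hermetic test-data generator: reference FASTA and paired FASTQ with truth.

Emulates the structure of a paired-end sequencing dataset at toy scale: a
uniform-random reference sequence, read pairs sampled from opposite ends
of fixed-length fragments (mate 2 reverse-complemented), independent
per-base substitutions at a configurable rate, and optional deliberate
faults (orphan reads, duplicate keys, shuffled file-2 order) to exercise
the pairing error paths.  Everything is a pure function of the spec, so a
fixed seed reproduces byte-identical files; a truth table records each
pair's true mapping coordinates and strand.

What this deliberately does not model: indels, quality-score profiles,
read-length or insert-size distributions, adapter or contaminant
sequence.  Qualities are a constant high-quality character — the pipeline
never interprets them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .backends import reverse_complement
from .fastq import ReadRecord, write_fastq_path

#: Constant quality character (Phred 40 in Sanger encoding).
QUALITY_CHAR = "I"

#: Bases between the two mates of a fragment (fixed-size insert model).
DEFAULT_INSERT_GAP = 40

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; all outputs are functions of it."""

    ref_length: int = 5000
    n_pairs: int = 100
    read_length: int = 70
    substitution_rate: float = 0.01
    orphan_count: int = 0
    duplicate_key_count: int = 0
    shuffle_file2: bool = False
    seed: int = 0
    insert_gap: int = DEFAULT_INSERT_GAP

    def __post_init__(self) -> None:
        if self.read_length > self.ref_length:
            raise ValueError(
                f"read_length {self.read_length} exceeds ref_length {self.ref_length}"
            )
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError(f"substitution_rate must be in [0,1], got {self.substitution_rate}")
        if self.n_pairs and 2 * self.read_length + self.insert_gap > self.ref_length:
            raise ValueError("reference too short for the fragment model")


@dataclass(frozen=True)
class TruthEntry:
    """Ground-truth placement of one pair (1-based leftmost coordinates)."""

    key: str
    pos1: int
    pos2: int
    strand2: str  # '-': mate 2 stored reverse-complemented


@dataclass(frozen=True)
class FixtureDataset:
    reference_path: Path
    fastq1: Path
    fastq2: Path
    truth_path: Path
    truth: tuple[TruthEntry, ...]
    records1: tuple[ReadRecord, ...]
    records2: tuple[ReadRecord, ...]
    reference: dict[str, str]


REF_NAME = "ref1"


def generate_reference(spec: FixtureSpec, out_path: Path | str) -> str:
    """Write a uniform-random A/C/G/T reference FASTA; returns the sequence."""
    rng = random.Random(spec.seed)
    sequence = "".join(rng.choice(_BASES) for _ in range(spec.ref_length))
    out_path = Path(out_path)
    with open(out_path, "w", encoding="utf-8", newline="") as out:
        out.write(f">{REF_NAME} synthetic uniform-random reference\n")
        for start in range(0, len(sequence), 70):
            out.write(sequence[start : start + 70] + "\n")
    return sequence


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    """Independent per-base substitution to a different base.

    Substituted positions are drawn by geometric inter-arrival jumps,
    which is distributionally identical to a per-base Bernoulli trial but
    costs O(substitutions) instead of O(length).
    """
    if rate <= 0.0:
        return seq
    if rate >= 1.0:
        return "".join(rng.choice([b for b in _BASES if b != base]) for base in seq)
    import math

    out = list(seq)
    log_keep = math.log1p(-rate)
    i = 0
    while True:
        i += int(math.log(1.0 - rng.random()) / log_keep)
        if i >= len(out):
            break
        out[i] = rng.choice([b for b in _BASES if b != out[i]])
        i += 1
    return "".join(out)


def generate_pairs(
    spec: FixtureSpec, reference: str, out_dir: Path | str, reference_path: Path | str
) -> FixtureDataset:
    """Sample read pairs from the reference and write the two mate files.

    Mate 1 is the forward strand of the fragment's left end; mate 2 is the
    reverse complement of its right end, a fixed ``insert_gap`` bases
    downstream.  Substitutions are applied independently per base.  The
    truth table (key, pos1, pos2, strand2) is written as TSV alongside the
    FASTQ files.  Requested faults are injected exactly: ``orphan_count``
    unmatched reads appended alternately to the two files,
    ``duplicate_key_count`` repeated-key records appended to file 1, and
    ``shuffle_file2`` permuting file 2's record order.
    """
    # separate stream from the reference so ref and reads decouple cleanly
    rng = random.Random(spec.seed * 2 + 1_000_003)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L, gap = spec.read_length, spec.insert_gap
    max_start = spec.ref_length - (2 * L + gap)
    records1: list[ReadRecord] = []
    records2: list[ReadRecord] = []
    truth: list[TruthEntry] = []
    qual = QUALITY_CHAR * L
    for i in range(spec.n_pairs):
        key = f"sim.{spec.seed}.{i:06d}"
        p1 = rng.randint(0, max_start)
        p2 = p1 + L + gap
        frag1 = reference[p1 : p1 + L]
        frag2 = reference[p2 : p2 + L]
        bases1 = _mutate(rng, frag1, spec.substitution_rate)
        bases2 = reverse_complement(_mutate(rng, frag2, spec.substitution_rate))
        records1.append(ReadRecord(raw_id=f"{key}/1", bases=bases1, quality=qual))
        records2.append(ReadRecord(raw_id=f"{key}/2", bases=bases2, quality=qual))
        truth.append(TruthEntry(key=key, pos1=p1 + 1, pos2=p2 + 1, strand2="-"))
    for i in range(spec.orphan_count):
        p = rng.randint(0, spec.ref_length - L)
        record = ReadRecord(
            raw_id=f"orphan.{spec.seed}.{i:06d}/{1 if i % 2 == 0 else 2}",
            bases=reference[p : p + L],
            quality=qual,
        )
        (records1 if i % 2 == 0 else records2).append(record)
    for i in range(spec.duplicate_key_count):
        donor = records1[i % spec.n_pairs]
        records1.append(ReadRecord(raw_id=donor.raw_id, bases=donor.bases, quality=donor.quality))
    if spec.shuffle_file2:
        rng.shuffle(records2)
    fastq1 = out_dir / "reads_1.fastq"
    fastq2 = out_dir / "reads_2.fastq"
    write_fastq_path(records1, fastq1)
    write_fastq_path(records2, fastq2)
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8", newline="") as out:
        out.write("key\tpos1\tpos2\tstrand2\n")
        for entry in truth:
            out.write(f"{entry.key}\t{entry.pos1}\t{entry.pos2}\t{entry.strand2}\n")
    return FixtureDataset(
        reference_path=Path(reference_path),
        fastq1=fastq1,
        fastq2=fastq2,
        truth_path=truth_path,
        truth=tuple(truth),
        records1=tuple(records1),
        records2=tuple(records2),
        reference={REF_NAME: reference},
    )


def generate_dataset(spec: FixtureSpec, out_dir: Path | str) -> FixtureDataset:
    """Convenience: reference plus pairs in one call, under one directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference_path = out_dir / "reference.fasta"
    reference = generate_reference(spec, reference_path)
    return generate_pairs(spec, reference, out_dir, reference_path)
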