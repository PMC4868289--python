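"""Aligner backends: toy aligner vs exhaustive oracle, SAM rendering,
external-command construction and error paths."""

import random
import stat

import pysam
import pytest

from shardalign import (
    Algorithm,
    BackendError,
    BackendRequest,
    ConfigurationError,
    ExternalBwaBackend,
    FixtureSpec,
    MateInfo,
    ReadRecord,
    SamFragment,
    ToyBackend,
    ToyHit,
    UnsupportedOperationError,
    generate_dataset,
    make_partitions,
    pair_join,
    reverse_complement,
    run_backend,
    toy_align,
    toy_hit_to_sam,
)
from shardalign.backends import (
    FLAG_FIRST_MATE,
    FLAG_PAIRED,
    FLAG_REVERSE,
    FLAG_UNMAPPED,
    TOY_MAPQ,
    fragment_filename,
)

from .conftest import exhaustive_best_hit


def _read(bases, raw_id="r1"):
    return ReadRecord(raw_id=raw_id, bases=bases, quality="I" * len(bases))


REFERENCE = {"chrA": "ACGTACGGTACCTTAGGACCAGTACCATTAGGCATCAGGACTACCAGTAGAGATTACACA"}


class TestToyAlign:
    def test_reference_prefix_maps_at_position_one(self):
        hit = toy_align(_read(REFERENCE["chrA"][:30]), REFERENCE, seed_len=10)
        assert hit == ToyHit(ref_name="chrA", pos=1, mismatches=0, mapped=True, reverse=False)

    def test_all_n_read_is_unmapped(self):
        hit = toy_align(_read("N" * 30), REFERENCE, seed_len=10)
        assert not hit.mapped
        assert hit.pos == 0

    def test_reverse_complement_read_is_placed_on_reverse_strand(self):
        fragment = REFERENCE["chrA"][10:40]
        hit = toy_align(_read(reverse_complement(fragment)), REFERENCE, seed_len=10)
        assert hit.mapped and hit.reverse
        assert hit.pos == 11

    def test_read_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            toy_align(_read("ACGT"), REFERENCE, seed_len=10)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            toy_align(_read("ACGTACGTACGT"), {}, seed_len=4)

    def test_excess_mismatch_fraction_is_unmapped(self):
        # seed matches, but the extension is over 25% mismatched
        seq = REFERENCE["chrA"][:12] + "T" * 20
        ref = {"chrA": REFERENCE["chrA"][:12] + "G" * 20 + REFERENCE["chrA"][32:]}
        hit = toy_align(_read(seq), ref, seed_len=12)
        assert not hit.mapped

    def test_tie_break_prefers_smallest_position(self):
        # identical 12-mer at offsets 0 and 20
        motif = "ACGTACGTACGT"
        ref = {"c": motif + "T" * 8 + motif + "G" * 8}
        hit = toy_align(_read(motif), ref, seed_len=6)
        assert (hit.ref_name, hit.pos, hit.mismatches) == ("c", 1, 0)

    def test_agrees_with_exhaustive_scan_on_mutated_reads(self, tmp_path):
        """200 reads with <= 2 substitutions: seed-and-extend equals the
        vectorised every-offset scan, including tie-breaks."""
        dataset = generate_dataset(
            FixtureSpec(n_pairs=100, substitution_rate=0.0, seed=77), tmp_path
        )
        reference = dataset.reference
        rng = random.Random(123)
        reads = []
        for record in (*dataset.records1[:100], *dataset.records2[:100]):
            bases = list(record.bases)
            for pos in rng.sample(range(len(bases)), k=rng.randint(0, 2)):
                bases[pos] = rng.choice([b for b in "ACGT" if b != bases[pos]])
            reads.append(_read("".join(bases), raw_id=record.raw_id))
        seed_len = 20
        disagreements = [
            (read.raw_id, got, want)
            for read in reads
            for got, want in [(
                toy_align(read, reference, seed_len),
                exhaustive_best_hit(read.bases, reference, seed_len),
            )]
            if got != want
        ]
        assert disagreements == []


class TestToySam:
    def test_unmapped_hit_follows_sam_conventions(self):
        line = toy_hit_to_sam(_read("ACGT"), None, ToyHit())
        fields = line.split("\t")
        assert int(fields[1]) & FLAG_UNMAPPED
        assert fields[3] == "0"
        assert fields[5] == "*"

    def test_mapped_first_mate_flags(self):
        hit = ToyHit(ref_name="chrA", pos=5, mismatches=1, mapped=True)
        mate_hit = ToyHit(ref_name="chrA", pos=40, mismatches=0, mapped=True, reverse=True)
        line = toy_hit_to_sam(_read("ACGT", "p/1"), MateInfo(1, mate_hit), hit)
        fields = line.split("\t")
        flag = int(fields[1])
        assert flag & FLAG_PAIRED and flag & FLAG_FIRST_MATE
        assert not flag & FLAG_UNMAPPED
        assert fields[0] == "p"  # mate designator stripped from QNAME
        assert fields[4] == str(TOY_MAPQ)
        assert fields[6] == "="
        assert fields[7] == "40"

    def test_reverse_hit_emits_reverse_complemented_sequence(self):
        hit = ToyHit(ref_name="chrA", pos=3, mismatches=0, mapped=True, reverse=True)
        line = toy_hit_to_sam(_read("ACGT"), None, hit)
        fields = line.split("\t")
        assert int(fields[1]) & FLAG_REVERSE
        assert fields[9] == reverse_complement("ACGT")

    def test_fragment_passes_pysam_validation(self, tmp_path, small_dataset):
        backend = ToyBackend(small_dataset.reference_path)
        pairs, _ = pair_join(small_dataset.records1, small_dataset.records2)
        partition = make_partitions(pairs, 1)[0]
        request = BackendRequest(
            algorithm=Algorithm.MEM, paired=True, threads=1,
            index_ref=str(small_dataset.reference_path),
            partition=partition, workdir=tmp_path,
        )
        fragment = run_backend(request, backend)
        sam_path = tmp_path / fragment_filename(0)
        assert sam_path.exists()  # persisted per-partition file
        with pysam.AlignmentFile(str(sam_path), "r") as sam:
            records = list(sam)
        assert len(records) == 2 * len(pairs)
        for rec in records:
            assert rec.flag & 0x1  # paired
            if not rec.is_unmapped:
                assert rec.reference_start >= 0
                assert rec.cigarstring.endswith("M")
        for line in fragment.alignment_lines:
            assert line.count("\t") >= 10


class TestToyBackend:
    def test_identical_requests_give_byte_identical_fragments(self, tmp_path, small_dataset):
        pairs, _ = pair_join(small_dataset.records1, small_dataset.records2)
        partition = make_partitions(pairs, 2)[0]
        def fragment():
            backend = ToyBackend(small_dataset.reference_path)
            request = BackendRequest(
                algorithm=Algorithm.MEM, paired=True, threads=1,
                index_ref=str(small_dataset.reference_path),
                partition=partition, workdir=tmp_path,
            )
            return backend.run(request).to_text()
        assert fragment() == fragment()

    def test_empty_partition_yields_header_only_fragment(self, tmp_path, small_dataset):
        from shardalign import PartitionSpec

        backend = ToyBackend(small_dataset.reference_path)
        request = BackendRequest(
            algorithm=Algorithm.MEM, paired=True, threads=1,
            index_ref=str(small_dataset.reference_path),
            partition=PartitionSpec(index=0), workdir=tmp_path,
        )
        fragment = backend.run(request)
        assert fragment.alignment_lines == ()
        assert any(l.startswith("@SQ") for l in fragment.header_lines)

    def test_unknown_algorithm_is_unsupported(self, tmp_path, small_dataset):
        from shardalign import PartitionSpec

        backend = ToyBackend(small_dataset.reference_path)
        request = BackendRequest(
            algorithm=99, paired=True, threads=1,
            index_ref=str(small_dataset.reference_path),
            partition=PartitionSpec(index=0), workdir=tmp_path,
        )
        with pytest.raises(UnsupportedOperationError):
            backend.run(request)

    def test_missing_reference_is_a_configuration_error(self, tmp_path):
        backend = ToyBackend(tmp_path / "nope.fasta")
        with pytest.raises(ConfigurationError):
            backend.reference


class TestExternalBackend:
    def _request(self, tmp_path, small_dataset, threads=1, algorithm=Algorithm.MEM):
        pairs, _ = pair_join(small_dataset.records1, small_dataset.records2)
        partition = make_partitions(pairs, 1)[0]
        return BackendRequest(
            algorithm=algorithm, paired=True, threads=threads,
            index_ref=str(tmp_path / "idx"), partition=partition, workdir=tmp_path,
        )

    def test_threads_value_reaches_command_line_verbatim(self, tmp_path, small_dataset):
        backend = ExternalBwaBackend()
        request = self._request(tmp_path, small_dataset, threads=4)
        argv = backend.mem_command(request, [tmp_path / "a.fq", tmp_path / "b.fq"])
        assert argv[:4] == ["bwa", "mem", "-t", "4"]
        assert backend.aln_command(request, tmp_path / "a.fq")[2:4] == ["-t", "4"]

    def test_missing_index_is_a_configuration_error(self, tmp_path, small_dataset):
        backend = ExternalBwaBackend()
        with pytest.raises(ConfigurationError, match="index"):
            backend.run(self._request(tmp_path, small_dataset))

    def test_failing_executable_surfaces_exit_status(self, tmp_path, small_dataset):
        for ext in (".bwt", ".pac", ".sa", ".ann", ".amb"):
            (tmp_path / ("idx" + ext)).touch()
        fake = tmp_path / "fakebwa"
        fake.write_text("#!/bin/sh\necho 'simulated aligner crash' >&2\nexit 3\n")
        fake.chmod(fake.stat().st_mode | stat.S_IXUSR)
        backend = ExternalBwaBackend(executable=str(fake))
        with pytest.raises(BackendError) as err:
            backend.run(self._request(tmp_path, small_dataset))
        assert err.value.returncode == 3
        assert "simulated aligner crash" in err.value.stderr

    def test_absent_executable_is_a_backend_error(self, tmp_path, small_dataset):
        for ext in (".bwt", ".pac", ".sa", ".ann", ".amb"):
            (tmp_path / ("idx" + ext)).touch()
        backend = ExternalBwaBackend(executable=str(tmp_path / "no-such-aligner"))
        with pytest.raises(BackendError, match="not found"):
            backend.run(self._request(tmp_path, small_dataset))


def test_sam_fragment_invariants():
    with pytest.raises(ValueError):
        SamFragment(0, header_lines=("HD no at",), alignment_lines=())
    with pytest.raises(ValueError):
        SamFragment(0, header_lines=(), alignment_lines=("too\tfew\tfields",))
    text = "@HD\tVN:1.6\n@SQ\tSN:c\tLN:9\nr\t0\tc\t1\t37\t4M\t*\t0\t0\tACGT\tIIII\n"
    fragment = SamFragment.from_text(text, partition_index=2)
    assert fragment.header_lines == ("@HD\tVN:1.6", "@SQ\tSN:c\tLN:9")
    assert len(fragment.alignment_lines) == 1
    assert fragment.to_text() == text
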