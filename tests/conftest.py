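"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import threading
from dataclasses import dataclass, field

import numpy as np
import pytest

from shardalign import (
    FixtureSpec,
    SamFragment,
    ToyHit,
    generate_dataset,
    reverse_complement,
)
from shardalign.backends import TOY_MAX_MISMATCH_FRACTION


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """30 clean pairs sampled from a 5 kb reference (1% substitutions)."""
    return generate_dataset(
        FixtureSpec(n_pairs=30, seed=11), tmp_path_factory.mktemp("small")
    )


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Substitution-free pairs: every mate matches the reference exactly."""
    return generate_dataset(
        FixtureSpec(n_pairs=40, substitution_rate=0.0, seed=5),
        tmp_path_factory.mktemp("clean"),
    )


def exhaustive_best_hit(
    bases: str,
    reference: dict[str, str],
    seed_len: int,
    max_fraction: float = TOY_MAX_MISMATCH_FRACTION,
) -> ToyHit:
    """Independent placement oracle: vectorised scan of every offset.

    Enumerates every full-overlap offset on both strands with numpy
    sliding windows, keeps offsets whose first ``seed_len`` bases match
    exactly, and picks the minimum of (mismatches, ref_name, pos, strand)
    with the forward strand preferred.  Shares no code with the
    seed-and-extend implementation it checks.
    """
    candidates: list[tuple[int, str, int, int]] = []
    for is_reverse, seq in ((0, bases.upper()), (1, reverse_complement(bases.upper()))):
        read = np.frombuffer(seq.encode(), dtype=np.uint8)
        for name in sorted(reference):
            ref = np.frombuffer(reference[name].encode(), dtype=np.uint8)
            if len(ref) < len(read):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, len(read))
            mismatches = (windows != read).sum(axis=1)
            seed_exact = (windows[:, :seed_len] != read[:seed_len]).sum(axis=1) == 0
            for offset in np.nonzero(seed_exact)[0]:
                candidates.append((int(mismatches[offset]), name, int(offset), is_reverse))
    if not candidates:
        return ToyHit()
    best = min(candidates)
    if best[0] > max_fraction * len(bases):
        return ToyHit()
    return ToyHit(
        ref_name=best[1], pos=best[2] + 1, mismatches=best[0],
        mapped=True, reverse=bool(best[3]),
    )


def join_oracle(records1, records2):
    """Brute-force pairing oracle: hash map of file 1, probed with file 2."""
    from shardalign import normalize_key

    lookup = {}
    for record in records1:
        lookup[normalize_key(record.raw_id)] = record
    pairs = set()
    for record in records2:
        key = normalize_key(record.raw_id)
        if key in lookup:
            pairs.add((key.value, lookup[key].bases, record.bases))
    return pairs


def pair_multiset(pairs):
    """Canonical multiset representation of a pair stream."""
    from collections import Counter

    return Counter((p.key.value, p.mate1.bases, p.mate2.bases) for p in pairs)


def alignment_multiset(sam_path):
    """Multiset of alignment lines of a SAM file (header excluded)."""
    from collections import Counter

    with open(sam_path) as handle:
        return Counter(l.rstrip("\n") for l in handle if not l.startswith("@"))


@dataclass
class RecordingBackend:
    """Wraps a backend to record requests and peak concurrent invocations."""

    inner: object
    requests: list = field(default_factory=list)
    peak_concurrency: int = 0
    fail_first_attempts: int = 0  # raise on the first N run() calls
    _active: int = 0
    _calls: int = 0
    _lock: threading.Lock = field(default_factory=threading.Lock)

    def run(self, request) -> SamFragment:
        import time

        with self._lock:
            self._calls += 1
            call_number = self._calls
            self._active += 1
            self.peak_concurrency = max(self.peak_concurrency, self._active)
            self.requests.append(request)
        try:
            if call_number <= self.fail_first_attempts:
                raise RuntimeError(f"injected failure on call {call_number}")
            time.sleep(0.01)  # hold the slot so overlap is observable
            return self.inner.run(request)
        finally:
            with self._lock:
                self._active -= 1
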