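"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from repeatchip.alignment import AlignmentHit, Read, reverse_complement

_BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; any other read base -> 5, target base -> 4.

    Distinct sentinels guarantee that non-ACGT bases mismatch everything,
    including each other (N vs N is a mismatch).
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = np.full(arr.shape, 4, dtype=np.int16)
    for i, b in enumerate(b"ACGT"):
        out[arr == bytes([b])] = i
    return out


def brute_force_hits(reads, records, max_mismatch=1):
    """Exhaustive sliding-window oracle: every ungapped alignment of every
    read on both strands with <= max_mismatch mismatches. Independent of the
    package's seeded aligner."""
    encoded = {name: encode(seq) for name, seq in records.items()}
    hits = set()
    for read in reads:
        for strand in "+-":
            seq = read.sequence if strand == "+" else reverse_complement(read.sequence)
            q = encode(seq)
            q[q == 4] = 5  # read-side sentinel
            L = len(q)
            for name, t in encoded.items():
                if len(t) < L:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(t, L)
                mm = (windows != q).sum(axis=1)
                for off in np.nonzero(mm <= max_mismatch)[0]:
                    hits.add(
                        AlignmentHit(read.read_id, name, int(off), strand, int(mm[off]))
                    )
    return sorted(hits, key=lambda h: (h.read_id, h.target, h.offset, h.strand))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def mutate(seq: str, positions, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        out[p] = _BASES[(_BASES.index(out[p]) + rng.integers(1, 4)) % 4]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_library(tmp_path):
    """Two-entry Repbase-style canonical library FASTA."""
    path = tmp_path / "lib.fa"
    path.write_text(
        ">IAPLTR1#LTR/ERVK\n"
        "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT\n"
        ">B1#SINE/Alu\n"
        "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA\n"
    )
    return path
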