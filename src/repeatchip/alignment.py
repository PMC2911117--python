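"""Full-sensitivity ungapped short-read alignment.

Finds EVERY ungapped alignment of each read, on both strands, with at most
``max_mismatch`` mismatches. Sensitivity is guaranteed by pigeonhole
seeding: a read is split into ``max_mismatch + 1`` non-overlapping chunks,
so any admissible alignment leaves at least one chunk mismatch-free; each
chunk's leading k-mer is looked up exactly in a k-mer index of the targets
and candidates are verified by direct comparison.

Bases outside {A,C,G,T} (in reads or targets) mismatch everything — in
particular the all-'N' spacers of a repeat assembly can never be matched,
so alignments never bridge assembly segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .reference import RepeatAssembly

_ACGT = frozenset("ACGT")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MAX_SEED_LEN = 16


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    target: str  # record name: repeat type or chromosome
    offset: int  # 0-based position on the target plus strand
    strand: str  # '+' or '-'
    mismatches: int


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _mismatch_count(read: str, ref: str, offset: int, limit: int) -> int:
    """Mismatches of ``read`` vs ``ref[offset:offset+len(read)]``, early exit at >limit."""
    mm = 0
    for i, base in enumerate(read):
        r = ref[offset + i]
        if base != r or base not in _ACGT:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _chunk_starts(length: int, n_chunks: int) -> list[int]:
    """Start offsets of n contiguous chunks covering [0, length)."""
    base, extra = divmod(length, n_chunks)
    starts, pos = [], 0
    for i in range(n_chunks):
        starts.append(pos)
        pos += base + (1 if i >= n_chunks - extra else 0)
    return starts


class KmerIndex:
    """Exact k-mer index over a set of named target sequences."""

    def __init__(self, records: Mapping[str, str], k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.records = dict(records)
        index: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.records):
            seq = self.records[name]
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if _ACGT.issuperset(kmer):
                    index.setdefault(kmer, []).append((name, pos))
        self.index = index

    def lookup(self, kmer: str) -> Sequence[tuple[str, int]]:
        return self.index.get(kmer, ())


def _target_records(targets: Mapping[str, str] | RepeatAssembly) -> dict[str, str]:
    if isinstance(targets, RepeatAssembly):
        return targets.records
    return dict(targets)


def align_all_hits(
    reads: Iterable[Read],
    targets: Mapping[str, str] | RepeatAssembly,
    max_mismatch: int = 1,
    index: KmerIndex | None = None,
) -> list[AlignmentHit]:
    """All ungapped alignments of every read with ≤ ``max_mismatch`` mismatches.

    Reads too short to be split into ``max_mismatch + 1`` seeds are reported
    as unalignable (they simply produce no hits). Output order is sorted and
    independent of read and index construction order.
    """
    reads = list(reads)
    records = _target_records(targets)
    n_seeds = max_mismatch + 1
    lengths = [len(r.sequence) for r in reads if len(r.sequence) >= n_seeds]
    if not lengths or not records:
        return []
    if index is None or index.records != records:
        k = max(1, min(MAX_SEED_LEN, min(lengths) // n_seeds))
        index = KmerIndex(records, k)
    k = index.k

    hits: dict[tuple[str, str, int, str], int] = {}
    for read in reads:
        seq = read.sequence.upper()
        L = len(seq)
        if L // n_seeds < 1 or L < k:
            continue
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            seen_offsets: set[tuple[str, int]] = set()
            for start in _chunk_starts(L, n_seeds):
                start = min(start, L - k)
                seed = oriented[start : start + k]
                for name, pos in index.lookup(seed):
                    offset = pos - start
                    if offset < 0 or offset + L > len(index.records[name]):
                        continue
                    if (name, offset) in seen_offsets:
                        continue
                    seen_offsets.add((name, offset))
                    mm = _mismatch_count(oriented, index.records[name], offset, max_mismatch)
                    if mm <= max_mismatch:
                        hits[(read.read_id, name, offset, strand)] = mm
    return [
        AlignmentHit(read_id=r, target=t, offset=o, strand=s, mismatches=m)
        for (r, t, o, s), m in sorted(hits.items())
    ]


def read_fastq(path) -> list[Read]:
    """Minimal FASTQ reader returning uppercase sequences."""
    from Bio import SeqIO

    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
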