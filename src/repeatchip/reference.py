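"""Repeat reference construction.

Builds the alignment targets used throughout the package: a canonical
(consensus) repeat library, the genomic repeat instances annotated by
RepeatMasker, and per-repeat-type "assemblies" in which the canonical
sequence and all flanked instance copies of a type are concatenated into a
single record, separated by spacer blocks of 'N' characters. Because bases
outside {A,C,G,T} mismatch everything during alignment, a spacer longer
than the read length guarantees that no admissible alignment can bridge two
neighbouring segments.

Coordinates are 0-based half-open internally; RepeatMasker input is 1-based
inclusive and converted on parse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

DEFAULT_SPACER_LEN = 80
DEFAULT_FLANK_BP = 13  # half of a 26-bp read; configurable as floor(read_length / 2)


@dataclass(frozen=True)
class CanonicalRepeat:
    """One prototypical (consensus) repeat sequence from a Repbase-style library."""

    name: str
    family: str
    repeat_class: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("repeat name must be non-empty")
        if not self.sequence:
            raise ValueError(f"repeat {self.name!r}: sequence must be non-empty")


@dataclass(frozen=True)
class RepeatInstance:
    """A genomic copy of a repeat type (0-based half-open interval)."""

    type_name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    family: str = "Unknown"
    repeat_class: str = "Unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"instance {self.type_name} {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.type_name}:{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class Segment:
    """Maps an offset interval of an assembly record back to its source."""

    start: int
    end: int
    kind: str  # canonical | instance | spacer
    chrom: str = "."
    g_start: int = -1  # genomic span including flanks (instance segments only)
    g_end: int = -1
    strand: str = "."
    instance: RepeatInstance | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def leaf_id(self) -> str:
        if self.kind == "canonical":
            return "canonical"
        assert self.instance is not None
        return self.instance.key


@dataclass
class RepeatAssembly:
    """Concatenated per-type alignment targets with interval bookkeeping.

    ``records`` maps repeat-type name to its record sequence; ``segment_map``
    maps the same name to the ordered list of segments making up the record.
    """

    records: dict[str, str]
    segment_map: dict[str, list[Segment]]
    spacer_len: int = DEFAULT_SPACER_LEN
    flank_bp: int = DEFAULT_FLANK_BP
    mode: str = "combined"

    def segment_at(self, type_name: str, offset: int, length: int = 1) -> Segment | None:
        """Return the non-spacer segment fully containing [offset, offset+length)."""
        for seg in self.segment_map[type_name]:
            if seg.kind == "spacer":
                continue
            if seg.start <= offset and offset + length <= seg.end:
                return seg
        return None

    def instance_segments(self, type_name: str) -> list[Segment]:
        return [s for s in self.segment_map[type_name] if s.kind == "instance"]

    def instance_intervals(self) -> dict[str, list[tuple[str, int, int]]]:
        """Flanked genomic intervals of every annotated instance, per type."""
        out: dict[str, list[tuple[str, int, int]]] = {}
        for name, segs in self.segment_map.items():
            out[name] = [
                (s.chrom, s.g_start, s.g_end) for s in segs if s.kind == "instance"
            ]
        return out

    def nonspacer_length(self) -> int:
        return sum(
            seg.length
            for segs in self.segment_map.values()
            for seg in segs
            if seg.kind != "spacer"
        )


def _parse_header(header: str) -> tuple[str, str, str]:
    """Split a Repbase-style 'NAME#CLASS/FAMILY' FASTA id."""
    name, _, anno = header.partition("#")
    repeat_class, family = "Unknown", "Unknown"
    if anno:
        cls, _, fam = anno.partition("/")
        repeat_class = cls or "Unknown"
        family = fam or "Unknown"
    return name, repeat_class, family


def read_canonical_fasta(path: str | Path) -> list[CanonicalRepeat]:
    """Read a canonical repeat library (headers ``NAME#CLASS/FAMILY``)."""
    repeats: list[CanonicalRepeat] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name, repeat_class, family = _parse_header(rec.id)
        if name in seen:
            raise ValueError(f"duplicate repeat name in library: {name!r}")
        seen.add(name)
        repeats.append(
            CanonicalRepeat(
                name=name,
                family=family,
                repeat_class=repeat_class,
                sequence=str(rec.seq).upper(),
            )
        )
    if not repeats:
        raise ValueError(f"no FASTA entries found in {path}")
    return repeats


def read_repeatmasker_out(path: str | Path) -> list[RepeatInstance]:
    """Parse a RepeatMasker ``.out`` file into 0-based half-open instances.

    The standard layout has two header lines plus a blank line; annotation
    rows are whitespace-delimited with 1-based inclusive genomic coordinates
    and strand '+' or 'C' (complement).
    """
    instances: list[RepeatInstance] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            # header lines start with the "SW"/"score" banner or ruler tokens
            if fields[0] in {"SW", "score", "bit"}:
                continue
            try:
                int(fields[0])
            except ValueError:
                continue  # e.g. continuation of the banner
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: too few columns: {line.rstrip()}")
            try:
                begin, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinates: {line.rstrip()}"
                ) from exc
            strand = "-" if fields[8] == "C" else "+"
            name = fields[9]
            repeat_class, family = "Unknown", "Unknown"
            if "#" in name:
                name, repeat_class, family = _parse_header(name)
            elif len(fields) > 10:
                cls, _, fam = fields[10].partition("/")
                repeat_class = cls or "Unknown"
                family = fam or "Unknown"
            instances.append(
                RepeatInstance(
                    type_name=name,
                    chrom=fields[4],
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    family=family,
                    repeat_class=repeat_class,
                )
            )
    return instances


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a chromosome -> uppercase sequence dict."""
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def extract_instance_sequences(
    genome: Mapping[str, str],
    instances: Sequence[RepeatInstance],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[tuple[RepeatInstance, str, int, int]]:
    """Slice flanked instance sequences out of the genome.

    Returns ``(instance, sequence, flanked_start, flanked_end)`` tuples; the
    flank is clipped at chromosome boundaries and minus-strand instances are
    kept in genomic (plus-strand) orientation — the aligner handles both
    strands of each read.
    """
    out = []
    for inst in instances:
        if inst.chrom not in genome:
            raise KeyError(f"unknown chromosome {inst.chrom!r} for {inst.key}")
        chrom_seq = genome[inst.chrom]
        if inst.end > len(chrom_seq):
            raise ValueError(f"instance {inst.key} extends past end of {inst.chrom}")
        lo = max(0, inst.start - flank_bp)
        hi = min(len(chrom_seq), inst.end + flank_bp)
        out.append((inst, chrom_seq[lo:hi], lo, hi))
    return out


def build_assembly(
    canonicals: Sequence[CanonicalRepeat],
    instance_seqs: Sequence[tuple[RepeatInstance, str, int, int]] = (),
    mode: str = "combined",
    spacer_len: int = DEFAULT_SPACER_LEN,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> RepeatAssembly:
    """Assemble per-type alignment records.

    mode='canonical': consensus sequences only; mode='instance': flanked
    genomic copies only; mode='combined': canonical followed by every
    instance, all joined by ``spacer_len`` 'N' characters. Instances whose
    type is not in the canonical library are skipped with a warning.
    """
    if mode not in {"canonical", "instance", "combined"}:
        raise ValueError(f"unknown assembly mode {mode!r}")
    known = {c.name for c in canonicals}
    by_type: dict[str, list[tuple[RepeatInstance, str, int, int]]] = {}
    for inst, seq, lo, hi in instance_seqs:
        if inst.type_name not in known:
            warnings.warn(
                f"instance {inst.key} has unknown repeat type; skipped", stacklevel=2
            )
            continue
        by_type.setdefault(inst.type_name, []).append((inst, seq, lo, hi))

    if mode == "instance" and not any(by_type.values()):
        raise ValueError("instance-only assembly requested but no type has instances")

    spacer = "N" * spacer_len
    records: dict[str, str] = {}
    segment_map: dict[str, list[Segment]] = {}
    for canon in canonicals:
        parts: list[str] = []
        segs: list[Segment] = []
        pos = 0

        def _push(seq: str, **kw) -> None:
            nonlocal pos
            parts.append(seq)
            segs.append(Segment(start=pos, end=pos + len(seq), **kw))
            pos += len(seq)

        if mode in {"canonical", "combined"}:
            _push(canon.sequence, kind="canonical")
        if mode in {"instance", "combined"}:
            for inst, seq, lo, hi in by_type.get(canon.name, []):
                if segs:
                    _push(spacer, kind="spacer")
                _push(
                    seq,
                    kind="instance",
                    chrom=inst.chrom,
                    g_start=lo,
                    g_end=hi,
                    strand=inst.strand,
                    instance=inst,
                )
        if mode == "instance" and not segs:
            continue  # type without instances has no record in instance mode
        records[canon.name] = "".join(parts)
        segment_map[canon.name] = segs
    return RepeatAssembly(
        records=records,
        segment_map=segment_map,
        spacer_len=spacer_len,
        flank_bp=flank_bp,
        mode=mode,
    )


def write_assembly_fasta(assembly: RepeatAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_segment_map(assembly: RepeatAssembly, path: str | Path) -> None:
    """TSV: record, offset_start, offset_end, source_kind, chrom, start, end, strand."""
    with open(path, "w") as fh:
        fh.write("record\toffset_start\toffset_end\tsource_kind\tchrom\tstart\tend\tstrand\n")
        for name, segs in assembly.segment_map.items():
            for s in segs:
                fh.write(
                    f"{name}\t{s.start}\t{s.end}\t{s.kind}\t{s.chrom}\t"
                    f"{s.g_start}\t{s.g_end}\t{s.strand}\n"
                )


def read_segment_map(path: str | Path) -> dict[str, list[Segment]]:
    segment_map: dict[str, list[Segment]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record\t"):
            raise ValueError(f"{path}: not a segment-map TSV")
        for line in fh:
            rec, o0, o1, kind, chrom, g0, g1, strand = line.rstrip("\n").split("\t")
            inst = None
            if kind == "instance":
                core0, core1 = int(g0), int(g1)
                inst = RepeatInstance(
                    type_name=rec, chrom=chrom, start=core0, end=core1, strand=strand
                )
            segment_map.setdefault(rec, []).append(
                Segment(
                    start=int(o0),
                    end=int(o1),
                    kind=kind,
                    chrom=chrom,
                    g_start=int(g0),
                    g_end=int(g1),
                    strand=strand,
                    instance=inst,
                )
            )
    return segment_map


def write_instance_bed(instances: Iterable[RepeatInstance], path: str | Path) -> None:
    """0-based half-open BED of annotated instances."""
    with open(path, "w") as fh:
        for inst in instances:
            fh.write(
                f"{inst.chrom}\t{inst.start}\t{inst.end}\t{inst.type_name}\t0\t{inst.strand}\n"
            )
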