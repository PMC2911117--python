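"""Synthetic data generation with known truth.

Two generators are provided. ``sample_assembly_reads`` re-samples a repeat
assembly under a positional sequencing-error model (rates rising linearly
across the read, matching the Illumina-style profile of 5.4e-3 at the
first to 1.0e-2 at the last position of a 32-bp read) and is the basis of
the mis-assignment (false positive / false negative) rate analysis;
``apply_snps`` plants independent substitutions at a fixed per-base rate
(default 8.3e-5). ``synth_dataset`` builds a complete desk-scale study:
a background genome with planted repeat families (canonical sequence,
diverged annotated instances, optional un-annotated partial copies) plus
ChIP and input read sets in which each type's instances are over-sampled
by a known fold enrichment theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import Read, reverse_complement, write_fastq
from .assignment import TypeAssignment, STATUS_ASSIGNED
from .reference import (
    CanonicalRepeat,
    RepeatAssembly,
    RepeatInstance,
    write_instance_bed,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ErrorModel:
    """Positional substitution model for simulated sequencing errors."""

    per_position_rates: np.ndarray  # shape (L,)
    substitution_matrix: np.ndarray  # 4x4, rows sum to 1, zero diagonal

    def __post_init__(self) -> None:
        rates = np.asarray(self.per_position_rates, dtype=float)
        if ((rates < 0) | (rates > 1)).any():
            raise ValueError("per-position rates must lie in [0, 1]")
        m = np.asarray(self.substitution_matrix, dtype=float)
        if m.shape != (4, 4) or not np.allclose(m.sum(axis=1), 1.0) or np.diag(m).any():
            raise ValueError("substitution matrix must be 4x4 row-stochastic, zero diagonal")

    @property
    def read_length(self) -> int:
        return len(self.per_position_rates)


def make_error_model(
    first: float = 5.4e-3,
    last: float = 1.0e-2,
    L: int = 32,
    matrix: np.ndarray | None = None,
) -> ErrorModel:
    """Linear interpolation of per-position error rates from first to last."""
    if L < 2:
        raise ValueError("read length must be at least 2")
    if not 0 <= first <= 1 and 0 <= last <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rates = np.linspace(first, last, L)
    if matrix is None:
        matrix = (np.ones((4, 4)) - np.eye(4)) / 3.0
    return ErrorModel(per_position_rates=rates, substitution_matrix=np.asarray(matrix))


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        out[arr == b] = i
    return out


def _decode(codes: np.ndarray) -> str:
    lut = np.array(list("ACGTN"))
    return "".join(lut[codes])


def apply_read_errors(
    sequences: Sequence[str], model: ErrorModel, rng: np.random.Generator
) -> list[str]:
    """Substitute bases position-wise according to the error model."""
    if not sequences:
        return []
    codes = np.stack([_encode(s) for s in sequences])
    n, L = codes.shape
    rates = model.per_position_rates[:L]
    hit = (rng.random(codes.shape) < rates) & (codes < 4)
    out = codes.copy()
    if hit.any():
        idx = np.nonzero(hit)
        originals = codes[idx]
        u = rng.random(originals.shape[0])
        cum = np.cumsum(model.substitution_matrix[originals], axis=1)
        new = (u[:, None] < cum).argmax(axis=1)
        out[idx] = new
    return [_decode(row) for row in out]


@dataclass(frozen=True)
class SimulatedRead:
    read: Read
    source_record: str  # repeat type (assembly sampling) or chromosome
    offset: int
    strand: str
    segment_leaf: str | None = None  # instance key or 'canonical'


def sample_assembly_reads(
    assembly: RepeatAssembly,
    coverage: float = 100.0,
    model: ErrorModel | None = None,
    read_length: int = 32,
    seed: int | np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Sample reads uniformly from the non-spacer portion of an assembly.

    Read count is coverage * (non-spacer length) / read length; each read
    starts inside a single segment (so its true source is unambiguous),
    takes either strand with equal probability, and is passed through the
    error model when one is given.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = read_length
    positions: list[tuple[str, int, str]] = []  # (record, offset, leaf)
    for name in sorted(assembly.records):
        for seg in assembly.segment_map[name]:
            if seg.kind == "spacer" or seg.length < L:
                continue
            for off in range(seg.start, seg.end - L + 1):
                positions.append((name, off, seg.leaf_id))
    if not positions:
        raise ValueError(f"no segment is long enough for {L}-bp reads")
    n_reads = int(round(coverage * assembly.nonspacer_length() / L))
    picks = rng.integers(0, len(positions), size=n_reads)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    raw, meta = [], []
    for i, (pick, strand) in enumerate(zip(picks, strands)):
        rec, off, leaf = positions[pick]
        seq = assembly.records[rec][off : off + L]
        if strand == "-":
            seq = reverse_complement(seq)
        raw.append(seq)
        meta.append((rec, off, strand, leaf))
    if model is not None:
        raw = apply_read_errors(raw, model, rng)
    return [
        SimulatedRead(Read(f"sim{i}", seq), rec, off, strand, leaf)
        for i, (seq, (rec, off, strand, leaf)) in enumerate(zip(raw, meta))
    ]


def apply_snps(
    sequences: Mapping[str, str],
    rate: float = 8.3e-5,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Plant i.i.d. per-base substitutions; returns mutated copies + positions."""
    if not 0 <= rate < 1:
        raise ValueError("SNP rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mutated, positions = {}, {}
    for name in sorted(sequences):
        codes = _encode(sequences[name])
        hit = (rng.random(codes.shape) < rate) & (codes < 4)
        idx = np.nonzero(hit)[0]
        out = codes.copy()
        if idx.size:
            shifts = rng.integers(1, 4, size=idx.size)
            out[idx] = (codes[idx] + shifts) % 4
        mutated[name] = _decode(out)
        positions[name] = idx.tolist()
    return mutated, positions


def misassignment_rates(
    truth: Mapping[str, str], assignments: Iterable[TypeAssignment]
) -> pd.DataFrame:
    """Per-type false-positive and false-negative assignment rates.

    FP(T) = reads assigned to T whose true source is not T, over all reads
    assigned to T; FN(T) = reads truly from T not assigned to T, over all
    reads truly from T. Denominators are reported alongside the rates.
    """
    if not truth:
        raise ValueError("empty truth set")
    assigned: dict[str, str] = {
        a.read_id: a.type_name for a in assignments if a.status == STATUS_ASSIGNED
    }
    types = sorted(set(truth.values()) | set(assigned.values()))
    rows = []
    for t in types:
        n_assigned = sum(1 for v in assigned.values() if v == t)
        fp = sum(1 for r, v in assigned.items() if v == t and truth.get(r) != t)
        n_true = sum(1 for v in truth.values() if v == t)
        fn = sum(1 for r, v in truth.items() if v == t and assigned.get(r) != t)
        rows.append(
            (
                t,
                fp / n_assigned if n_assigned else 0.0,
                n_assigned,
                fn / n_true if n_true else 0.0,
                n_true,
            )
        )
    return pd.DataFrame(
        rows, columns=["type", "fp_rate", "n_assigned", "fn_rate", "n_true"]
    ).set_index("type")


@dataclass(frozen=True)
class FamilySpec:
    """One planted repeat family."""

    name: str
    canonical_length: int = 300
    n_instances: int = 4
    divergence: float = 0.05  # per-base substitution rate between instances
    unannotated_fraction: float = 0.0  # extra partial copies omitted from the .out
    theta: float = 1.0  # true ChIP fold enrichment
    family: str = "Unknown"
    repeat_class: str = "Unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must lie in [0, 0.3]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")


@dataclass(frozen=True)
class SyntheticRepeatSpec:
    """Desk-scale stand-in for a genome + Repbase library + ChIP experiment."""

    families: tuple[FamilySpec, ...]
    background_length: int = 20_000
    read_length: int = 32
    n_chip: int = 5_000
    n_input: int = 5_000
    seed: int = 0
    error_model: ErrorModel | None = None
    snp_rate: float = 0.0
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one family required")
        longest = max(f.canonical_length for f in self.families)
        if longest > self.background_length:
            raise ValueError("canonical repeat longer than the background genome")
        if self.read_length < 2:
            raise ValueError("read length must be at least 2")


@dataclass
class SyntheticDataset:
    spec: SyntheticRepeatSpec
    genome: dict[str, str]
    canonicals: list[CanonicalRepeat]
    instances: list[RepeatInstance]  # annotated (in the .out)
    unannotated: list[RepeatInstance]  # planted but hidden from the .out
    chip_reads: list[Read]
    input_reads: list[Read]
    chip_truth: pd.DataFrame  # read_id, source (type or 'background')
    input_truth: pd.DataFrame
    theta: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(outdir / "library.fa", "w") as fh:
            for c in self.canonicals:
                fh.write(f">{c.name}#{c.repeat_class}/{c.family}\n{c.sequence}\n")
        write_repeatmasker_out(self.instances, outdir / "repeats.out")
        write_instance_bed(self.instances, outdir / "repeats.bed")
        write_fastq(self.chip_reads, outdir / "chip.fastq")
        write_fastq(self.input_reads, outdir / "input.fastq")
        self.chip_truth.to_csv(outdir / "chip_truth.tsv", sep="\t", index=False)
        self.input_truth.to_csv(outdir / "input_truth.tsv", sep="\t", index=False)
        pd.Series(self.theta, name="theta").to_csv(
            outdir / "theta_truth.tsv", sep="\t", index_label="type"
        )
        with open(outdir / "spec.txt", "w") as fh:
            fh.write(repr(self.spec) + "\n")


def write_repeatmasker_out(instances: Sequence[RepeatInstance], path: str | Path) -> None:
    """Write a RepeatMasker-style ``.out`` (1-based inclusive, strand +/C)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching"
            "       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    repeat"
            "         class/family         begin  end (left)   ID\n\n"
        )
        for i, inst in enumerate(instances, start=1):
            strand = "C" if inst.strand == "-" else "+"
            fh.write(
                f"  500   5.0  0.0  0.0  {inst.chrom} {inst.start + 1} {inst.end} "
                f"(0) {strand} {inst.type_name} {inst.repeat_class}/{inst.family} "
                f"1 {inst.end - inst.start} (0) {i}\n"
            )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _decode(rng.integers(0, 4, size=length).astype(np.int8))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = _encode(seq)
    hit = (rng.random(codes.shape) < rate) & (codes < 4)
    idx = np.nonzero(hit)[0]
    if idx.size:
        codes = codes.copy()
        codes[idx] = (codes[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return _decode(codes)


def synth_dataset(spec: SyntheticRepeatSpec) -> SyntheticDataset:
    """Generate the full synthetic study described by ``spec``.

    The genome is a uniform-random background into which diverged copies of
    each family's canonical sequence are planted, evenly spread; a fraction
    of additional partial copies can be planted without appearing in the
    annotation, to exercise the masking procedure. Input reads sample the
    genome uniformly; ChIP reads over-sample each type's planted copies
    (annotated and not) by the family's true fold enrichment theta, with the
    background weight lowered correspondingly (sequencing depth is fixed, so
    enrichment crowds out background reads) — theta is therefore exactly the
    ratio of ChIP to input read proportions that the estimator measures.
    """
    rng = np.random.default_rng(spec.seed)
    canonicals = [
        CanonicalRepeat(
            name=f.name,
            family=f.family,
            repeat_class=f.repeat_class,
            sequence=_random_seq(rng, f.canonical_length),
        )
        for f in spec.families
    ]

    # planted copies: (family, sequence, annotated?)
    copies: list[tuple[FamilySpec, str, bool]] = []
    for fam, canon in zip(spec.families, canonicals):
        for _ in range(fam.n_instances):
            copies.append((fam, _mutate(canon.sequence, fam.divergence, rng), True))
        n_extra = int(round(fam.unannotated_fraction * fam.n_instances))
        for _ in range(n_extra):
            frac = rng.uniform(0.3, 0.7)
            length = max(spec.read_length + 4, int(frac * fam.canonical_length))
            start = rng.integers(0, fam.canonical_length - length + 1)
            fragment = canon.sequence[start : start + length]
            copies.append((fam, _mutate(fragment, fam.divergence, rng), False))

    order = rng.permutation(len(copies))
    copies = [copies[i] for i in order]
    n_gaps = len(copies) + 1
    gap = spec.background_length // n_gaps
    if gap < spec.read_length:
        raise ValueError("background too short for the planted copies")

    parts, pos = [], 0
    instances, unannotated = [], []
    placed: list[tuple[FamilySpec, int, int]] = []
    for fam, seq, annotated in copies:
        bg = _random_seq(rng, gap)
        parts.append(bg)
        pos += len(bg)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = seq if strand == "+" else reverse_complement(seq)
        inst = RepeatInstance(
            type_name=fam.name,
            chrom=spec.chrom_name,
            start=pos,
            end=pos + len(planted),
            strand=strand,
            family=fam.family,
            repeat_class=fam.repeat_class,
        )
        (instances if annotated else unannotated).append(inst)
        placed.append((fam, pos, pos + len(planted)))
        parts.append(planted)
        pos += len(planted)
    parts.append(_random_seq(rng, spec.background_length - gap * (n_gaps - 1) + gap))
    genome_seq = "".join(parts)
    genome = {spec.chrom_name: genome_seq}
    if spec.snp_rate > 0:
        genome, _ = apply_snps(genome, spec.snp_rate, rng)
        genome_seq = genome[spec.chrom_name]

    L = spec.read_length
    G = len(genome_seq)

    # ChIP enrichment crowds out background reads at fixed sequencing depth:
    # the background weight is reduced so that the total sampling mass equals
    # the input's, making each planted theta equal the measurable ratio of
    # ChIP to input read proportions (the estimand of the enrichment model).
    repeat_mass = sum(hi - lo for _, lo, hi in placed)
    enriched_mass = sum(f.theta * (hi - lo) for f, lo, hi in placed)
    bg_mass = G - repeat_mass
    bg_weight = 1.0 - (enriched_mass - repeat_mass) / bg_mass
    if bg_weight <= 0:
        raise ValueError(
            "planted enrichment exceeds the background read mass; enlarge the "
            "background or lower theta"
        )

    def _sample_reads(n: int, weighted: bool, prefix: str) -> tuple[list[Read], pd.DataFrame]:
        # piecewise-constant start-position weights over placed intervals
        bg = bg_weight if weighted else 1.0
        bounds, weights, labels = [0], [], []
        cursor = 0
        for fam, lo, hi in sorted(placed, key=lambda x: x[1]):
            if lo > cursor:
                weights.append(bg)
                labels.append("background")
                bounds.append(lo)
            weights.append(fam.theta if weighted else 1.0)
            labels.append(fam.name)
            bounds.append(hi)
            cursor = hi
        if cursor < G - L + 1:
            weights.append(bg)
            labels.append("background")
            bounds.append(G - L + 1)
        widths = np.diff(bounds).astype(float)
        probs = widths * np.asarray(weights)
        probs /= probs.sum()
        segs = rng.choice(len(widths), size=n, p=probs)
        starts = (np.asarray(bounds)[segs] + (rng.random(n) * widths[segs])).astype(int)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        seqs = []
        for st, strand in zip(starts, strands):
            s = genome_seq[st : st + L]
            seqs.append(s if strand == "+" else reverse_complement(s))
        if spec.error_model is not None:
            seqs = apply_read_errors(seqs, spec.error_model, rng)
        reads = [Read(f"{prefix}{i}", s) for i, s in enumerate(seqs)]
        truth = pd.DataFrame(
            {
                "read_id": [r.read_id for r in reads],
                "source": [labels[k] for k in segs],
                "start": starts,
                "strand": strands,
            }
        )
        return reads, truth

    chip_reads, chip_truth = _sample_reads(spec.n_chip, True, "chip")
    input_reads, input_truth = _sample_reads(spec.n_input, False, "inp")
    return SyntheticDataset(
        spec=spec,
        genome=genome,
        canonicals=canonicals,
        instances=instances,
        unannotated=unannotated,
        chip_reads=chip_reads,
        input_reads=input_reads,
        chip_truth=chip_truth,
        input_truth=input_truth,
        theta={f.name: f.theta for f in spec.families},
    )
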