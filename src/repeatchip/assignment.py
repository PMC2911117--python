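"""Assignment of aligned reads to repeat types.

A read is associated with a repeat type when (1) all of its equal-best
alignments fall within the canonical sequence or annotated instances of
that single type — multiple positions within the type are allowed — and
(2) no equal-or-better alignment exists in any other annotated type.
An optional masking step adds condition (3): no equal-or-better alignment
anywhere in the genome assembly outside the flanked annotated instances of
the assigned type.

Quality strata are defined solely by mismatch count (0 beats 1); ungapped
equal-length alignments admit no other score.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .alignment import AlignmentHit, Read, align_all_hits
from .reference import RepeatAssembly

STATUS_ASSIGNED = "assigned"
STATUS_AMBIGUOUS = "cross_type_ambiguous"
STATUS_MASKED = "masked"
STATUS_UNMAPPED = "unmapped"


@dataclass(frozen=True)
class TypeAssignment:
    read_id: str
    status: str
    type_name: str | None  # set iff status == assigned or masked (pre-mask type)
    hit_types: frozenset[str]  # types with a best-stratum hit
    best_mismatches: int | None  # None iff unmapped


def dedup_reads(reads: Iterable[Read]) -> list[Read]:
    """Collapse reads with identical sequences, keeping the first id.

    Off by default throughout the package (the underlying protocol does not
    deduplicate); exposed for PCR-duplicate-heavy libraries.
    """
    seen: set[str] = set()
    out: list[Read] = []
    for r in reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    return out


def group_hits_by_read(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    grouped: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        grouped[h.read_id].append(h)
    return dict(grouped)


def best_stratum_hits(read_hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    best = min(h.mismatches for h in read_hits)
    return [h for h in read_hits if h.mismatches == best]


def assign_to_types(
    reads: Iterable[Read], hits: Iterable[AlignmentHit]
) -> list[TypeAssignment]:
    """Assign each read to a repeat type under conditions 1 and 2."""
    grouped = group_hits_by_read(hits)
    out: list[TypeAssignment] = []
    for read in reads:
        read_hits = grouped.get(read.read_id)
        if not read_hits:
            out.append(
                TypeAssignment(read.read_id, STATUS_UNMAPPED, None, frozenset(), None)
            )
            continue
        best = best_stratum_hits(read_hits)
        types = frozenset(h.target for h in best)
        mm = best[0].mismatches
        if len(types) == 1:
            out.append(
                TypeAssignment(read.read_id, STATUS_ASSIGNED, next(iter(types)), types, mm)
            )
        else:
            out.append(TypeAssignment(read.read_id, STATUS_AMBIGUOUS, None, types, mm))
    return out


def apply_genome_mask(
    assignments: Sequence[TypeAssignment],
    genome_hits: Iterable[AlignmentHit],
    instance_intervals: Mapping[str, Sequence[tuple[str, int, int]]],
    read_lengths: Mapping[str, int],
) -> list[TypeAssignment]:
    """Apply condition 3: mask reads alignable outside their type's instances.

    ``instance_intervals`` maps each type to the flanked genomic intervals of
    its annotated instances (chrom, start, end; 0-based half-open). An
    assigned read becomes masked iff it has a genome hit at no more
    mismatches than its best repeat-assembly hit whose footprint is not
    fully contained in any flanked instance interval of its assigned type.
    """
    genome_by_read = group_hits_by_read(genome_hits)
    out: list[TypeAssignment] = []
    for a in assignments:
        if a.status != STATUS_ASSIGNED:
            out.append(a)
            continue
        intervals = instance_intervals.get(a.type_name, ())
        length = read_lengths[a.read_id]
        masked = False
        for h in genome_by_read.get(a.read_id, ()):
            if h.mismatches > a.best_mismatches:
                continue  # strictly worse outside hit does not trigger masking
            lo, hi = h.offset, h.offset + length
            contained = any(
                chrom == h.target and start <= lo and hi <= end
                for chrom, start, end in intervals
            )
            if not contained:
                masked = True
                break
        if masked:
            out.append(
                TypeAssignment(a.read_id, STATUS_MASKED, a.type_name, a.hit_types, a.best_mismatches)
            )
        else:
            out.append(a)
    return out


def type_counts(assignments: Iterable[TypeAssignment]) -> dict[str, int]:
    """Per-type assigned-read counts (the s or c of the enrichment model)."""
    counts: dict[str, int] = defaultdict(int)
    for a in assignments:
        if a.status == STATUS_ASSIGNED:
            counts[a.type_name] += 1
    return dict(counts)


def instance_counts(
    assignments: Iterable[TypeAssignment],
    hits: Iterable[AlignmentHit],
    assembly: RepeatAssembly,
    read_lengths: Mapping[str, int],
) -> dict[str, float]:
    """Fractional per-instance-segment counts for instance-level analyses.

    A read assigned to a type and hitting several of its instance segments
    at the best stratum contributes 1/(number of segments hit) to each, so
    segment counts sum to the type's integer assigned count (up to reads
    hitting only the canonical segment).
    """
    grouped = group_hits_by_read(hits)
    counts: dict[str, float] = defaultdict(float)
    for a in assignments:
        if a.status != STATUS_ASSIGNED:
            continue
        segs = set()
        for h in best_stratum_hits(grouped[a.read_id]):
            if h.target != a.type_name:
                continue
            seg = assembly.segment_at(h.target, h.offset, read_lengths[a.read_id])
            if seg is not None and seg.kind == "instance":
                segs.add(seg.leaf_id)
        for leaf in segs:
            counts[leaf] += 1.0 / len(segs)
    return dict(counts)


def effective_dataset_size(
    reads: Sequence[Read],
    genome: Mapping[str, str],
    canonical_assembly: RepeatAssembly | Mapping[str, str],
    max_mismatch: int = 1,
) -> int:
    """Number of reads mapping at least once to the genome or the canonical
    repeat sequences; this is the S (or C) of the enrichment equations."""
    mapped: set[str] = set()
    for h in align_all_hits(reads, genome, max_mismatch=max_mismatch):
        mapped.add(h.read_id)
    for h in align_all_hits(reads, canonical_assembly, max_mismatch=max_mismatch):
        mapped.add(h.read_id)
    return len(mapped)


def read_sam_hits(path: str | Path, max_mismatch: int = 1) -> list[AlignmentHit]:
    """Ingest all-hit alignments from SAM/BAM produced by an external aligner.

    Records must carry the NM tag; records with indels/clipping in the CIGAR
    or with NM above ``max_mismatch`` are discarded.
    """
    import pysam

    hits: list[AlignmentHit] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NM"):
                raise ValueError(
                    f"{path}: alignment for {rec.query_name} lacks the NM tag; "
                    "re-align emitting NM (e.g. bwa samse -n)"
                )
            if any(op != 0 for op, _ in rec.cigartuples or ()):
                continue  # gapped/clipped alignment: outside the ungapped model
            nm = rec.get_tag("NM")
            if nm > max_mismatch:
                continue
            hits.append(
                AlignmentHit(
                    read_id=rec.query_name,
                    target=rec.reference_name,
                    offset=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(nm),
                )
            )
    return hits


def write_counts_tsv(
    counts: Mapping[str, int], assignments: Sequence[TypeAssignment], path: str | Path
) -> None:
    """TSV: type, n_assigned, n_ambiguous_involving_type."""
    ambiguous: dict[str, int] = defaultdict(int)
    for a in assignments:
        if a.status == STATUS_AMBIGUOUS:
            for t in a.hit_types:
                ambiguous[t] += 1
    names = sorted(set(counts) | set(ambiguous))
    with open(path, "w") as fh:
        fh.write("type\tn_assigned\tn_ambiguous_involving_type\n")
        for name in names:
            fh.write(f"{name}\t{counts.get(name, 0)}\t{ambiguous.get(name, 0)}\n")


def read_counts_tsv(path: str | Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            name, n, _ = line.rstrip("\n").split("\t")
            counts[name] = int(n)
    return counts


def write_assignment_summary(
    assignments: Sequence[TypeAssignment], path: str | Path, dataset_size: int | None = None
) -> None:
    totals: dict[str, int] = defaultdict(int)
    for a in assignments:
        totals[a.status] += 1
    summary = {"n_reads": len(assignments), "by_status": dict(totals)}
    if dataset_size is not None:
        summary["effective_dataset_size"] = dataset_size
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")
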