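"""End-to-end orchestration: reference build, assignment, enrichment,
clustering and tree construction, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import Read, align_all_hits, read_fastq
from .assignment import (
    apply_genome_mask,
    assign_to_types,
    effective_dataset_size,
    type_counts,
    write_assignment_summary,
    write_counts_tsv,
)
from .phylogeny import (
    annotate_tree,
    build_tree,
    leaf_read_sets_from_hits,
    write_newick,
)
from .reference import (
    build_assembly,
    extract_instance_sequences,
    read_canonical_fasta,
    read_genome_fasta,
    read_repeatmasker_out,
    write_assembly_fasta,
    write_instance_bed,
    write_segment_map,
)
from .relnorm import (
    build_proportions,
    fit_background_table,
    relative_zscores,
    write_background_tsv,
    write_zscores_tsv,
)
from .stats import cluster_types, estimate_table

log = logging.getLogger("repeatchip")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    genome: str
    library: str
    rmout: str
    chip: dict[str, str]  # mark name -> FASTQ path
    control: str | None = None
    out_dir: str = "repeatchip_run"
    max_mismatch: int = 1
    flank_bp: int = 13
    spacer_len: int = 80
    alpha: float = 0.05
    n_omit: int = 5
    n_resample: int = 100
    seed: int = 0
    mask: bool = False
    mode: str = "combined"

    def validate(self) -> None:
        for p in [self.genome, self.library, self.rmout, *self.chip.values()]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.control is not None and not Path(self.control).exists():
            raise FileNotFoundError(self.control)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_mismatch < 0 or self.flank_bp < 0 or self.spacer_len < 0:
            raise ValueError("parameters must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key=value config file; chip marks as ``chip.MARK = path``."""
        raw: dict[str, str] = {}
        chip: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key.startswith("chip."):
                    chip[key[5:]] = value
                else:
                    raw[key] = value
        kwargs: dict = {"chip": chip}
        for f in ("genome", "library", "rmout", "control", "out_dir", "mode"):
            if f in raw:
                kwargs[f] = raw[f]
        for f in ("max_mismatch", "flank_bp", "spacer_len", "n_omit", "n_resample", "seed"):
            if f in raw:
                kwargs[f] = int(raw[f])
        if "alpha" in raw:
            kwargs["alpha"] = float(raw["alpha"])
        if "mask" in raw:
            kwargs["mask"] = raw["mask"].lower() in {"1", "true", "yes"}
        kwargs.update(overrides)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Stages: reference build -> per-mark assignment (+ optional masking) ->
    enrichment against the control, or input-free relative normalization
    when no control is given -> clustering -> type-level enrichment tree
    for the first mark. A manifest records parameters and output checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "build-reference"
    try:
        genome = read_genome_fasta(config.genome)
        canonicals = read_canonical_fasta(config.library)
        instances = read_repeatmasker_out(config.rmout)
        inst_seqs = extract_instance_sequences(genome, instances, config.flank_bp)
        assembly = build_assembly(
            canonicals, inst_seqs, config.mode, config.spacer_len, config.flank_bp
        )
        write_assembly_fasta(assembly, out / "reference.fa")
        write_segment_map(assembly, out / "reference.segments.tsv")
        write_instance_bed(instances, out / "instances.bed")
        canonical_only = build_assembly(canonicals, (), "canonical")

        stage = "assign"
        datasets: dict[str, Sequence[Read]] = {
            m: read_fastq(p) for m, p in config.chip.items()
        }
        if config.control:
            datasets["__control__"] = read_fastq(config.control)
        counts: dict[str, dict[str, int]] = {}
        sizes: dict[str, int] = {}
        chip_hits_first = None
        control_hits = None
        for name, reads in datasets.items():
            hits = align_all_hits(reads, assembly, config.max_mismatch)
            assignments = assign_to_types(reads, hits)
            if config.mask:
                genome_hits = align_all_hits(reads, genome, config.max_mismatch)
                assignments = apply_genome_mask(
                    assignments,
                    genome_hits,
                    assembly.instance_intervals(),
                    {r.read_id: len(r.sequence) for r in reads},
                )
            size = effective_dataset_size(reads, genome, canonical_only, config.max_mismatch)
            counts[name] = type_counts(assignments)
            sizes[name] = size
            label = "control" if name == "__control__" else name
            write_counts_tsv(counts[name], assignments, out / f"{label}_counts.tsv")
            write_assignment_summary(assignments, out / f"{label}_summary.json", size)
            if name == "__control__":
                control_hits = hits
            elif chip_hits_first is None:
                chip_hits_first = (name, hits)

        marks = list(config.chip)
        if config.control:
            stage = "enrich"
            mle_cols, sig_cols = {}, {}
            for m in marks:
                est = estimate_table(
                    counts[m], counts["__control__"], sizes[m], sizes["__control__"], config.alpha
                )
                est.to_csv(out / f"{m}_enrichment.tsv", sep="\t")
                mle_cols[m], sig_cols[m] = est["mle"], est["significant"]
            mle = pd.DataFrame(mle_cols).fillna(1.0)
            sig = pd.DataFrame(sig_cols).fillna(False)
        else:
            stage = "normalize-relative"
            table = build_proportions(counts, {m: float(sizes[m]) for m in marks})
            model = fit_background_table(
                table, config.n_omit, config.n_resample, config.seed
            )
            z = relative_zscores(table, model)
            write_zscores_tsv(z, out / "relative_zscores.tsv")
            write_background_tsv(model, out / "background_model.tsv")
            mle = z  # cluster on Z in the input-free route
            sig = z > 3.1

        stage = "cluster"
        if len(mle) >= 2:
            order, linkage = cluster_types(mle, sig)
            mle.loc[order].to_csv(out / "clustered_matrix.tsv", sep="\t")
            np.savetxt(out / "linkage.tsv", linkage, delimiter="\t")
            export_heatmap_data(mle, sig, order, out / "heatmap.tsv")

        stage = "tree"
        if chip_hits_first is not None and len(assembly.records) >= 2:
            name, hits = chip_hits_first
            chip_map = leaf_read_sets_from_hits(hits)
            tree = build_tree(sorted(assembly.records), chip_map)
            if config.control and control_hits is not None:
                control_map = leaf_read_sets_from_hits(control_hits)
                annotate_tree(tree, control_map, sizes[name], sizes["__control__"], config.alpha)
            write_newick(tree, out / f"{name}_tree.nwk", out / f"{name}_tree.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "tool": "repeatchip",
        "version": __version__,
        "parameters": asdict(config),
        "dataset_sizes": sizes,
        "inputs": {
            p: _sha256(Path(p))
            for p in [config.genome, config.library, config.rmout, *config.chip.values()]
            + ([config.control] if config.control else [])
        },
        "outputs": {
            f.name: _sha256(f)
            for f in sorted(out.iterdir())
            if f.is_file() and f.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


# three-state heatmap coding: significant enrichment in red, significant
# depletion in blue, everything else white
def heatmap_color(mle: float, significant: bool) -> str:
    if not significant:
        return "white"
    return "red" if mle > 1.0 else "blue"


def export_heatmap_data(
    mle: pd.DataFrame,
    significant: pd.DataFrame,
    ordering: Sequence[str],
    path: str | Path,
    image_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the clustered matrix with its three-state color coding."""
    rows = []
    for t in ordering:
        for m in mle.columns:
            val = float(mle.at[t, m])
            rows.append((t, m, val, heatmap_color(val, bool(significant.at[t, m]))))
    df = pd.DataFrame(rows, columns=["type", "mark", "value", "color"])
    df.to_csv(path, sep="\t", index=False)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import TwoSlopeNorm

        shown = mle.where(significant, 1.0).loc[list(ordering)]
        data = np.log2(shown.to_numpy(dtype=float))
        fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(mle.columns)), max(4, 0.12 * len(ordering))))
        lim = max(1.0, np.abs(data).max())
        ax.imshow(data, aspect="auto", cmap="bwr", norm=TwoSlopeNorm(0.0, -lim, lim))
        ax.set_xticks(range(len(mle.columns)), mle.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(ordering)), ordering, fontsize=5)
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return df
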