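"""Input-free relative normalization across many chromatin marks.

When no input/control library exists, the enrichment of a repeat type in
one mark is scored against that repeat's own distribution of scaled read
proportions across all measured marks, under the assumption that most
marks are not enriched at any given repeat. For each repeat type:

1. the percentage of the mark's reads assigned to the type (100 * s / S)
   is computed per mark;
2. the marks with the highest point percentages are set aside (default:
   the top 5 of 21) so outliers do not inflate the background;
3. each retained percentage is resampled from the Beta posterior of the
   proportion (Jeffreys prior: Beta(s + 1/2, S - s + 1/2), 100 draws per
   mark) and a Gaussian (mu, sigma) is fitted to the pooled draws;
4. every mark — including the set-aside candidates — receives
   Z = (percentage - mu) / sigma.

Only enrichment calls are meaningful: depletion cannot be established this
way, so negative Z-scores are reported but flagged non-callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_N_OMIT = 5
DEFAULT_N_RESAMPLE = 100
SIGMA_FLOOR_REL = 1e-12


@dataclass
class MarkProportionTable:
    """Repeat-type x mark table of assigned counts, sizes and percentages."""

    counts: pd.DataFrame  # types x marks, integer s
    sizes: pd.Series  # per-mark dataset size S

    def __post_init__(self) -> None:
        if (self.sizes <= 0).any():
            bad = list(self.sizes.index[self.sizes <= 0])
            raise ValueError(f"non-positive dataset size for marks: {bad}")
        if ((self.counts < 0) | self.counts.gt(self.sizes, axis=1)).any().any():
            raise ValueError("counts must satisfy 0 <= s <= S")

    @property
    def marks(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def ratios(self) -> pd.DataFrame:
        """Percentages on the 0-100 scale."""
        return 100.0 * self.counts.div(self.sizes, axis=1)


def build_proportions(
    counts_per_mark: Mapping[str, Mapping[str, int]],
    sizes_per_mark: Mapping[str, float],
) -> MarkProportionTable:
    """Assemble the proportion table from per-mark count dicts and sizes."""
    marks = sorted(counts_per_mark)
    types = sorted({t for c in counts_per_mark.values() for t in c})
    counts = pd.DataFrame(
        {m: [counts_per_mark[m].get(t, 0) for t in types] for m in marks}, index=types
    )
    sizes = pd.Series({m: float(sizes_per_mark[m]) for m in marks})
    return MarkProportionTable(counts=counts, sizes=sizes)


def beta_resample(
    s: float, S: float, n: int = DEFAULT_N_RESAMPLE, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """n posterior draws of the percentage, Beta(s + 1/2, S - s + 1/2) * 100."""
    if not 0 <= s <= S:
        raise ValueError("require 0 <= s <= S")
    rng = np.random.default_rng(rng)
    return 100.0 * rng.beta(s + 0.5, S - s + 0.5, size=n)


@dataclass
class BackgroundModel:
    """Per-repeat-type trimmed Gaussian background of mark percentages."""

    params: pd.DataFrame  # index: type; columns: mu, sigma
    trimmed: dict[str, list[str]]  # type -> marks omitted from the fit
    n_omit: int = DEFAULT_N_OMIT
    n_resample: int = DEFAULT_N_RESAMPLE
    seed: int | None = None


def fit_background(
    point_ratios: pd.Series,
    draws_by_mark: Mapping[str, np.ndarray],
    n_omit: int = DEFAULT_N_OMIT,
) -> tuple[float, float, list[str]]:
    """Fit (mu, sigma) for one repeat type from per-mark resampled draws.

    Marks are ranked by their point percentage; the ``n_omit`` highest are
    excluded and the Gaussian is fitted on the pooled draws of all
    remaining marks. Returns (mu, sigma, trimmed mark names).
    """
    if len(point_ratios) <= n_omit + 1:
        raise ValueError(
            f"need more than n_omit + 1 = {n_omit + 1} marks, got {len(point_ratios)}"
        )
    order = sorted(point_ratios.index, key=lambda m: (-point_ratios[m], m))
    trimmed = order[:n_omit]
    kept = [m for m in point_ratios.index if m not in trimmed]
    pool = np.concatenate([np.asarray(draws_by_mark[m], dtype=float) for m in kept])
    mu = float(pool.mean())
    sigma = float(pool.std(ddof=1)) if pool.size > 1 else 0.0
    sigma = max(sigma, SIGMA_FLOOR_REL * max(abs(mu), 1.0))
    return mu, sigma, trimmed


def fit_background_table(
    table: MarkProportionTable,
    n_omit: int = DEFAULT_N_OMIT,
    n_resample: int = DEFAULT_N_RESAMPLE,
    seed: int | None = None,
) -> BackgroundModel:
    """Fit the trimmed Gaussian background for every repeat type."""
    rng = np.random.default_rng(seed)
    ratios = table.ratios
    rows, trimmed_all = [], {}
    for t in table.counts.index:
        draws = {
            m: beta_resample(table.counts.at[t, m], table.sizes[m], n_resample, rng)
            for m in table.marks
        }
        mu, sigma, trimmed = fit_background(ratios.loc[t], draws, n_omit)
        rows.append((t, mu, sigma))
        trimmed_all[t] = trimmed
    params = pd.DataFrame(rows, columns=["type", "mu", "sigma"]).set_index("type")
    return BackgroundModel(
        params=params, trimmed=trimmed_all, n_omit=n_omit, n_resample=n_resample, seed=seed
    )


def relative_zscores(table: MarkProportionTable, model: BackgroundModel) -> pd.DataFrame:
    """Z-score matrix (types x marks), including the trimmed marks.

    Positive Z indicates candidate enrichment; negative Z cannot be read as
    significant depletion under this normalization.
    """
    missing = set(table.counts.index) - set(model.params.index)
    if missing:
        raise ValueError(f"background model missing types: {sorted(missing)}")
    ratios = table.ratios
    mu = model.params["mu"].reindex(ratios.index)
    sigma = model.params["sigma"].reindex(ratios.index)
    return ratios.sub(mu, axis=0).div(sigma, axis=0)


def write_zscores_tsv(z: pd.DataFrame, path) -> None:
    z.to_csv(path, sep="\t", index_label="type")


def write_background_tsv(model: BackgroundModel, path) -> None:
    df = model.params.copy()
    df["trimmed_marks"] = [",".join(model.trimmed[t]) for t in df.index]
    df.to_csv(path, sep="\t", index_label="type")
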