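"""Fold-enrichment estimation and related statistics.

The fold enrichment of a repeat set is modelled as the ratio of two Poisson
rates — ChIP reads s out of a dataset of size S versus control reads c out
of C — with a non-informative (half-count) Bayesian prior:

    theta_hat = C (s + 1/2) / (S (c + 1/2))

Equal-tailed interval bounds at level 1 - alpha come from the F
distribution: lambda(x) = theta_hat * F[x, 2(s + 1/2), 2(c + 1/2)], the
two bounds being lambda at the alpha/2 and 1 - alpha/2 quantiles (computed
with the lower-tail quantile and sorted, which is tail-convention
independent). Significance of enrichment or depletion is reported as a
signed Z-score capped at ±10, calibrated so that Z = 3.1 corresponds to a
one-sided p-value of 1e-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch

Z_CAP = 10.0


def enrichment_mle(s: float, c: float, S: float, C: float) -> float:
    """Maximum-likelihood fold enrichment with the half-count prior."""
    if S <= 0 or C <= 0:
        raise ValueError("dataset sizes S and C must be positive")
    return C * (s + 0.5) / (S * (c + 0.5))


def enrichment_ci(
    s: float, c: float, S: float, C: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Equal-tailed (1 - alpha) interval for the fold enrichment."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    theta = enrichment_mle(s, c, S, C)
    dfn, dfd = 2.0 * (np.asarray(s) + 0.5), 2.0 * (np.asarray(c) + 0.5)
    lam_a = theta * sps.f.ppf(alpha / 2.0, dfn, dfd)
    lam_b = theta * sps.f.ppf(1.0 - alpha / 2.0, dfn, dfd)
    lo, hi = np.minimum(lam_a, lam_b), np.maximum(lam_a, lam_b)
    if np.ndim(s) == 0:
        return float(lo), float(hi)
    return lo, hi


def enrichment_zscore(s: int, c: int, S: float, C: float, cap: float = Z_CAP) -> float:
    """Signed significance Z-score for enrichment (positive) or depletion.

    Based on the exact two-sided binomial test of s signal reads among the
    s + c reads of the set against the null proportion S / (S + C); the
    two-sided p is folded back to a one-sided normal quantile so that
    Z = 3.1 corresponds to a one-sided p of 1e-3.
    """
    theta = enrichment_mle(s, c, S, C)
    n = int(s) + int(c)
    if n == 0 or theta == 1.0:
        return 0.0
    p0 = S / (S + C)
    pval = sps.binomtest(int(s), n, p0).pvalue
    z = -sps.norm.ppf(min(pval, 1.0) / 2.0)
    if not np.isfinite(z):
        z = cap
    z = min(float(z), cap)
    return z if theta > 1.0 else -z


@dataclass(frozen=True)
class EnrichmentEstimate:
    """Fold-enrichment estimate for one repeat set under one mark."""

    set_id: str
    s: int
    c: int
    S: float
    C: float
    mle: float
    ci_low: float
    ci_high: float
    zscore: float
    significant: bool
    alpha: float = 0.05

    @classmethod
    def from_counts(
        cls,
        set_id: str,
        s: int,
        c: int,
        S: float,
        C: float,
        alpha: float = 0.05,
        cap: float = Z_CAP,
    ) -> "EnrichmentEstimate":
        mle = enrichment_mle(s, c, S, C)
        lo, hi = enrichment_ci(s, c, S, C, alpha)
        return cls(
            set_id=set_id,
            s=int(s),
            c=int(c),
            S=S,
            C=C,
            mle=mle,
            ci_low=lo,
            ci_high=hi,
            zscore=enrichment_zscore(s, c, S, C, cap),
            significant=bool(lo > 1.0 or hi < 1.0),
            alpha=alpha,
        )


def estimate_table(
    chip_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    S: float,
    C: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-type enrichment estimates as a DataFrame indexed by type."""
    types = sorted(set(chip_counts) | set(control_counts))
    rows = []
    for t in types:
        e = EnrichmentEstimate.from_counts(
            t, chip_counts.get(t, 0), control_counts.get(t, 0), S, C, alpha
        )
        rows.append(
            (t, e.s, e.c, e.S, e.C, e.mle, e.ci_low, e.ci_high, e.zscore, e.significant)
        )
    return pd.DataFrame(
        rows,
        columns=["set_id", "s", "c", "S", "C", "mle", "ci_low", "ci_high", "zscore", "significant"],
    ).set_index("set_id")


def compare_estimates(
    s1: int, c1: int, S1: float, C1: float,
    s2: int, c2: int, S2: float, C2: float,
    alpha: float = 0.05,
) -> tuple[float, float, float, bool]:
    """Interval for the ratio of two fold-enrichment coefficients.

    Each coefficient is a ratio of two binomial proportions (s/S over c/C);
    the non-iterative approximate Bayesian construction of Price and Bonett
    adds half a count to every count and size and works on the log scale
    with variance 1/(x+1/2) - 1/(n+1/2) per proportion. Returns
    (ratio, ci_low, ci_high, consistent) where ``consistent`` means the
    interval contains 1 (the two estimates agree).
    """
    def _adj_log_theta(s, c, S, C):
        est = np.log((s + 0.5) / (S + 0.5)) - np.log((c + 0.5) / (C + 0.5))
        var = (
            1.0 / (s + 0.5) - 1.0 / (S + 0.5) + 1.0 / (c + 0.5) - 1.0 / (C + 0.5)
        )
        return est, var

    l1, v1 = _adj_log_theta(s1, c1, S1, C1)
    l2, v2 = _adj_log_theta(s2, c2, S2, C2)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    diff, se = l1 - l2, np.sqrt(v1 + v2)
    ratio = float(np.exp(diff))
    lo, hi = float(np.exp(diff - z * se)), float(np.exp(diff + z * se))
    return ratio, lo, hi, bool(lo <= 1.0 <= hi)


def clustering_values(mle: pd.DataFrame, significant: pd.DataFrame) -> pd.DataFrame:
    """Transform an MLE matrix for clustering: non-significant cells and
    significant depletion (MLE < 1) are set to 0; enrichment keeps its MLE."""
    vals = mle.where(significant, 0.0)
    vals = vals.where(vals >= 1.0, 0.0)
    return vals.astype(float)


def cluster_types(
    mle: pd.DataFrame, significant: pd.DataFrame
) -> tuple[list[str], np.ndarray]:
    """Ward clustering of repeat types by their enrichment profile.

    Returns (ordered row labels, scipy linkage matrix). Deterministic for a
    fixed set of rows regardless of input row order.
    """
    vals = clustering_values(mle, significant).sort_index()
    if (vals.to_numpy() == 0).all():
        warnings.warn("all-zero enrichment matrix: single trivial cluster", stacklevel=2)
    if len(vals) < 2:
        return list(vals.index), np.empty((0, 4))
    linkage = sch.linkage(vals.to_numpy(), method="ward")
    order = sch.leaves_list(linkage)
    return [vals.index[i] for i in order], linkage


def family_overrepresentation(
    cluster_members: set[str],
    universe: set[str],
    family_labels: Mapping[str, str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric over-representation of repeat families in a cluster.

    For every family in the universe, the upper-tail hypergeometric p-value
    of drawing at least the observed number of family members in a cluster
    of this size; corrected across the families tested (Bonferroni by
    default, 'none' to disable). Families absent from the cluster get p = 1.
    """
    if not cluster_members:
        raise ValueError("empty cluster")
    if not cluster_members <= universe:
        raise ValueError("cluster members must be a subset of the universe")
    M, n = len(universe), len(cluster_members)
    fam_universe: dict[str, int] = {}
    fam_cluster: dict[str, int] = {}
    for t in universe:
        fam = family_labels.get(t, "Unknown")
        fam_universe[fam] = fam_universe.get(fam, 0) + 1
        if t in cluster_members:
            fam_cluster[fam] = fam_cluster.get(fam, 0) + 1
    families = sorted(fam_universe)
    n_tests = len(families)
    rows = []
    for fam in families:
        K, k = fam_universe[fam], fam_cluster.get(fam, 0)
        p = float(sps.hypergeom.sf(k - 1, M, K, n))
        p_corr = p if correction == "none" else min(1.0, p * n_tests)
        rows.append((fam, k, K, n, M, p, p_corr))
    return pd.DataFrame(
        rows,
        columns=["family", "in_cluster", "in_universe", "cluster_size", "universe_size",
                 "p_raw", "p_corrected"],
    ).set_index("family")
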