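"""Comparative statistics for M across cell metadata groups.

Permutation tests for correlation significance, rank-based group
comparisons, min–max feature scaling of M, percent differences against a
grand mean, and neuron-count weighting of species averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonReport",
    "perm_corr_test",
    "group_compare",
    "feature_scale",
    "percent_diff",
    "weighted_species_total",
    "compare_groups",
]


def perm_corr_test(
    x,
    y,
    n_perm: int = 10000,
    mode: str = "standard",
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Pearson correlation with a permutation significance test.

    ``standard`` mode returns the usual two-sided permutation p-value: the
    fraction of shuffles whose |R| is at least |R_observed|. ``as_printed``
    mode reproduces the historical rule verbatim: the reported value is the
    fraction of shuffles whose (signed) correlation exceeds 0.05, and the
    null is rejected when that fraction falls below ``alpha``. The printed
    rule degenerates for long vectors (a shuffled R rarely exceeds 0.05), so
    ``standard`` is the default.

    Returns (R, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rng = np.random.default_rng(seed)
    r_obs = float(np.corrcoef(x, y)[0, 1])

    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    count = 0
    for _ in range(n_perm):
        r_perm = float(xc @ rng.permutation(yc)) / denom
        if mode == "standard":
            if abs(r_perm) >= abs(r_obs):
                count += 1
        elif mode == "as_printed":
            if r_perm > 0.05:
                count += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    p = count / n_perm
    return r_obs, p


def group_compare(groups: dict[str, np.ndarray], test: str = "ranksum") -> pd.DataFrame:
    """Rank-based comparisons between labelled groups (α = 0.05).

    ``ranksum`` performs all pairwise Wilcoxon rank-sum tests; ``kruskal``
    performs the k-group Kruskal–Wallis test. Returns a DataFrame with one
    row per comparison: labels, p-value and the rejection decision.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if len(np.asarray(groups[lab])) == 0:
            raise ValueError(f"group {lab!r} is empty")
    rows = []
    if test == "ranksum":
        for i in range(len(labels) - 1):
            for j in range(i + 1, len(labels)):
                a, b = np.asarray(groups[labels[i]]), np.asarray(groups[labels[j]])
                stat, p = sps.ranksums(a, b)
                rows.append(
                    {
                        "comparison": f"{labels[i]} vs {labels[j]}",
                        "statistic": float(stat),
                        "p_value": float(p),
                        "reject_at_0.05": bool(p < 0.05),
                    }
                )
    elif test == "kruskal":
        stat, p = sps.kruskal(*[np.asarray(groups[lab]) for lab in labels])
        rows.append(
            {
                "comparison": " vs ".join(labels),
                "statistic": float(stat),
                "p_value": float(p),
                "reject_at_0.05": bool(p < 0.05),
            }
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(rows)


def feature_scale(values) -> np.ndarray:
    """Min–max scaling to [0, 1] (M*); requires at least two distinct values."""
    v = np.asarray(values, dtype=float)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        raise ValueError("cannot feature-scale a constant input")
    return (v - vmin) / (vmax - vmin)


def percent_diff(group_mean: float, reference_mean: float) -> float:
    """Signed percent difference 100·(group − reference)/reference."""
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (group_mean - reference_mean) / reference_mean


def weighted_species_total(mean_M: float, n_neurons: float) -> float:
    """Whole-nervous-system pattern capacity: average M × neuron count."""
    if mean_M < 0 or n_neurons < 0:
        raise ValueError("inputs must be >= 0")
    return float(mean_M) * float(n_neurons)


@dataclass
class ComparisonReport:
    """Group-wise comparison of M across a metadata column."""

    group_col: str
    labels: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    counts: dict[str, int]
    overall_mean: float
    percent_diffs: dict[str, float]
    scaled: pd.Series
    pairwise: pd.DataFrame
    kruskal: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.labels,
                "n": [self.counts[g] for g in self.labels],
                "mean_M": [self.means[g] for g in self.labels],
                "sd_M": [self.sds[g] for g in self.labels],
                "percent_diff_vs_overall": [self.percent_diffs[g] for g in self.labels],
            }
        )


def compare_groups(
    df: pd.DataFrame, group_col: str = "species", value_col: str = "M"
) -> ComparisonReport:
    """Full comparison report for a metadata table.

    Expects columns ``group_col`` and ``value_col`` (one row per cell, e.g.
    cell_id, species, cell_type, region, M, n_branches, total_length).
    Scales M to [0, 1], computes per-group means/SDs, percent differences
    against the grand mean, pairwise rank-sum tests and the k-group
    Kruskal–Wallis test.
    """
    if group_col not in df.columns or value_col not in df.columns:
        raise ValueError(f"table must contain columns {group_col!r} and {value_col!r}")
    labels = sorted(df[group_col].unique())
    groups = {lab: df.loc[df[group_col] == lab, value_col].to_numpy(float) for lab in labels}
    overall = float(df[value_col].mean())
    means = {lab: float(v.mean()) for lab, v in groups.items()}
    sds = {lab: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for lab, v in groups.items()}
    counts = {lab: int(len(v)) for lab, v in groups.items()}
    pdiffs = {lab: percent_diff(means[lab], overall) for lab in labels}
    scaled = pd.Series(feature_scale(df[value_col].to_numpy(float)), index=df.index, name="M_star")
    pairwise = group_compare(groups, test="ranksum")
    kruskal = (
        group_compare(groups, test="kruskal")
        if len(labels) >= 2
        else pd.DataFrame()
    )
    return ComparisonReport(
        group_col=group_col,
        labels=labels,
        means=means,
        sds=sds,
        counts=counts,
        overall_mean=overall,
        percent_diffs=pdiffs,
        scaled=scaled,
        pairwise=pairwise,
        kruskal=kruskal,
    )
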