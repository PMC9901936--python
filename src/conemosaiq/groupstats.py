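"""Rank-based group comparisons: tie-corrected Kruskal-Wallis, the
Conover-Iman posthoc with Bonferroni adjustment, and plain group
summaries (mean +/- sd, fold and percent change vs a control group).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsConfig",
    "GroupComparison",
    "kruskal_wallis",
    "conover_iman",
    "bonferroni_adjust",
    "summarize",
    "compare_groups",
]


class StatsError(ValueError):
    pass


@dataclass
class StatsConfig:
    significance_level: float = 0.01
    adjustment: str = "bonferroni"
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not (0 < self.significance_level < 1):
            raise StatsError("significance_level must be in (0, 1)")
        if self.adjustment != "bonferroni":
            raise StatsError("only bonferroni adjustment is supported")
        if self.sidedness not in ("two-sided", "one-sided"):
            raise StatsError("sidedness must be 'two-sided' or 'one-sided'")


@dataclass
class GroupComparison:
    group_labels: list[str]
    n_per_group: list[int]
    N: int
    k: int
    H: float
    p: float
    pairwise: pd.DataFrame
    summaries: pd.DataFrame
    effects: pd.DataFrame | None


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties sharing their average (mid) rank."""
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    ranks = np.empty(len(pooled))
    i = 0
    n = len(pooled)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _validate_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise StatsError(f"group {i} is empty")
        if not np.all(np.isfinite(a)):
            raise StatsError(f"group {i} contains non-finite values")
    if sum(a.size for a in arrays) < 3:
        raise StatsError("need N >= 3 observations in total")
    return arrays


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square tail p.

    H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / [1 - sum(t^3 - t)/(N^3 - N)]
    with mid-ranks for ties; p from chi-square with k-1 df. All-tied
    data (zero tie-correction denominator) returns H = 0, p = 1 by
    convention.
    """
    arrays = _validate_groups(groups)
    k = len(arrays)
    sizes = np.array([a.size for a in arrays])
    N = int(sizes.sum())
    pooled = np.concatenate(arrays)
    ranks = _midranks(pooled)

    bounds = np.cumsum(sizes)[:-1]
    rank_sums = np.array([r.sum() for r in np.split(ranks, bounds)])
    h_raw = 12.0 / (N * (N + 1)) * np.sum(rank_sums ** 2 / sizes) - 3.0 * (N + 1)

    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts ** 3 - tie_counts) / (N ** 3 - N)
    if correction == 0:  # every observation tied
        return 0.0, 1.0
    H = h_raw / correction
    p = float(stats.chi2.sf(H, k - 1))
    return float(H), p


def conover_iman(
    groups,
    H: float | None = None,
    group_labels: list[str] | None = None,
    sidedness: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise Conover-Iman t statistics on the Kruskal-Wallis ranks.

    t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))
    with S^2 = (sum R^2 - N(N+1)^2/4)/(N-1) over all mid-ranks; p from
    Student's t with N-k df, Bonferroni-adjusted over the k(k-1)/2
    pairs. If ``H`` is omitted it is recomputed from the same data.
    """
    arrays = _validate_groups(groups)
    k = len(arrays)
    sizes = np.array([a.size for a in arrays])
    N = int(sizes.sum())
    if N <= k:
        raise StatsError("need N > k for the posthoc test")
    if H is None:
        H, _ = kruskal_wallis(groups)
    if group_labels is None:
        group_labels = [f"group{i}" for i in range(k)]
    if len(group_labels) != k:
        raise StatsError("group_labels length must equal number of groups")

    pooled = np.concatenate(arrays)
    ranks = _midranks(pooled)
    bounds = np.cumsum(sizes)[:-1]
    per_group = np.split(ranks, bounds)
    mean_ranks = np.array([r.mean() for r in per_group])
    S2 = (np.sum(ranks ** 2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    factor = (N - 1.0 - H) / (N - k)
    if factor < 0:
        warnings.warn(
            "H exceeds N-1 (extreme ties); variance factor clamped to 0",
            stacklevel=2,
        )
        factor = 0.0
    df = N - k

    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        denom_sq = S2 * factor * (1.0 / sizes[i] + 1.0 / sizes[j])
        diff = mean_ranks[i] - mean_ranks[j]
        if denom_sq > 0:
            t = diff / np.sqrt(denom_sq)
            if sidedness == "two-sided":
                p_raw = 2.0 * float(stats.t.sf(abs(t), df))
            else:
                p_raw = float(stats.t.sf(t, df))
            p_raw = min(p_raw, 1.0)
        else:
            t = 0.0
            p_raw = 1.0
        rows.append(
            {
                "group_i": group_labels[i],
                "group_j": group_labels[j],
                "mean_rank_i": mean_ranks[i],
                "mean_rank_j": mean_ranks[j],
                "t": t,
                "df": df,
                "p_raw": p_raw,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bonferroni_adjust(table["p_raw"].to_numpy(), len(pairs))
    return table


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Map each p to min(1, m * p); m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise StatsError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def summarize(
    groups,
    group_labels: list[str],
    control_label: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-group mean, sample sd (n-1), n; fold/percent change vs control.

    fold = mean_group / mean_control; percent change =
    100 * (mean_control - mean_group) / mean_control. A zero control
    mean reports missing effects rather than infinities.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) != len(group_labels):
        raise StatsError("group_labels length must equal number of groups")
    summaries = pd.DataFrame(
        {
            "group": group_labels,
            "n": [a.size for a in arrays],
            "mean": [a.mean() if a.size else np.nan for a in arrays],
            "sd": [a.std(ddof=1) if a.size > 1 else np.nan for a in arrays],
        }
    )
    if control_label is None:
        return summaries, None
    if control_label not in group_labels:
        raise StatsError(f"control group {control_label!r} not found")
    control_mean = float(
        summaries.loc[summaries["group"] == control_label, "mean"].iloc[0]
    )
    rows = []
    for label, a in zip(group_labels, arrays):
        if label == control_label:
            continue
        if control_mean == 0 or not np.isfinite(control_mean):
            fold = np.nan
            pct = np.nan
        else:
            fold = a.mean() / control_mean
            pct = 100.0 * (control_mean - a.mean()) / control_mean
        rows.append({"group": label, "fold_vs_control": fold, "percent_change": pct})
    return summaries, pd.DataFrame(rows)


def compare_groups(
    data: dict[str, list[float] | np.ndarray],
    control_label: str | None = None,
    config: StatsConfig | None = None,
) -> GroupComparison:
    """Full comparison: Kruskal-Wallis, Conover-Iman posthoc, summaries."""
    if config is None:
        config = StatsConfig()
    labels = list(data)
    groups = [data[label] for label in labels]
    H, p = kruskal_wallis(groups)
    pairwise = conover_iman(groups, H, labels, sidedness=config.sidedness)
    summaries, effects = summarize(groups, labels, control_label)
    sizes = [len(np.asarray(g)) for g in groups]
    return GroupComparison(
        group_labels=labels,
        n_per_group=sizes,
        N=int(sum(sizes)),
        k=len(labels),
        H=H,
        p=p,
        pairwise=pairwise,
        summaries=summaries,
        effects=effects,
    )
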