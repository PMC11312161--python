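"""Storage-trend statistics: one-way ANOVA and Duncan's multiple range test.

Duncan's test compares the sorted group means with span-dependent critical
ranges R_p = q(p, df_error; level (1-alpha)^(p-1)) * sqrt(MSE / n_h), where
q is the studentized-range quantile evaluated at Duncan's special
protection level and n_h the harmonic mean group size (Kramer adjustment
for unequal n). Groups that cannot be separated share a significance
letter, reproducing the familiar letter columns of storage-trend tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import ReferenceTable

__all__ = [
    "AnovaResult",
    "DuncanResult",
    "one_way_anova",
    "duncan_mrt",
    "trend_report",
    "adjacent_false_difference_rate",
]


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    df_between: int
    df_error: int
    mse: float
    F: float


@dataclass(frozen=True)
class DuncanResult:
    """Group means with Duncan significance letters.

    ``groups`` holds (label, n, mean) in the input order; groups sharing
    any letter in ``letters`` are not significantly different at ``alpha``.
    """

    groups: tuple[tuple[object, int, float], ...]
    mse: float
    df_error: int
    alpha: float
    letters: dict


def one_way_anova(groups: Mapping[object, Sequence[float]]) -> AnovaResult:
    """Standard one-way decomposition; MSE = SS_within / df_error."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 1 for a in arrays.values()):
        raise ValueError("every group needs at least one value")
    n_total = sum(a.size for a in arrays.values())
    df_error = n_total - len(arrays)
    if df_error < 1:
        raise ValueError("all groups are singletons: no error degrees of freedom")
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(arrays) - 1
    mse = ss_within / df_error
    F = (ss_between / df_between) / mse if mse > 0 else np.inf
    if ss_between == 0:
        F = 0.0
    return AnovaResult(
        float(ss_between), float(ss_within), df_between, df_error, float(mse), float(F)
    )


@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, p: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level (1-alpha)^(p-1)."""
    return float(stats.studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df))


def _protected_significance(sorted_means: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    """Upper-triangular significance matrix under the range-protection rule.

    ``sorted_means`` descending; ``ranges[p-2]`` is the critical range for a
    span of p means. A span is tested only if every containing span was
    significant; sub-spans of a non-significant span are declared
    non-significant without testing.
    """
    k = sorted_means.size
    sig = np.zeros((k, k), dtype=bool)
    blocked = np.zeros((k, k), dtype=bool)
    for p in range(k, 1, -1):
        for i in range(0, k - p + 1):
            j = i + p - 1
            if blocked[i, j]:
                continue
            if sorted_means[i] - sorted_means[j] > ranges[p - 2]:
                sig[i, j] = True
            else:
                blocked[i : j + 1, i : j + 1] = True
    return sig


def duncan_mrt(groups: Mapping[object, Sequence[float]], alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with significance-letter assignment."""
    anova = one_way_anova(groups)
    labels = list(groups.keys())
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    means = np.array([a.mean() for a in arrays])
    sizes = np.array([a.size for a in arrays])
    k = len(labels)
    n_h = k / np.sum(1.0 / sizes)  # harmonic mean group size
    se = np.sqrt(anova.mse / n_h)
    ranges = np.array([_duncan_q(alpha, p, anova.df_error) * se for p in range(2, k + 1)])

    order = np.argsort(-means, kind="stable")
    sorted_means = means[order]
    sig = _protected_significance(sorted_means, ranges)

    # maximal runs of mutually non-significant groups each get one letter;
    # protection makes j_max(i) non-decreasing, so containment is a prefix test
    j_max = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i, j + 1]:
            j += 1
        j_max.append(j)
    intervals = [
        (i, j_max[i]) for i in range(k) if i == 0 or j_max[i] > j_max[i - 1]
    ]
    letters: dict = {label: "" for label in labels}
    for letter_idx, (i, j) in enumerate(intervals):
        letter = chr(ord("a") + letter_idx)
        for pos in range(i, j + 1):
            letters[labels[order[pos]]] += letter
    return DuncanResult(
        groups=tuple((labels[i], int(sizes[i]), float(means[i])) for i in range(k)),
        mse=anova.mse,
        df_error=anova.df_error,
        alpha=alpha,
        letters=letters,
    )


def trend_report(refs: ReferenceTable, alpha: float = 0.05) -> dict[str, dict]:
    """Per-constituent storage-day mean +/- SD table with Duncan letters."""
    days = sorted(refs.df["storage_day"].unique())
    if len(days) < 2:
        raise ValueError("need at least 2 storage days for a trend report")
    out: dict[str, dict] = {}
    for constituent in refs.constituents:
        sub = refs.df[refs.df["constituent"] == constituent]
        groups = {
            int(day): sub.loc[sub["storage_day"] == day, "concentration_pct"].to_numpy()
            for day in days
        }
        groups = {d: v for d, v in groups.items() if v.size}
        if len(groups) < 2:
            raise ValueError(f"constituent {constituent!r} present on < 2 days")
        duncan = duncan_mrt(groups, alpha=alpha)
        table = pd.DataFrame(
            {
                "storage_day": list(groups),
                "n": [v.size for v in groups.values()],
                "mean_pct": [float(v.mean()) for v in groups.values()],
                "sd_pct": [float(v.std(ddof=1)) if v.size > 1 else 0.0 for v in groups.values()],
                "letters": [duncan.letters[d] for d in groups],
            }
        )
        out[constituent] = {"duncan": duncan, "table": table}
    return out


def adjacent_false_difference_rate(
    n_groups: int = 5,
    n_per_group: int = 15,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo size of Duncan's span-2 critical range under the null.

    Draws all groups from one normal distribution and, for each pair of
    groups adjacent in label order (consecutive sampling dates), declares a
    difference when the mean gap exceeds the span-2 critical range
    R_2 = q(2, df; 1-alpha) * sqrt(MSE / n_h). Duncan's protection level for
    a span of two means is exactly ``alpha``, so the false-difference rate
    calibrates the critical-range computation itself.
    """
    rng = np.random.default_rng(seed)
    false_hits = 0
    comparisons = 0
    for _ in range(n_reps):
        data = rng.standard_normal((n_groups, n_per_group))
        groups = {g: data[g] for g in range(n_groups)}
        anova = one_way_anova(groups)
        r2 = _duncan_q(alpha, 2, anova.df_error) * np.sqrt(anova.mse / n_per_group)
        means = data.mean(axis=1)
        for g in range(n_groups - 1):
            false_hits += abs(means[g] - means[g + 1]) > r2
            comparisons += 1
    return false_hits / comparisons
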