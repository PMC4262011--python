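"""Group comparisons: rank-sum tests, effect sizes, power, and a
dataset-blocked permutation stand-in for mixed-effects modeling.

The permutation test is NOT equivalent to a mixed-effects analysis; it
permutes group labels at the dataset (block) level and compares group
means of per-dataset means.  It is provided as a documented substitute.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, nct
from scipy.stats import t as t_dist

from .errors import DomainError, EmptyInputError, InsufficientDataError

EXACT_LIMIT = 10_000  # n_x * n_y above which the normal approximation is used


def wilcoxon_rank_sum(x, y) -> dict:
    """Two-sided rank-sum test; ``W`` is the Mann-Whitney statistic of x.

    Exact enumeration when ``n_x * n_y <= 10_000`` and there are no ties,
    otherwise the tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise EmptyInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) * len(y) <= EXACT_LIMIT) and not has_ties
    res = mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return {"W": float(res.statistic), "p_value": float(res.pvalue),
            "exact": exact}


def cohens_d(x, y) -> float:
    """Difference of means over the (n-1)-weighted pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("Cohen's d needs >= 2 per group")
    nx, ny = len(x), len(y)
    pooled_var = (
        (nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)
    ) / (nx + ny - 2)
    if pooled_var == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def power_two_sample(n_x: int, n_y: int, d: float, alpha: float = 0.05) -> float:
    """Two-sided two-sample t-test power via the noncentral t distribution."""
    if n_x < 2 or n_y < 2:
        raise InsufficientDataError("power needs >= 2 per group")
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    df = n_x + n_y - 2
    ncp = d * math.sqrt(n_x * n_y / (n_x + n_y))
    crit = t_dist.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - nct.cdf(crit, df, ncp) + nct.cdf(-crit, df, ncp)
    )


def blocked_permutation_test(
    table: pd.DataFrame,
    metric: str,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    group_col: str = "clade",
    block_col: str = "dataset",
) -> dict:
    """Permute group labels at the block level; the statistic is the
    difference of group means of per-block means.

    With few blocks all distinct assignments are enumerated exactly (a
    warning notes the switch); p is the proportion of permuted statistics
    at least as extreme as the observed one.
    """
    df = table[[block_col, group_col, metric]].dropna()
    block_means = (
        df.groupby([block_col, group_col], observed=True)[metric]
        .mean()
        .reset_index()
    )
    groups = sorted(block_means[group_col].unique())
    if len(groups) != 2:
        raise DomainError(f"need exactly 2 groups, found {groups}")
    g_a, g_b = groups
    counts = block_means[group_col].value_counts()
    if counts.min() < 2:
        raise InsufficientDataError("need >= 2 datasets per group")
    values = block_means[metric].to_numpy()
    labels = block_means[group_col].to_numpy()
    n_a = int((labels == g_a).sum())
    n_blocks = len(values)

    def stat(mask_a: np.ndarray) -> float:
        return float(values[mask_a].mean() - values[~mask_a].mean())

    obs = stat(labels == g_a)
    n_exact = math.comb(n_blocks, n_a)
    if n_exact <= reps:
        warnings.warn(
            f"only {n_exact} distinct assignments; using exact enumeration",
            stacklevel=2,
        )
        null = np.empty(n_exact)
        for i, idx in enumerate(
            itertools.combinations(range(n_blocks), n_a)
        ):
            mask = np.zeros(n_blocks, dtype=bool)
            mask[list(idx)] = True
            null[i] = stat(mask)
        exact = True
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        null = np.empty(reps)
        for i in range(reps):
            perm = rng.permutation(n_blocks)
            mask = np.zeros(n_blocks, dtype=bool)
            mask[perm[:n_a]] = True
            null[i] = stat(mask)
        exact = False
    p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
    return {
        "metric": metric,
        "group_a": g_a,
        "group_b": g_b,
        "observed_diff": obs,
        "p_value": p,
        "exact": exact,
        "n_permutations": len(null),
        "note": "block-permutation stand-in; not a mixed-effects model",
    }


@dataclass
class GroupComparison:
    statistic_name: str
    group_a: str
    group_b: str
    W: float
    p_value: float
    d: float
    power: float


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "clade",
    block_col: str = "dataset",
    alpha: float = 0.05,
) -> GroupComparison:
    """Dataset-level comparison of one metric between two groups.

    Each dataset contributes its mean; the rank-sum test, Cohen's d and
    retrospective power are computed on those per-dataset means.
    """
    df = table[[block_col, group_col, metric]].dropna()
    block_means = (
        df.groupby([block_col, group_col], observed=True)[metric]
        .mean()
        .reset_index()
    )
    groups = sorted(block_means[group_col].unique())
    if len(groups) != 2:
        raise DomainError(f"need exactly 2 groups, found {groups}")
    g_a, g_b = groups
    x = block_means.loc[block_means[group_col] == g_a, metric].to_numpy()
    y = block_means.loc[block_means[group_col] == g_b, metric].to_numpy()
    w = wilcoxon_rank_sum(x, y)
    d = cohens_d(x, y)
    power = power_two_sample(len(x), len(y), abs(d), alpha)
    return GroupComparison(
        statistic_name=metric,
        group_a=g_a,
        group_b=g_b,
        W=w["W"],
        p_value=w["p_value"],
        d=d,
        power=power,
    )


__all__ = [
    "GroupComparison",
    "wilcoxon_rank_sum",
    "cohens_d",
    "power_two_sample",
    "blocked_permutation_test",
    "compare_groups",
]
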