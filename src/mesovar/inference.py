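"""Thin inferential-statistics helpers used around the variability analyses:
one-way ANOVA across stimulation groups, paired one-sided Wilcoxon tests for
pre/post comparisons, and Bonferroni-corrected pairwise rank-sum tests
across groups (e.g. cortical regions)."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "n_pairwise_comparisons",
    "bonferroni_threshold",
    "variability_anova",
    "paired_prepost_wilcoxon",
    "pairwise_ranksum",
]


def n_pairwise_comparisons(n_groups: int) -> int:
    """Number of unordered group pairs, C(n, 2)."""
    if n_groups < 0:
        raise ValueError("n_groups must be nonnegative")
    return comb(n_groups, 2)


def bonferroni_threshold(alpha: float, n_comparisons: int, digits: int | None = 2) -> float:
    """Per-comparison significance threshold alpha / m.

    ``digits`` rounds the mantissa to the stated precision (e.g. 0.05/66
    reported as 7.6e-4); pass None for the unrounded value.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    thr = alpha / n_comparisons
    if digits is None:
        return thr
    exp = int(np.floor(np.log10(thr)))
    mant = round(thr / 10**exp, digits - 1)
    return mant * 10**exp


def variability_anova(groups: dict) -> tuple[float, float]:
    """One-way ANOVA of per-trial variability changes across stimulus groups.

    ``groups`` maps a stimulation level (amplitude/contrast) to the vector
    of per-trial post-minus-pre deviation values.  Returns (F, p).
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def paired_prepost_wilcoxon(pre: np.ndarray, post: np.ndarray, alternative: str = "less") -> tuple[float, float]:
    """Paired one-sided Wilcoxon signed-rank test of post vs pre values.

    Default alternative 'less' tests whether post values are systematically
    smaller than pre (variability quenching).  Returns (statistic, p).
    """
    res = stats.wilcoxon(np.asarray(post, float), np.asarray(pre, float), alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def pairwise_ranksum(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided rank-sum test between every pair of groups, Bonferroni-corrected.

    Each sample (e.g. a neuron's variability) belongs to one group (e.g. a
    cortical region).  The corrected per-pair threshold is alpha / C(n, 2).
    """
    names = list(groups)
    m = n_pairwise_comparisons(len(names))
    thr = bonferroni_threshold(alpha, m) if m else np.nan
    rows = []
    for a, b in combinations(names, 2):
        stat, p = stats.ranksums(np.asarray(groups[a], float), np.asarray(groups[b], float))
        rows.append({"group_a": a, "group_b": b, "statistic": float(stat), "p_value": float(p),
                     "threshold": thr, "significant": bool(p < thr)})
    return pd.DataFrame(rows)
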