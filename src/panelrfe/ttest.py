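"""Paired t-test feature screen and ranking-overlap utilities.

The statistical baseline the consensus selection is compared against: each
analyte is tested independently for a zero mean within-subject pre/post
difference, features are ranked by ascending p, and the top-k overlap with
the consensus ranking is counted.  Raw (uncorrected) p-values are reported at
alpha = 0.05, exactly as the baseline does; an optional Bonferroni flag is
provided but off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PANEL
from .simulate import Cohort

__all__ = ["paired_t", "screen_features", "topk_overlap"]


def paired_t(pre_values, post_values) -> tuple[float, int, float]:
    """Paired t-test on differences ``d = pre - post``.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d) / sqrt(n))``, df = n-1
    and a two-sided p from the t distribution.  Rejects vectors of unequal
    length, fewer than two pairs, or zero difference variance (the statistic
    is undefined there).
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d vectors")
    n = len(pre)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = pre - post
    if np.var(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, n - 1, 1.0
        raise ValueError("zero difference variance: t statistic undefined")
    res = stats.ttest_rel(pre, post)
    return float(res.statistic), n - 1, float(res.pvalue)


def screen_features(cohort: Cohort, alpha: float = 0.05,
                    bonferroni: bool = False) -> pd.DataFrame:
    """Screen all 41 analytes with the paired t-test.

    Pairs are matched by ``subject_id``; subjects lacking either phase are
    ignored.  Output is ranked by ascending p (ties by panel index) in the
    shape of the published screen: analyte, before mean +/- SD, after
    mean +/- SD, t, df, p, significance flag at ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    pre, post = cohort.complete_pairs()
    if len(pre) == 0:
        raise ValueError("cohort has no complete subject pairs")
    level = alpha / len(PANEL) if bonferroni else alpha
    rows = []
    for entry in PANEL:
        a = pre[entry.name].to_numpy(dtype=float)
        b = post[entry.name].to_numpy(dtype=float)
        t, df, p = paired_t(a, b)
        rows.append(
            {
                "index": entry.index,
                "name": entry.name,
                "pre_mean": a.mean(),
                "pre_sd": a.std(ddof=1),
                "post_mean": b.mean(),
                "post_sd": b.std(ddof=1),
                "t": t,
                "df": df,
                "p_value": p,
                "significant": p < level,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(["p_value", "index"], kind="mergesort")
    table.insert(0, "rank", range(1, len(table) + 1))
    return table.reset_index(drop=True)


def topk_overlap(ranking_a, ranking_b, k: int) -> int:
    """Size of the intersection of the top-k entries of two rankings."""
    a = list(ranking_a)
    b = list(ranking_b)
    if k > len(a) or k > len(b):
        raise ValueError("k exceeds ranking length")
    return len(set(a[:k]) & set(b[:k]))
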