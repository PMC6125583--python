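"""Group-level inference: one-way ANOVA across depths, one-tailed t-tests,
and the multiple-comparison corrections applied to them.

The depth ANOVA defaults to the classical one-way form (df = k-1, N-k over
pooled observations); a subject-blocked repeated-measures variant is
available for paired designs.  Post-hoc depth tests are corrected by BH-FDR
over the fixed seven-pair family; region-by-depth comparisons by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StatResult",
    "DEPTH_PAIR_FAMILY",
    "one_way_anova",
    "one_tailed_t",
    "adjust_fdr",
    "adjust_bonferroni",
]

#: The seven depth pairs forming the post-hoc correction family.
DEPTH_PAIR_FAMILY = (
    (0.1, 0.3), (0.1, 0.5), (0.1, 0.7), (0.1, 0.9),
    (0.3, 0.9), (0.5, 0.9), (0.7, 0.9),
)


@dataclass
class StatResult:
    """One inferential result with its correction bookkeeping."""

    test: str
    statistic: float
    df: tuple
    p: float
    p_adjusted: float = np.nan
    family_size: int = 1
    extra: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> bool:
        p = self.p_adjusted if (adjusted and np.isfinite(self.p_adjusted)) else self.p
        return bool(p < alpha)


def one_way_anova(groups, repeated: bool = False) -> StatResult:
    """One-way F test across k groups of observations.

    Classical form (default): ``F`` with df (k-1, N-k) on pooled values.
    ``repeated=True`` treats rows as subjects (all groups equal length) and
    removes the subject effect: df (k-1, (k-1)(n-1)).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    if not repeated:
        f, p = stats.f_oneway(*groups)
        n_total = sum(g.size for g in groups)
        df = (k - 1, n_total - k)
        if not np.isfinite(f):  # zero within-group variance, unequal means
            return StatResult("anova", float("inf"), df, 0.0,
                              extra={"degenerate": True})
        return StatResult("anova", float(f), df, float(p))
    lengths = {g.size for g in groups}
    if len(lengths) != 1:
        raise ValueError("repeated-measures ANOVA needs equal group sizes")
    data = np.stack(groups, axis=1)  # (n_subjects, k)
    n = data.shape[0]
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    if ms_err == 0:
        return StatResult("rm-anova", float("inf"), (df1, df2), 0.0,
                          extra={"degenerate": True})
    f = ms_cond / ms_err
    return StatResult("rm-anova", float(f), (df1, df2),
                      float(stats.f.sf(f, df1, df2)))


def one_tailed_t(a, b, paired: bool = False, direction: str = "greater") -> StatResult:
    """Student t with a one-sided p in the stated direction (a vs b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal lengths")
        res = stats.ttest_rel(a, b, alternative=direction)
        df = (a.size - 1,)
    else:
        res = stats.ttest_ind(a, b, alternative=direction)
        df = (a.size + b.size - 2,)
    if not np.isfinite(res.statistic):
        return StatResult("t", np.nan, df, np.nan, extra={"degenerate": True})
    return StatResult("t", float(res.statistic), df, float(res.pvalue))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone-enforced step-up)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if p.size == 1:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def adjust_bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, p * m)
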