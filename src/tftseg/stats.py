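"""One-tailed Mann-Whitney U comparisons and group summary tables.

The study's group comparisons are rank-based: U counts pairwise wins of
the first group over the second.  The p-value is exact (full
enumeration) for small tie-free samples and a tie- and
continuity-corrected normal approximation otherwise.  Reports also carry
the SPSS-style ``min(U1, U2)`` convention used in the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

#: largest "smaller group" for which the exact null distribution is used
EXACT_N_MAX = 8


@dataclass
class MWUResult:
    """Result of a Mann-Whitney U comparison of two groups.

    ``u`` counts pairwise wins of x over y (ties count 1/2), so
    ``u(x, y) + u(y, x) = n1 * n2``; ``u_min`` is the SPSS-style
    ``min(U1, U2)`` used when reporting.
    """

    u: float
    p: float
    n1: int
    n2: int
    method: str                 # "exact" | "normal-approx"
    alternative: str            # "greater" | "less" | "two-sided"
    name: str = ""

    @property
    def u_min(self) -> float:
        return min(self.u, self.n1 * self.n2 - self.u)

    def __str__(self):
        stars = significance_stars(self.p)
        tag = f" {stars}" if stars else ""
        return (f"{self.name + ': ' if self.name else ''}"
                f"U = {self.u_min:g}, p = {self.p:.4g}{tag}")


def significance_stars(p: float) -> str:
    """Conventional significance markers (formatting only)."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def mwu(x, y, alternative: str = "two-sided", name: str = "") -> MWUResult:
    """Mann-Whitney U test of x against y.

    Exact enumeration when the smaller group has <= 8 observations and
    the pooled data are tie-free; otherwise the normal approximation
    with midrank tie correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = min(x.size, y.size) <= EXACT_N_MAX and tie_free
    res = mannwhitneyu(x, y, alternative=alternative,
                       method="exact" if exact else "asymptotic",
                       use_continuity=True)
    return MWUResult(u=float(res.statistic), p=float(res.pvalue),
                     n1=int(x.size), n2=int(y.size),
                     method="exact" if exact else "normal-approx",
                     alternative=alternative, name=name)


def group_summary(cohort: pd.DataFrame, value: str = "score",
                  by=("treatment", "session", "phase")) -> pd.DataFrame:
    """Mean +/- sample SD (n-1 denominator) per group cell.

    Missing values (NaN markers) propagate into the counts; a single-
    value cell reports an undefined (NaN) SD.
    """
    g = cohort.groupby(list(by))[value]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
    if (out["n"] == 0).any():
        raise ValueError("empty group cell in summary")
    return out.reset_index()


# ---------------------------------------------------------------------------
# The study's contrast set

@dataclass
class Contrast:
    """One configured group comparison on a per-participant metric."""

    name: str
    metric: str            # improvement | opposite_score | workload_change
    group1: str            # treatment prefix/suffix, e.g. "VT" or "HA"
    group2: str
    alternative: str       # direction of the one-tailed test for group1


#: Hypothesized directions: virtual training transfers better than real;
#: low abstraction gains more on the trained task; high abstraction
#: mobilizes better to the opposite task; workload drops more under
#: virtual training and high abstraction.
DEFAULT_CONTRASTS = (
    Contrast("transfer_by_training", "improvement", "VT", "RT", "greater"),
    Contrast("transfer_by_abstraction", "improvement", "LA", "HA", "greater"),
    Contrast("mobilization_by_abstraction", "opposite_score",
             "HA", "LA", "greater"),
    Contrast("workload_by_training", "workload_change", "VT", "RT", "less"),
    Contrast("workload_by_abstraction", "workload_change",
             "HA", "LA", "less"),
)


def _metric_series(cohort: pd.DataFrame, metric: str) -> pd.Series:
    from .behavior import improvement, workload_change

    if metric == "improvement":
        return improvement(cohort)
    if metric == "opposite_score":
        return cohort[cohort["phase"] == "execution_opposite"] \
            .set_index("participant")["score"]
    if metric == "workload_change":
        return workload_change(cohort)
    raise ValueError(f"unknown metric: {metric!r}")


def condition_contrasts(cohort: pd.DataFrame,
                        contrasts=DEFAULT_CONTRASTS) -> list[MWUResult]:
    """Run the configured one-tailed contrasts on a cohort table.

    Groups are formed by matching the treatment label against the
    contrast's factor level (``VT``/``RT`` for training type,
    ``HA``/``LA`` for abstraction level).
    """
    treat = cohort.drop_duplicates("participant") \
        .set_index("participant")["treatment"]
    results = []
    for c in contrasts:
        vals = _metric_series(cohort, c.metric).dropna()
        t = treat.loc[vals.index]
        g1 = vals[t.str.contains(c.group1)]
        g2 = vals[t.str.contains(c.group2)]
        if g1.empty or g2.empty:
            raise ValueError(f"contrast {c.name}: missing factor level")
        results.append(mwu(g1, g2, alternative=c.alternative, name=c.name))
    return results
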