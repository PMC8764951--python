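"""Normality-gated within/between-group comparisons with mean +/- SEM summaries.

The comparison scheme: paired contrasts (the same animals across sessions)
use a paired t-test when the paired differences pass a Shapiro-Wilk
normality check at alpha = 0.05 and the Wilcoxon signed-rank test otherwise;
group contrasts use one-way ANOVA when every group passes the check and
otherwise Mann-Whitney U (two groups) or Kruskal-Wallis (three or more) with
pairwise Mann-Whitney follow-ups when the omnibus test is significant.

All tests are two-sided; p < 0.05 is flagged significant.  Rank tests use
exact null distributions for n <= 12 without ties, and the normal
approximation with continuity and tie corrections otherwise.  No
multiple-testing correction is applied (none is used in the study design
this package mirrors); reports flag this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

__all__ = [
    "ALPHA",
    "StatResult",
    "is_normal",
    "paired_t",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "one_way_anova",
    "kruskal_wallis",
    "choose_and_compare_within",
    "choose_and_compare_between",
    "summarize",
]

ALPHA = 0.05
EXACT_N_MAX = 12


@dataclass
class StatResult:
    """One planned comparison: which test ran, its statistic and verdict."""

    comparison: str
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    n: tuple
    details: dict = field(default_factory=dict)


def _result(comparison, test_name, statistic, p_value, n, **details) -> StatResult:
    p = float(p_value)
    return StatResult(
        comparison=comparison,
        test_name=test_name,
        statistic=float(statistic),
        p_value=p,
        significant=bool(p < ALPHA),
        n=tuple(int(v) for v in n),
        details=details,
    )


def is_normal(values, alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk normality gate; constant samples count as non-normal."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or np.ptp(values) == 0:
        return False
    stat, p = sst.shapiro(values)
    return bool(p > alpha)


# ---------------------------------------------------------------------------
# Individual tests
# ---------------------------------------------------------------------------

def paired_t(a, b, comparison: str = "") -> StatResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    stat, p = sst.ttest_rel(a, b)
    return _result(comparison, "paired_t", stat, p, (a.size, b.size))


def wilcoxon_signed_rank(a, b, comparison: str = "") -> StatResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = a - b
    if np.all(d == 0):
        # Degenerate pairing: no evidence against the null by convention.
        return _result(comparison, "wilcoxon_signed_rank", 0.0, 1.0,
                       (a.size, b.size), degenerate=True)
    nz = d[d != 0]
    abs_ranks_tied = np.unique(np.abs(nz)).size < nz.size
    exact = nz.size <= EXACT_N_MAX and not abs_ranks_tied and nz.size == d.size
    stat, p = sst.wilcoxon(
        a, b, zero_method="wilcox",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return _result(comparison, "wilcoxon_signed_rank", stat, p,
                   (a.size, b.size), exact=exact)


def mann_whitney_u(a, b, comparison: str = "") -> StatResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    exact = (max(a.size, b.size) <= EXACT_N_MAX
             and np.unique(pooled).size == pooled.size)
    stat, p = sst.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return _result(comparison, "mann_whitney_u", stat, p, (a.size, b.size),
                   exact=exact)


def one_way_anova(groups, comparison: str = "") -> StatResult:
    groups = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(groups)
    ns = tuple(g.size for g in groups)
    if np.ptp(pooled) == 0:
        return _result(comparison, "anova", 0.0, 1.0, ns, degenerate=True)
    stat, p = sst.f_oneway(*groups)
    return _result(comparison, "anova", stat, p, ns)


def kruskal_wallis(groups, comparison: str = "") -> StatResult:
    groups = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(groups)
    ns = tuple(g.size for g in groups)
    if np.ptp(pooled) == 0:
        return _result(comparison, "kruskal_wallis", 0.0, 1.0, ns, degenerate=True)
    stat, p = sst.kruskal(*groups)
    return _result(comparison, "kruskal_wallis", stat, p, ns)


# ---------------------------------------------------------------------------
# Normality-gated choosers
# ---------------------------------------------------------------------------

def choose_and_compare_within(values_a, values_b, comparison: str = "") -> StatResult:
    """Paired within-group contrast with the parametric/nonparametric gate."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size != b.size:
        raise ValueError(f"paired samples differ in length: {a.size} != {b.size}")
    if a.size < 3:
        raise ValueError(f"need at least 3 pairs, got {a.size}")
    d = a - b
    if np.all(d == 0):
        return wilcoxon_signed_rank(a, b, comparison)
    if is_normal(d):
        res = paired_t(a, b, comparison)
    else:
        res = wilcoxon_signed_rank(a, b, comparison)
    res.details["normal_differences"] = is_normal(d)
    return res


def choose_and_compare_between(groups, comparison: str = "") -> StatResult:
    """Between-group contrast: ANOVA if all groups normal, ranks otherwise.

    A significant Kruskal-Wallis omnibus adds pairwise Mann-Whitney U results
    under ``details['pairwise']``.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 3:
            raise ValueError(f"group {i} has n={g.size} < 3")
    if all(is_normal(g) for g in groups):
        res = one_way_anova(groups, comparison)
    elif len(groups) == 2:
        res = mann_whitney_u(groups[0], groups[1], comparison)
    else:
        res = kruskal_wallis(groups, comparison)
        if res.significant:
            res.details["pairwise"] = [
                mann_whitney_u(groups[i], groups[j], f"{comparison}[{i}v{j}]")
                for i in range(len(groups)) for j in range(i + 1, len(groups))
            ]
    return res


def summarize(values) -> tuple[float, float]:
    """(mean, SEM) with the sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"SEM needs at least 2 values, got {values.size}")
    return float(np.mean(values)), float(np.std(values, ddof=1) / np.sqrt(values.size))
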