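"""Risk-stratification and cohort-table statistics.

Survival machinery (Kaplan-Meier curves, log-rank comparison of score
quantiles) is delegated to ``lifelines``; ROC AUC uses the rank
(Mann-Whitney) formulation with ties counted one half; the cohort-table
helpers reproduce the statistics computable from printed group summaries
(Fisher exact tests on 2x2 counts, two-sample t-tests from (n, mean, SD),
and pooling of per-cohort summaries into a total row).
"""

from __future__ import annotations

import warnings
import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import GroupSummary

__all__ = [
    "assign_quantiles",
    "kaplan_meier",
    "logrank_test",
    "roc_auc",
    "pearson_corr",
    "fisher_exact_2x2",
    "ttest_from_summaries",
    "pool_group_summaries",
]


def assign_quantiles(scores, q: int = 4) -> np.ndarray:
    """Split samples into q near-equal risk groups by score rank.

    Group labels run 0 (lowest scores) to q-1 (highest); sizes differ by at
    most one.  Ties are broken by stable input order; a fully tied score
    vector still yields balanced groups, with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if q < 2:
        raise ValueError("q must be at least 2")
    n = scores.size
    if n < q:
        raise ValueError(f"cannot form {q} quantiles from {n} samples")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if np.unique(scores).size == 1:
        warnings.warn("all scores tied; quantile groups follow input order")
    order = np.argsort(scores, kind="stable")
    labels = np.empty(n, dtype=np.intp)
    bounds = np.linspace(0, n, q + 1).round().astype(int)
    for g in range(q):
        labels[order[bounds[g]:bounds[g + 1]]] = g
    return labels


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit survival estimate with right censoring.

    Returns a DataFrame of (time, survival) starting at (0, 1).  With no
    censoring the curve equals the empirical survival function.
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=bool)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(time, event_observed=event)
    sf = km.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank_test(time, event, group) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square, p) with k-1 df."""
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if np.unique(group).size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if not event.any():
        raise ValueError("log-rank test needs at least one event")
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


def roc_auc(scores, status) -> float:
    """AUC as the Mann-Whitney probability that a case outranks a control.

    Ties count one half; invariant to strictly monotone transforms of the
    scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    status = np.asarray(status)
    case = status == 1
    n1 = int(case.sum())
    n0 = int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both cases and controls")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r and two-sided t-based p on pairwise-complete observations."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("correlation undefined for constant input")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sided by summing the hypergeometric probabilities of all tables with
    probability not exceeding the observed one.  A zero margin makes every
    table equally (un)informative: p = 1 by convention, with a warning.
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def ttest_from_summaries(g1: GroupSummary, g2: GroupSummary,
                         variant: str = "welch") -> float:
    """Two-sided two-sample t-test from (n, mean, SD) summaries.

    ``variant``: ``"welch"`` (default, unequal variances) or ``"pooled"``.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n,
        equal_var=(variant == "pooled"),
    )
    return float(res.pvalue)


def pool_group_summaries(groups) -> GroupSummary:
    """Pool per-group (n, mean, SD) summaries into one overall summary.

    Pooled variance combines within-group sums of squares with the
    between-group spread of means:
    ``[sum (n_i - 1) s_i^2 + sum n_i (m_i - m)^2] / (sum n_i - 1)``.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("need at least one group")
    n_tot = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n_tot
    if n_tot < 2:
        return GroupSummary(n_tot, mean, 0.0)
    ss = sum((g.n - 1) * g.sd ** 2 for g in groups)
    ss += sum(g.n * (g.mean - mean) ** 2 for g in groups)
    return GroupSummary(n_tot, mean, math.sqrt(ss / (n_tot - 1)))
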