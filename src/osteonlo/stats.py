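"""Group-comparison statistics: Mann–Whitney U and two-sample t tests.

The Mann–Whitney U test uses an exact null distribution obtained by full
enumeration of rank assignments whenever the combined sample is small
(n_a + n_b <= 12), handling ties with mid-ranks; larger samples fall back
to the normal approximation with tie correction.  The exact two-sided p is
the null probability of a U at least as far from its mean n_a·n_b/2 as the
observed one, which reduces to tail doubling for the symmetric tie-free
null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "two_sample_t",
    "compare_groups",
    "EXACT_LIMIT",
]

#: largest combined sample size for which the exact null is enumerated
EXACT_LIMIT = 12


@dataclass
class GroupComparison:
    """Outcome of one two-group comparison of a scalar metric."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    test: str  # "mann_whitney_u" or "t_test"
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "metric": self.metric,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sem_a": self.sem_a,
            "sem_b": self.sem_b,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "degenerate": self.degenerate,
        }


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of group_a, p).

    Exact p by enumeration of all C(n, n_a) rank splits when
    n_a + n_b <= ``EXACT_LIMIT`` (ties mid-ranked); otherwise the normal
    approximation with tie correction (continuity-corrected).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_obs = _u_statistic(ranks[:n_a], n_a)
    if n <= EXACT_LIMIT:
        mu = n_a * n_b / 2.0
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), n_a):
            u = _u_statistic(ranks[list(idx)], n_a)
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def two_sample_t(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test; Student (pooled) or Welch per flag.

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    give (±inf, 0) — callers that need a flag use :func:`compare_groups`.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2 for a t test")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def compare_groups(
    metric: str,
    values_a,
    values_b,
    label_a: str = "WT",
    label_b: str = "KO",
    test: str = "mann_whitney_u",
    alpha: float = 0.1,
) -> GroupComparison:
    """Run one configured two-group test and package mean ± SEM summaries.

    Significance is declared for p < alpha (strict), alpha defaulting to
    0.1 as used for these bone phenotype comparisons.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    degenerate = False
    if test == "mann_whitney_u":
        stat, p = mann_whitney_u(a, b)
    elif test == "t_test":
        stat, p = two_sample_t(a, b)
        if not np.isfinite(stat):
            degenerate = True
    else:
        raise ParameterError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        group_a=label_a,
        group_b=label_b,
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=_sem(a),
        sem_b=_sem(b),
        test=test,
        statistic=stat,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
        degenerate=degenerate,
    )
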