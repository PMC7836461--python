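"""RECIST response statistics and two-stage phase II design
operating characteristics.

Includes best-change categorization, binomial response rates with Wald
confidence intervals, per-group rates, the 2x2 chi-squared association
test, and exact (binomial-enumeration) operating characteristics of a
two-stage single-arm design with an interim futility stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("gctrial")


@dataclass
class RateResult:
    """A response rate with its confidence interval, on the percent scale."""

    numerator: int
    denominator: int
    rate: float
    ci_low: float
    ci_high: float
    level: float

    def __str__(self) -> str:
        return (
            f"{self.rate:.1f}% ({self.numerator}/{self.denominator}; "
            f"{self.level:.0%} CI {self.ci_low:.1f}-{self.ci_high:.1f})"
        )


@dataclass
class TwoStageDesign:
    """A two-stage single-arm design with an interim futility stop.

    Stage 1 treats ``n1`` patients and stops for futility when responders
    <= ``r1``; otherwise accrual continues to ``n_total`` and the therapy
    is rejected when cumulative responders <= ``r_total``. ``p0``/``p1``
    are the uninteresting and target response probabilities.
    """

    n1: int
    r1: int
    n_total: int
    r_total: int
    p0: float
    p1: float

    def __post_init__(self) -> None:
        if not (0 <= self.r1 < self.n1 <= self.n_total):
            raise ValueError("need 0 <= r1 < n1 <= n_total")
        if not (0 <= self.r_total < self.n_total):
            raise ValueError("need 0 <= r_total < n_total")
        if not (0 < self.p0 < self.p1 < 1):
            raise ValueError("need 0 < p0 < p1 < 1")


def recist_category(
    best_change: float, pr_cut: float = -30.0, pd_cut: float = 20.0
) -> str:
    """Best-overall-response category from the best percent change of the
    target-lesion sum: -100 is CR, <= pr_cut PR, >= pd_cut PD, else SD."""
    if best_change < -100:
        raise ValueError("best change below -100% is impossible")
    if best_change == -100:
        return "CR"
    if best_change <= pr_cut:
        return "PR"
    if best_change >= pd_cut:
        return "PD"
    return "SD"


def orr_with_ci(responders: int, n: int, level: float = 0.95) -> RateResult:
    """Objective response rate with a Wald normal-approximation CI.

    The interval is clipped to [0, 100]; values are kept at full precision
    (round only for presentation).
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= responders <= n:
        raise ValueError("responders must be between 0 and n")
    p = responders / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return RateResult(
        numerator=responders,
        denominator=n,
        rate=100 * p,
        ci_low=float(np.clip(100 * (p - half), 0, 100)),
        ci_high=float(np.clip(100 * (p + half), 0, 100)),
        level=level,
    )


def rate_by_group(
    labels: list[str], responses: list[bool], level: float = 0.95
) -> dict[str, RateResult]:
    """One RateResult per group label; labels and flags must align."""
    if len(labels) != len(responses):
        raise ValueError("labels and responses have different lengths")
    out: dict[str, RateResult] = {}
    for group in sorted(set(labels)):
        flags = [r for g, r in zip(labels, responses) if g == group]
        if not flags:
            logger.warning("group %s has no samples; omitted", group)
            continue
        out[group] = orr_with_ci(sum(flags), len(flags), level)
    return out


def chi_squared_2x2(
    table: np.ndarray, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test of association in a 2x2 table.

    Returns (statistic, upper-tail p on 1 df); ``continuity=True`` applies
    the Yates correction. Both margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    diff = np.abs(t - expected)
    if continuity:
        diff = np.clip(diff - 0.5, 0, None)
    statistic = float((diff**2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


def fisher_exact_2x2(table: np.ndarray) -> tuple[float, float]:
    """Fisher's exact test (two-sided) for small cells."""
    res = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def two_stage_operating_characteristics(
    design: TwoStageDesign, p: float
) -> tuple[float, float, float]:
    """Exact operating characteristics at true response probability p.

    Returns (prob_accept_therapy, prob_early_stop, expected_sample_size),
    computed by summing binomial probabilities — the therapy is accepted
    iff stage-1 responders X1 > r1 and cumulative responders X1 + X2 >
    r_total with X1 ~ Bin(n1, p), X2 ~ Bin(n_total - n1, p). No normal
    approximation is used.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be a probability")
    n2 = design.n_total - design.n1
    x1 = np.arange(design.r1 + 1, design.n1 + 1)
    pmf1 = stats.binom.pmf(x1, design.n1, p)
    # accept needs X2 > r_total - x1, i.e. X2 >= r_total - x1 + 1
    tail2 = stats.binom.sf(design.r_total - x1, n2, p)
    prob_accept = float(np.sum(pmf1 * tail2))
    prob_early_stop = float(stats.binom.cdf(design.r1, design.n1, p))
    expected_n = design.n1 + (1 - prob_early_stop) * n2
    return prob_accept, prob_early_stop, float(expected_n)


def burden_strata(n_mutations: dict[str, int], cutoff: int = 100) -> dict[str, str]:
    """Split samples into high/low mutational-burden strata at ``cutoff``
    non-synonymous mutations (high means strictly greater)."""
    return {
        sid: ("high" if n > cutoff else "low") for sid, n in n_mutations.items()
    }
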