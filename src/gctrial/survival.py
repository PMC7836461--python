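"""Kaplan-Meier estimation, log-rank testing and Cox proportional-hazards
fitting.

The Cox model maximizes the Breslow-ties partial likelihood by damped
Newton-Raphson; it also serves as the unpenalized reference for the
penalized Cox fits of the integrative selector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SurvivalData:
    sample_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")


@dataclass
class KaplanMeierResult:
    """Product-limit estimate as a right-continuous step function."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # subjects at risk just before each event time
    n_events: np.ndarray   # events at each event time

    def evaluate(self, t: float) -> float:
        """S(t) for any t >= 0 (1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class CoxResult:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separation_flag: bool

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)


def _unpack(data: list[SurvivalData]) -> tuple[np.ndarray, np.ndarray]:
    time = np.array([d.time for d in data], dtype=float)
    event = np.array([d.event for d in data], dtype=bool)
    return time, event


def km_estimate(data: list[SurvivalData]) -> KaplanMeierResult:
    """Kaplan-Meier product-limit estimator.

    Censored subjects at a given time are considered at risk for events
    occurring at that same time (standard convention).
    """
    if not data:
        raise ValueError("empty survival data")
    time, event = _unpack(data)
    event_times = np.unique(time[event])
    at_risk = np.array([(time >= t).sum() for t in event_times])
    n_events = np.array([(event & (time == t)).sum() for t in event_times])
    survival = np.cumprod(1.0 - n_events / at_risk) if len(event_times) else np.array([])
    return KaplanMeierResult(event_times, survival, at_risk, n_events)


def logrank_test(
    group_a: list[SurvivalData], group_b: list[SurvivalData]
) -> tuple[float, float]:
    """Two-group log-rank test: chi-squared on 1 df from the summed
    observed-minus-expected events with hypergeometric variance."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _unpack(group_a)
    tb, eb = _unpack(group_b)
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    if not event.any():
        raise ValueError("no events in either group")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = (event & (time == t)).sum()
        d_a = (event & (time == t) & in_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    statistic = o_minus_e**2 / var
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def _breslow_loglik_grad_hess(
    beta: np.ndarray, time: np.ndarray, event: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], X[order]
    eta = x @ beta
    eta = eta - eta.max()  # overflow guard; cancels in all ratios
    r = np.exp(eta)
    n, p = x.shape
    # reverse cumulative sums over the risk set {j: t_j >= t_i}
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((r[:, None] * x)[::-1], axis=0)[::-1]
    s2 = np.cumsum((r[:, None, None] * x[:, :, None] * x[:, None, :])[::-1],
                   axis=0)[::-1]
    # risk-set sums must be taken at the first index of each tied-time group
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for i in np.flatnonzero(e):
        g = first[i]
        mean = s1[g] / s0[g]
        ll += eta[i] - np.log(s0[g])
        grad += x[i] - mean
        hess -= s2[g] / s0[g] - np.outer(mean, mean)
    return ll, grad, hess


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Cox proportional-hazards fit (Breslow ties) by damped Newton-Raphson.

    Converges when the gradient's infinity norm drops below ``tol``.
    Zero-variance covariates receive a zero coefficient. A monotone
    coefficient blow-up (|beta| > 50 on a standardized-scale covariate)
    is flagged as likely complete separation.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values")
    if not event.any():
        raise ValueError("no events observed")
    n, p = X.shape
    varying = X.std(axis=0) > 0
    beta = np.zeros(p)
    Xv = X[:, varying]
    if Xv.shape[1] == 0:
        ll, _, _ = _breslow_loglik_grad_hess(beta[varying], time, event, Xv)
        return CoxResult(beta, np.zeros(p), float(ll), 0, True, False)
    b = np.zeros(Xv.shape[1])
    ll, grad, hess = _breslow_loglik_grad_hess(b, time, event, Xv)
    n_iter = 0
    converged = False
    # the gradient is a sum over events, so the attainable precision
    # scales with the number of events
    tol_eff = tol * max(1.0, float(event.sum()))
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol_eff:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped update: halve until the partial likelihood improves
        scale = 1.0
        for _ in range(30):
            b_new = b - scale * step
            ll_new, grad_new, hess_new = _breslow_loglik_grad_hess(
                b_new, time, event, Xv
            )
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        b, ll, grad, hess = b_new, ll_new, grad_new, hess_new
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(|grad| = {np.max(np.abs(grad)):.3g})"
        )
    separation = bool(np.max(np.abs(b)) > 50)
    se_v = np.sqrt(np.clip(np.diag(np.linalg.pinv(-hess)), 0, None))
    beta = np.zeros(p)
    se = np.zeros(p)
    beta[varying] = b
    se[varying] = se_v
    return CoxResult(beta, se, float(ll), n_iter, converged, separation)


def breslow_partial_loglik(
    beta: np.ndarray, time: np.ndarray, event: np.ndarray, X: np.ndarray
) -> float:
    """The Breslow-ties partial log-likelihood at ``beta`` (exposed for
    cross-checks and cross-validated penalized fits)."""
    time = np.asarray(time, float)
    Xm = np.asarray(X, float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    if Xm.shape[0] != len(time):
        Xm = Xm.T
    ll, _, _ = _breslow_loglik_grad_hess(
        np.asarray(beta, float), time, np.asarray(event, bool), Xm
    )
    return float(ll)


def dichotomize(scores: dict[str, float], quantile: float = 0.5) -> dict[str, bool]:
    """High/low split of a per-sample score at a cohort quantile
    (median by default). True = high."""
    values = np.array(list(scores.values()), dtype=float)
    cut = np.quantile(values, quantile)
    return {s: bool(v > cut) for s, v in scores.items()}
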