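"""Elastic-net stability selection over combined molecular + clinical
features.

The selector repeatedly subsamples the cohort (80% without replacement,
100 draws by default), fits an elastic net of the combined feature table
against a clinical endpoint — linear for tumor reduction, penalized Cox
for survival endpoints — and ranks features by how often they receive a
nonzero coefficient, reporting the appearance count and the average
coefficient over the iterations in which each feature was selected.

The elastic net minimizes

    (1/2n) * sum_i (y_i - b0 - x_i b)^2  +  lam * (alpha*||b||_1
                                                   + (1-alpha)/2*||b||_2^2)

by cyclic coordinate descent with soft-thresholding; the Cox variant
maximizes the penalized Breslow partial likelihood via iteratively
reweighted least squares with the same inner loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalRecord, CopyNumberProfile, ExpressionMatrix
from .subtypes import aneuploidy_score
from .survival import _breslow_loglik_grad_hess, breslow_partial_loglik

logger = logging.getLogger("gctrial")

ENDPOINTS = ("tumor_reduction", "os", "pfs")


@dataclass
class ElasticNetConfig:
    """Penalty configuration.

    ``alpha`` mixes L1 (1 = lasso) with L2. ``lam`` is either a fixed
    penalty strength, "cv" for 5-fold cross-validation (one-standard-error
    rule), or "model_size" to tune the penalty so a full-cohort fit keeps
    about ``target_model_size`` features — the conventional calibration
    for stability selection, which needs per-fit model sizes controlled
    rather than prediction error minimized.
    """

    alpha: float = 0.5
    lam: float | str = "model_size"
    cv_folds: int = 5
    max_iter: int = 5000
    tol: float = 1e-6
    n_lambdas: int = 25
    lambda_min_ratio: float = 0.01  # n < p regime: do not descend to near-OLS
    target_model_size: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if isinstance(self.lam, str):
            if self.lam not in ("cv", "model_size"):
                raise ValueError("lam must be a number, 'cv' or 'model_size'")
        elif not np.isreal(self.lam) or self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass
class FeatureTable:
    """Standardized samples x features design matrix with provenance.

    Feature names carry a layer prefix (``expr:``, ``mut:``, ``cnv:``,
    ``clin:``); ``means``/``sds`` record the standardization applied.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")

    def subset(self, row_idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            [self.sample_ids[i] for i in row_idx],
            list(self.feature_names),
            self.values[row_idx],
            self.means,
            self.sds,
        )


@dataclass
class StabilityResult:
    """Per-feature selection frequency and averaged coefficient."""

    endpoint: str
    table: pd.DataFrame  # feature, appearance_count, mean_weight, ever_selected
    n_boot: int
    lam: float
    alpha: float


def build_feature_table(
    expression: ExpressionMatrix,
    mutations: pd.DataFrame,
    profiles: list[CopyNumberProfile],
    clinical: list[ClinicalRecord],
    top_var_genes: int = 2000,
    min_recurrent: int = 3,
) -> FeatureTable:
    """Assemble the combined design matrix.

    Expression features are the ``top_var_genes`` most variable genes of
    the normalized matrix; mutation features are 0/1 indicators for genes
    somatically mutated in at least ``min_recurrent`` samples; copy number
    contributes the fraction of genome altered; clinical features are the
    EBV and HER2 assay indicators. Constant columns are dropped and all
    features standardized to mean 0, sd 1.
    """
    sample_ids = [r.sample_id for r in clinical]
    missing = set(sample_ids) - set(expression.sample_ids)
    if missing:
        raise ValueError(f"samples missing from expression matrix: {sorted(missing)[:3]}")
    col_idx = [expression.sample_ids.index(s) for s in sample_ids]

    variances = expression.values[:, col_idx].var(axis=1)
    order = np.argsort(-variances, kind="stable")[:top_var_genes]
    names: list[str] = [f"expr:{expression.gene_ids[i]}" for i in order]
    blocks: list[np.ndarray] = [expression.values[np.ix_(order, col_idx)].T]

    counts = mutations.groupby("gene")["sample_id"].nunique()
    recurrent = sorted(counts.index[counts >= min_recurrent])
    mutated = {
        g: set(mutations.loc[mutations["gene"] == g, "sample_id"])
        for g in recurrent
    }
    if recurrent:
        names += [f"mut:{g}" for g in recurrent]
        blocks.append(
            np.array(
                [[float(s in mutated[g]) for g in recurrent] for s in sample_ids]
            )
        )

    prof_by_id = {p.sample_id: p for p in profiles}
    names.append("cnv:fraction_genome_altered")
    blocks.append(
        np.array([[aneuploidy_score(prof_by_id[s])] for s in sample_ids])
    )

    names += ["clin:ebv_positive", "clin:her2_positive"]
    blocks.append(
        np.array(
            [
                [float(r.ebv_status == "positive"), float(r.her2_status == "positive")]
                for r in clinical
            ]
        )
    )

    values = np.hstack(blocks)
    sds = values.std(axis=0)
    keep = sds > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.info("dropping %d constant features", len(dropped))
    values = values[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    means = values.mean(axis=0)
    sds = values.std(axis=0)
    values = (values - means) / sds
    return FeatureTable(sample_ids, names, values, means, sds)


# ---------------------------------------------------------------------------
# coordinate descent
# ---------------------------------------------------------------------------


def _soft(z: float, thresh: float) -> float:
    return math.copysign(max(abs(z) - thresh, 0.0), z)


def _cd_weighted(
    X: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    alpha: float,
    lam: float,
    beta0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent on a weighted penalized least squares:

        (1/2n) sum w_i (z_i - x_i b)^2 + lam*(alpha*||b||_1
                                              + (1-alpha)/2*||b||_2^2)

    Returns (beta, n_sweeps). ``beta0`` is the warm start.
    """
    n, p = X.shape
    beta = beta0.copy()
    wx = w[:, None] * X
    col_sq = (wx * X).sum(axis=0) / n
    denom = col_sq + lam * (1 - alpha)
    thresh = lam * alpha
    resid = z - X @ beta

    def sweep_over(indices: np.ndarray) -> float:
        max_delta = 0.0
        for j in indices:
            bj = beta[j]
            # rho = (1/n) sum_i w_i x_ij (resid_i + x_ij b_j); the partial
            # residual is never materialized
            rho = (wx[:, j] @ resid) / n + col_sq[j] * bj
            new = _soft(rho, thresh) / denom[j]
            if new != bj:
                resid[:] += X[:, j] * (bj - new)
                delta = abs(new - bj)
                if delta > max_delta:
                    max_delta = delta
                beta[j] = new
        return max_delta

    all_idx = np.arange(p)
    total = 0
    while total < max_iter:
        # full sweep establishes the active set
        total += 1
        full_delta = sweep_over(all_idx)
        active = np.flatnonzero(beta)
        # iterate on the active set only until it stabilizes
        while total < max_iter:
            total += 1
            if sweep_over(active) < tol:
                break
        if full_delta < tol:
            return beta, total
    raise RuntimeError(
        f"coordinate descent did not converge in {max_iter} sweeps"
    )


def elasticnet_objective(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float,
    alpha: float, lam: float,
) -> float:
    n = len(y)
    resid = y - intercept - X @ beta
    return float(
        resid @ resid / (2 * n)
        + lam * (alpha * np.abs(beta).sum() + (1 - alpha) / 2 * beta @ beta)
    )


def elasticnet_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lam: float = 0.1,
    max_iter: int = 5000,
    tol: float = 1e-6,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Linear elastic net by cyclic coordinate descent.

    ``X`` should be standardized (the stability selector guarantees
    this); the intercept is profiled out by centering ``y`` and centering
    each column of ``X``. Returns (beta, intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    xbar = X.mean(axis=0)
    Xc = X - xbar
    ybar = y.mean()
    beta0 = np.zeros(p) if beta0 is None else beta0
    beta, _ = _cd_weighted(
        Xc, y - ybar, np.ones(n), alpha, lam, beta0, max_iter, tol
    )
    intercept = float(ybar - xbar @ beta)
    return beta, intercept


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which every coefficient is zero (lasso side)."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    lmax = float(np.max(np.abs(Xc.T @ (y - y.mean()))) / n)
    return lmax / max(alpha, 1e-3)


def _lambda_path(lmax: float, n_lambdas: int, min_ratio: float) -> np.ndarray:
    return lmax * np.logspace(0, np.log10(min_ratio), n_lambdas)


def _one_se_rule(path: np.ndarray, fold_losses: np.ndarray) -> float:
    """Largest penalty whose mean CV loss is within one standard error of
    the minimum (the conventional sparser choice for selection tasks)."""
    mean = fold_losses.mean(axis=0)
    k = fold_losses.shape[0]
    se = fold_losses.std(axis=0, ddof=1) / np.sqrt(k) if k > 1 else np.zeros_like(mean)
    best = int(np.argmin(mean))
    within = np.flatnonzero(mean <= mean[best] + se[best])
    return float(path[int(within.min())])  # path is descending in lam


def cv_lambda_linear(
    X: np.ndarray, y: np.ndarray, cfg: ElasticNetConfig, seed: int = 0
) -> float:
    """Pick lam by K-fold cross-validated mean squared error with the
    one-standard-error rule."""
    n = len(y)
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % cfg.cv_folds
    path = _lambda_path(lambda_max(X, y, cfg.alpha), cfg.n_lambdas,
                        cfg.lambda_min_ratio)
    losses = np.zeros((cfg.cv_folds, len(path)))
    for k in range(cfg.cv_folds):
        train, test = folds != k, folds == k
        if test.sum() == 0 or train.sum() < 3:
            continue
        beta0 = np.zeros(X.shape[1])
        for i, lam in enumerate(path):
            beta0, icept = elasticnet_fit(
                X[train], y[train], cfg.alpha, lam,
                cfg.max_iter, cfg.tol, beta0=beta0,
            )
            pred = icept + X[test] @ beta0
            losses[k, i] = float(((y[test] - pred) ** 2).mean())
    return _one_se_rule(path, losses)


def lambda_for_model_size(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ElasticNetConfig,
    event: np.ndarray | None = None,
    target: int | None = None,
) -> float:
    """Walk the penalty path downward (warm-started) and return the first
    penalty at which the full-data fit keeps >= ``target`` features."""
    target = cfg.target_model_size if target is None else target
    if event is None:
        lmax = lambda_max(X, y, cfg.alpha)
    else:
        w0, z0 = _cox_irls_working(np.zeros(len(y)), np.asarray(y, float),
                                   np.asarray(event, bool))
        lmax = float(
            np.max(np.abs(X.T @ (w0 * (z0 - np.average(z0, weights=w0))))) / len(y)
        ) / max(cfg.alpha, 1e-3)
    path = _lambda_path(lmax, 2 * cfg.n_lambdas, cfg.lambda_min_ratio)
    beta = np.zeros(X.shape[1])
    for lam in path:
        if event is None:
            beta, _ = elasticnet_fit(X, y, cfg.alpha, lam, cfg.max_iter,
                                     cfg.tol, beta0=beta)
        else:
            beta = cox_elasticnet_fit(X, y, event, cfg.alpha, lam,
                                      cfg.max_iter, cfg.tol)
        if int((np.abs(beta) > 1e-10).sum()) >= target:
            return float(lam)
    return float(path[-1])


# ---------------------------------------------------------------------------
# penalized Cox
# ---------------------------------------------------------------------------


def _cox_irls_working(
    eta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Working weights/response for the Breslow partial likelihood.

    w_i = mu_i (the diagonal Hessian approximation) and
    z_i = eta_i + (d_i - mu_i)/w_i, where mu_i is the expected number of
    events for subject i under the current linear predictor.
    """
    order = np.argsort(time, kind="stable")
    r = np.exp(eta - eta.max())
    s0 = np.zeros(len(time))
    # cumulative hazard increments d_k / S0(t_k) at each event time
    t_sorted = time[order]
    r_sorted = r[order]
    rev = np.cumsum(r_sorted[::-1])[::-1]
    first = np.zeros(len(time), dtype=int)
    for i in range(1, len(time)):
        first[i] = first[i - 1] if t_sorted[i] == t_sorted[i - 1] else i
    event_times = {}
    for i in np.flatnonzero(event[order]):
        t = t_sorted[i]
        event_times[t] = event_times.get(t, 0.0) + 1.0 / rev[first[i]]
    times_arr = np.array(sorted(event_times))
    increments = np.array([event_times[t] for t in times_arr])
    cum = np.cumsum(increments)
    idx = np.searchsorted(times_arr, time, side="right")
    chaz = np.where(idx > 0, cum[np.clip(idx - 1, 0, None)], 0.0)
    mu = r * chaz
    w = np.clip(mu, 1e-10, None)
    z = eta + (event.astype(float) - mu) / w
    return w, z


def cox_elasticnet_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float = 0.5,
    lam: float = 0.1,
    max_iter: int = 5000,
    tol: float = 1e-6,
    max_outer: int = 200,
) -> np.ndarray:
    """Elastic-net-penalized Cox regression (Breslow ties).

    Outer loop: IRLS re-linearization of the partial likelihood; inner
    loop: the same weighted coordinate descent as the linear fit. At
    lam=0 the fixed point solves the unpenalized score equations, so the
    result matches the Newton-Raphson Cox fit.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not event.any():
        raise ValueError("no events observed")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    for _ in range(max_outer):
        w, z = _cox_irls_working(eta, time, event)
        beta_new, _ = _cd_weighted(X, z, w, alpha, lam, beta, max_iter, tol)
        eta_new = X @ beta_new
        delta = np.max(np.abs(beta_new - beta))
        beta, eta = beta_new, eta_new
        if delta < max(tol, 1e-9):
            return beta
    raise RuntimeError(f"penalized Cox IRLS did not converge in {max_outer} rounds")


def cv_lambda_cox(
    X: np.ndarray, time: np.ndarray, event: np.ndarray,
    cfg: ElasticNetConfig, seed: int = 0,
) -> float:
    """Pick lam by cross-validated partial likelihood (the
    Verweij-van Houwelingen difference criterion)."""
    n = len(time)
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % cfg.cv_folds
    # path anchored at the null-model working response
    w0, z0 = _cox_irls_working(np.zeros(n), np.asarray(time, float),
                               np.asarray(event, bool))
    lmax = float(np.max(np.abs(X.T @ (w0 * (z0 - np.average(z0, weights=w0))))) / n)
    path = _lambda_path(lmax / max(cfg.alpha, 1e-3), cfg.n_lambdas,
                        cfg.lambda_min_ratio)
    losses = np.zeros((cfg.cv_folds, len(path)))
    for k in range(cfg.cv_folds):
        train = folds != k
        if event[train].sum() == 0:
            continue
        for i, lam in enumerate(path):
            try:
                beta = cox_elasticnet_fit(
                    X[train], time[train], event[train], cfg.alpha, lam,
                    cfg.max_iter, cfg.tol,
                )
            except RuntimeError:
                losses[k, i] = np.inf
                continue
            ll_all = breslow_partial_loglik(beta, time, event, X)
            ll_train = breslow_partial_loglik(
                beta, time[train], event[train], X[train]
            )
            losses[k, i] = -(ll_all - ll_train)
    return _one_se_rule(path, losses)


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------


def _endpoint_arrays(
    clinical: list[ClinicalRecord], endpoint: str
) -> tuple[np.ndarray, np.ndarray | None]:
    if endpoint == "tumor_reduction":
        return np.array([r.tumor_reduction for r in clinical]), None
    if endpoint == "os":
        return (np.array([r.os_months for r in clinical]),
                np.array([r.os_event for r in clinical], dtype=bool))
    if endpoint == "pfs":
        return (np.array([r.pfs_months for r in clinical]),
                np.array([r.pfs_event for r in clinical], dtype=bool))
    raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")


def stability_select(
    features: FeatureTable,
    clinical: list[ClinicalRecord],
    endpoint: str,
    cfg: ElasticNetConfig | None = None,
    n_boot: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    with_replacement: bool = False,
) -> StabilityResult:
    """Resampled elastic-net feature selection against one endpoint.

    For each of ``n_boot`` iterations a random ``subsample_fraction`` of
    the cohort is drawn (without replacement by default) and an elastic
    net fitted; the penalty is chosen once on the full cohort by
    cross-validation (when ``cfg.lam == "cv"``) and held fixed so that
    appearance counts are comparable across iterations. Survival
    endpoints use the penalized Cox variant. Deterministic given ``seed``.
    """
    cfg = cfg or ElasticNetConfig()
    by_id = {r.sample_id: r for r in clinical}
    clinical = [by_id[s] for s in features.sample_ids]
    y, ev = _endpoint_arrays(clinical, endpoint)
    X = features.values
    n = X.shape[0]
    n_sub = math.ceil(subsample_fraction * n)
    if n_sub < 3:
        raise ValueError("subsample too small to fit")

    if cfg.lam == "cv":
        if ev is None:
            lam = cv_lambda_linear(X, y, cfg, seed=seed)
        else:
            lam = cv_lambda_cox(X, y, ev, cfg, seed=seed)
    elif cfg.lam == "model_size":
        lam = lambda_for_model_size(X, y, cfg, event=ev)
    else:
        lam = float(cfg.lam)
    logger.info("stability_select(%s): lam=%.5g alpha=%.2f", endpoint, lam, cfg.alpha)

    rng = np.random.default_rng(seed)
    p = X.shape[1]
    counts = np.zeros(p, dtype=int)
    weight_sums = np.zeros(p)
    for _ in range(n_boot):
        idx = rng.choice(n, size=n_sub, replace=with_replacement)
        if ev is None:
            beta, _ = elasticnet_fit(
                X[idx], y[idx], cfg.alpha, lam, cfg.max_iter, cfg.tol
            )
        else:
            if ev[idx].sum() == 0:
                continue
            beta = cox_elasticnet_fit(
                X[idx], y[idx], ev[idx], cfg.alpha, lam, cfg.max_iter, cfg.tol
            )
        nonzero = np.abs(beta) > 1e-10
        counts += nonzero
        weight_sums[nonzero] += beta[nonzero]
    ever = counts > 0
    mean_weight = np.where(ever, weight_sums / np.maximum(counts, 1), 0.0)
    table = pd.DataFrame(
        {
            "feature": features.feature_names,
            "appearance_count": counts,
            "mean_weight": mean_weight,
            "ever_selected": ever,
        }
    )
    # rank by how reliably a feature is selected, ties broken by effect size
    table = (
        table.assign(_absw=np.abs(table["mean_weight"]))
        .sort_values(
            ["appearance_count", "_absw", "feature"],
            ascending=[False, False, True], kind="stable",
        )
        .drop(columns="_absw")
        .reset_index(drop=True)
    )
    return StabilityResult(endpoint, table, n_boot, lam, cfg.alpha)
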