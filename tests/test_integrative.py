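"""Elastic-net coordinate descent, penalized Cox, and stability selection."""

import numpy as np
import pytest
from scipy.optimize import minimize

import gctrial as g
from gctrial.integrative import (ElasticNetConfig, build_feature_table,
                                 cox_elasticnet_fit, cv_lambda_linear,
                                 elasticnet_fit, elasticnet_objective,
                                 lambda_max, stability_select)
from gctrial.survival import cox_fit


def standardized(rng, n, p):
    X = rng.normal(size=(n, p))
    return (X - X.mean(0)) / X.std(0)


# ---------------------------------------------------------------------------
# linear elastic net
# ---------------------------------------------------------------------------


def test_full_shrinkage_above_lambda_max():
    rng = np.random.default_rng(0)
    X = standardized(rng, 50, 8)
    y = X @ rng.normal(size=8) + rng.normal(size=50)
    lmax = lambda_max(X, y, alpha=1.0)
    beta, icept = elasticnet_fit(X, y, alpha=1.0, lam=lmax * 1.0001)
    assert not beta.any()
    assert icept == pytest.approx(y.mean())
    # just below lambda_max something enters
    beta, _ = elasticnet_fit(X, y, alpha=1.0, lam=lmax * 0.95)
    assert beta.any()


def test_soft_threshold_closed_form_on_orthonormal_design():
    """With X'X/n = I and alpha = 1, each lasso coefficient equals
    soft(beta_OLS, lam)."""
    rng = np.random.default_rng(1)
    n, p = 64, 4
    # QR against an explicit intercept column gives centered columns that
    # stay orthonormal in the 1/n inner product
    A = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    Q, _ = np.linalg.qr(A)
    X = Q[:, 1:] * np.sqrt(n)
    beta_true = np.array([1.0, -0.6, 0.25, 0.0])
    y = X @ beta_true
    beta_ols = X.T @ y / n
    for lam in (0.05, 0.3, 0.7):
        beta, _ = elasticnet_fit(X, y, alpha=1.0, lam=lam, tol=1e-12)
        expected = np.sign(beta_ols) * np.clip(np.abs(beta_ols) - lam, 0, None)
        assert beta == pytest.approx(expected, abs=1e-8)


@pytest.mark.parametrize("alpha,lam", [(1.0, 0.15), (0.5, 0.2), (0.2, 0.4)])
def test_correlated_design_matches_convex_minimization_oracle(alpha, lam):
    """5 correlated features: the coordinate-descent objective matches an
    independent split-variable convex solver to 1e-8."""
    rng = np.random.default_rng(2)
    n, p = 40, 5
    base = rng.normal(size=(n, 1))
    X = base + 0.6 * rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = X @ np.array([1.0, -0.5, 0.0, 0.3, 0.0]) + rng.normal(0, 0.4, n)
    beta, icept = elasticnet_fit(X, y, alpha=alpha, lam=lam, tol=1e-13)
    mine = elasticnet_objective(X, y, beta, icept, alpha, lam)

    yc = y - y.mean()

    def objective(z):
        bp, bm = z[:p], z[p:]
        b = bp - bm
        r = yc - X @ b
        return (
            r @ r / (2 * n)
            + lam * (alpha * (bp.sum() + bm.sum()) + (1 - alpha) / 2 * b @ b)
        )

    res = minimize(
        objective, np.zeros(2 * p), method="SLSQP",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert mine <= res.fun + 1e-8


def test_sign_flip_of_feature_flips_coefficient():
    rng = np.random.default_rng(3)
    X = standardized(rng, 60, 6)
    y = X @ rng.normal(size=6) + rng.normal(size=60)
    beta, _ = elasticnet_fit(X, y, alpha=0.5, lam=0.1, tol=1e-12)
    X2 = X.copy()
    X2[:, 2] *= -1
    beta2, _ = elasticnet_fit(X2, y, alpha=0.5, lam=0.1, tol=1e-12)
    expected = beta.copy()
    expected[2] *= -1
    assert beta2 == pytest.approx(expected, abs=1e-9)


def test_elasticnet_rejects_bad_inputs():
    with pytest.raises(ValueError, match="non-finite"):
        elasticnet_fit(np.array([[np.nan], [1.0], [2.0]]), np.ones(3))
    with pytest.raises(ValueError, match="3 samples"):
        elasticnet_fit(np.ones((2, 1)), np.ones(2))
    with pytest.raises(ValueError):
        ElasticNetConfig(alpha=1.5)
    with pytest.raises(ValueError):
        ElasticNetConfig(lam=-1.0)


def test_cv_lambda_is_deterministic_given_seed():
    rng = np.random.default_rng(4)
    X = standardized(rng, 40, 10)
    y = X[:, 0] + rng.normal(size=40)
    cfg = ElasticNetConfig()
    assert cv_lambda_linear(X, y, cfg, seed=9) == cv_lambda_linear(X, y, cfg, seed=9)


# ---------------------------------------------------------------------------
# penalized Cox
# ---------------------------------------------------------------------------


def _cox_data(seed=5, n=90, p=4, beta=(0.7, -0.5, 0.0, 0.0)):
    rng = np.random.default_rng(seed)
    X = standardized(rng, n, p)
    t = rng.exponential(5, n) / np.exp(X @ np.asarray(beta))
    e = rng.random(n) < 0.8
    return X, t, e


def test_cox_elasticnet_huge_lambda_zeroes_everything():
    X, t, e = _cox_data()
    beta = cox_elasticnet_fit(X, t, e, alpha=0.5, lam=1e4)
    assert not beta.any()


def test_cox_elasticnet_unpenalized_matches_newton_cox():
    X, t, e = _cox_data()
    beta = cox_elasticnet_fit(X, t, e, alpha=0.5, lam=0.0, tol=1e-10)
    fit = cox_fit(t, e, X)
    assert beta == pytest.approx(fit.coef, abs=1e-6)


def test_cox_elasticnet_planted_feature_dominates_at_moderate_penalty():
    """The feature with planted HR 2.5 carries the largest coefficient."""
    X, t, e = _cox_data(seed=6, n=200, p=10,
                        beta=(np.log(2.5),) + (0.0,) * 9)
    beta = cox_elasticnet_fit(X, t, e, alpha=0.5, lam=0.05)
    assert int(np.argmax(np.abs(beta))) == 0
    assert beta[0] > 0


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------


def _records_for(y, sample_ids):
    return [
        g.ClinicalRecord(
            sample_id=s, age=60.0, sex="F", response_category="SD",
            tumor_reduction=float(v), pfs_months=1.0, pfs_event=True,
            os_months=2.0, os_event=True, ebv_status="negative",
            msi_status="MSS", her2_status="negative", biopsy_site="stomach",
        )
        for s, v in zip(sample_ids, y)
    ]


def _feature_table(X, sample_ids):
    from gctrial.integrative import FeatureTable
    return FeatureTable(
        sample_ids, [f"f{j}" for j in range(X.shape[1])], X,
        np.zeros(X.shape[1]), np.ones(X.shape[1]),
    )


def test_stability_select_deterministic_given_seed():
    rng = np.random.default_rng(7)
    X = standardized(rng, 40, 12)
    y = X[:, 0] + rng.normal(0, 0.5, 40)
    ids = [f"S{i}" for i in range(40)]
    feats = _feature_table(X, ids)
    records = _records_for(y, ids)
    a = stability_select(feats, records, "tumor_reduction", n_boot=20, seed=3)
    b = stability_select(feats, records, "tumor_reduction", n_boot=20, seed=3)
    assert a.table.equals(b.table)
    assert a.lam == b.lam


def test_strong_predictor_selected_in_nearly_every_subsample():
    """Standardized effect 1.0 among 50 noise features at n=100: the true
    predictor appears in >= 90 of 100 subsamples."""
    rng = np.random.default_rng(8)
    X = standardized(rng, 100, 51)
    y = 1.0 * X[:, 0] + rng.normal(0, 1.0, 100)
    ids = [f"S{i}" for i in range(100)]
    res = stability_select(
        _feature_table(X, ids), _records_for(y, ids), "tumor_reduction",
        cfg=ElasticNetConfig(lam="cv"), seed=1,
    )
    row = res.table.set_index("feature").loc["f0"]
    assert row["appearance_count"] >= 90
    assert res.table.iloc[0]["feature"] == "f0"


def test_pure_noise_features_rarely_selected_under_null():
    rng = np.random.default_rng(9)
    X = standardized(rng, 60, 30)
    y = rng.normal(size=60)  # endpoint unrelated to any feature
    ids = [f"S{i}" for i in range(60)]
    res = stability_select(
        _feature_table(X, ids), _records_for(y, ids), "tumor_reduction",
        cfg=ElasticNetConfig(lam="cv"), seed=2,
    )
    assert res.table["appearance_count"].median() <= 20
    weights = res.table.loc[res.table["ever_selected"], "mean_weight"]
    if len(weights):
        assert abs(weights.mean()) < 0.5


def test_survival_endpoint_uses_cox_variant(default_cohort, default_normalized):
    feats = build_feature_table(
        default_normalized, default_cohort.variants, default_cohort.copy_number,
        default_cohort.clinical, top_var_genes=20, min_recurrent=5,
    )
    res = stability_select(
        feats, default_cohort.clinical, "os",
        n_boot=10, seed=4, cfg=ElasticNetConfig(lam=0.1),
    )
    assert res.endpoint == "os"
    assert res.n_boot == 10
    assert (res.table["appearance_count"] <= 10).all()


def test_feature_table_layers_and_standardization(default_cohort, default_normalized):
    feats = build_feature_table(
        default_normalized, default_cohort.variants, default_cohort.copy_number,
        default_cohort.clinical, top_var_genes=30, min_recurrent=4,
    )
    prefixes = {n.split(":")[0] for n in feats.feature_names}
    assert prefixes == {"expr", "mut", "cnv", "clin"}
    assert np.allclose(feats.values.mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(feats.values.std(axis=0), 1.0, atol=1e-10)
    assert "mut:GNAQ" in feats.feature_names
    assert "clin:ebv_positive" in feats.feature_names


def test_unknown_endpoint_rejected(default_cohort, default_normalized):
    feats = build_feature_table(
        default_normalized, default_cohort.variants, default_cohort.copy_number,
        default_cohort.clinical, top_var_genes=5, min_recurrent=6,
    )
    with pytest.raises(ValueError, match="endpoint"):
        stability_select(feats, default_cohort.clinical, "orr")
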