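"""Normalization, signature scoring, ssGSEA and differential expression."""

import itertools

import numpy as np
import pytest
from scipy import stats

import gctrial as g
from gctrial.expression import (EmptySignatureError, quantile_normalize,
                                volcano_classes, _ssgsea_sample)
from gctrial.io import ExpressionMatrix


def make_matrix(values, state="log10_quantile_normalized"):
    values = np.asarray(values, dtype=float)
    genes = [f"G{i}" for i in range(values.shape[0])]
    samples = [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, state=state)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def test_quantile_normalization_hand_computed_toy():
    """3 genes x 2 samples: each column is replaced by the mean of the
    column-sorted vectors at its ranks."""
    raw = np.array([[1.0, 8.0], [3.0, 2.0], [5.0, 4.0]])
    # sorted columns: [1,3,5] and [2,4,8] -> reference [1.5, 3.5, 6.5]
    expected = np.array([[1.5, 6.5], [3.5, 1.5], [6.5, 3.5]])
    assert np.allclose(quantile_normalize(raw), expected)


def test_quantile_normalization_sorted_columns_identical():
    """Definitional property: after normalization every sample's sorted
    value vector equals the reference exactly (tie-free input)."""
    rng = np.random.default_rng(0)
    raw = rng.lognormal(1.0, 1.0, size=(200, 7))
    m = g.normalize_expression(ExpressionMatrix(
        [f"G{i}" for i in range(200)], [f"S{j}" for j in range(7)], raw))
    cols = np.sort(m.values, axis=0)
    for j in range(1, 7):
        assert np.array_equal(cols[:, j], cols[:, 0])


def test_quantile_normalization_tied_values_get_mean_reference():
    raw = np.array([[1.0, 5.0], [1.0, 2.0], [4.0, 3.0]])
    out = quantile_normalize(raw)
    # column 0 has a tie at rank 1-2: both receive mean(ref[0], ref[1])
    ref = np.sort(raw, axis=0).mean(axis=1)
    assert out[0, 0] == out[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)


def test_columns_that_are_permutations_map_to_log_of_each_other():
    raw = np.array([[1.0, 4.0], [4.0, 9.0], [9.0, 1.0]])
    m = g.normalize_expression(make_matrix(raw, state="raw_fpkm"), pseudocount=1.0)
    # both columns share the same value multiset, so normalization equals
    # the plain log transform
    assert np.allclose(np.sort(m.values, axis=0),
                       np.log10(np.sort(raw, axis=0) + 1.0))


def test_normalize_rejects_wrong_state_and_negatives():
    with pytest.raises(ValueError, match="state"):
        g.normalize_expression(make_matrix(np.ones((2, 2))))
    ok = make_matrix(np.ones((2, 2)), state="raw_fpkm")
    ok.values[0, 0] = -1.0
    with pytest.raises(ValueError, match="nonnegative"):
        g.normalize_expression(ok)


# ---------------------------------------------------------------------------
# signature scores
# ---------------------------------------------------------------------------


def test_score_signature_mean_and_single_gene():
    m = make_matrix([[1.0, 2.0], [3.0, 0.0], [10.0, 10.0]])
    one = g.GeneSignature("one", frozenset({"G0"}))
    assert g.score_signature(m, one).tolist() == [1.0, 2.0]
    two = g.GeneSignature("two", frozenset({"G0", "G1"}))
    assert g.score_signature(m, two).tolist() == [2.0, 1.0]


def test_score_signature_matches_brute_force_mean():
    rng = np.random.default_rng(1)
    m = make_matrix(rng.normal(size=(30, 4)))
    genes = frozenset(rng.choice(m.gene_ids, size=9, replace=False))
    scores = g.score_signature(m, g.GeneSignature("r", genes))
    rows = [m.gene_ids.index(gene) for gene in genes]
    assert np.allclose(scores.to_numpy(), m.values[rows].mean(axis=0))


def test_score_signature_requires_half_the_genes_present():
    m = make_matrix(np.ones((3, 2)))
    sig = g.GeneSignature("s", frozenset({"G0", "X1", "X2", "X3"}))
    with pytest.raises(ValueError, match="present"):
        g.score_signature(m, sig)
    with pytest.raises(ValueError, match="no genes"):
        g.score_signature(m, g.GeneSignature("s", frozenset({"X1"})))


def test_score_geometric_log10_arithmetic():
    m = make_matrix([[10.0, 100.0], [1000.0, 1.0]], state="raw_fpkm")
    sig = g.GeneSignature("s", frozenset({"G0", "G1"}))
    # log10 of (10, 1000) -> (1, 3) -> mean 2; (100, 1) -> (2, 0) -> 1
    assert g.score_geometric(m, sig, pseudocount=0.0).tolist() == [2.0, 1.0]


def test_score_geometric_equals_arithmetic_on_logged_values():
    rng = np.random.default_rng(2)
    raw = rng.lognormal(0.5, 0.8, size=(20, 5))
    m_raw = make_matrix(raw, state="raw_fpkm")
    m_log = make_matrix(np.log10(raw), state="log10")
    sig = g.GeneSignature("s", frozenset({"G1", "G5", "G9"}))
    assert np.allclose(
        g.score_geometric(m_raw, sig, pseudocount=0.0),
        g.score_signature(m_log, sig),
    )


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def ssgsea_oracle(values, in_set, alpha):
    """Independent step-by-step running-sum walk."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    w = [abs(values[i]) ** alpha if in_set[i] else 0.0 for i in order]
    total_in = sum(w) or float(sum(in_set[i] for i in order))
    if sum(w) == 0:
        w = [1.0 if in_set[i] else 0.0 for i in order]
    n_out = len(values) - sum(in_set)
    es = 0.0
    p_in = p_out = 0.0
    for k, i in enumerate(order):
        if in_set[i]:
            p_in += w[k] / total_in
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


@pytest.mark.parametrize("alpha", [0.0, 0.75])
def test_ssgsea_matches_oracle_exhaustively_for_three_gene_sets(alpha):
    """All 120 possible 3-gene sets of a 10-gene sample agree with the
    independently coded running-sum oracle."""
    values = np.array([9.0, 7.5, 6.0, 5.5, 4.0, 3.5, 2.0, 1.5, 1.0, 0.5])
    for combo in itertools.combinations(range(10), 3):
        mask = np.zeros(10, dtype=bool)
        mask[list(combo)] = True
        mine = _ssgsea_sample(values, mask, alpha)
        assert mine == pytest.approx(ssgsea_oracle(values, mask, alpha), abs=1e-12)


def test_ssgsea_top_ranked_set_is_maximal():
    values = np.arange(10, 0, -1).astype(float)
    top = np.zeros(10, dtype=bool)
    top[:3] = True
    es_top = _ssgsea_sample(values, top, alpha=0.0)
    for combo in itertools.combinations(range(10), 3):
        mask = np.zeros(10, dtype=bool)
        mask[list(combo)] = True
        assert _ssgsea_sample(values, mask, alpha=0.0) <= es_top + 1e-12


def test_ssgsea_monotone_in_set_upshift():
    """Raising all in-set genes of a sample never lowers its score."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        values = rng.normal(2.0, 1.0, size=30)
        mask = np.zeros(30, dtype=bool)
        mask[rng.choice(30, size=5, replace=False)] = True
        base = _ssgsea_sample(values, mask, alpha=0.75)
        up = values.copy()
        up[mask] += rng.uniform(0.1, 2.0)
        assert _ssgsea_sample(up, mask, alpha=0.75) >= base - 1e-12


def test_ssgsea_permutation_null_centers_near_zero():
    """Scores of label-permuted samples are centered near zero relative
    to the strongly enriched extreme."""
    rng = np.random.default_rng(4)
    values = rng.normal(2.0, 0.5, size=50)
    mask = np.zeros(50, dtype=bool)
    mask[:5] = True
    extreme = _ssgsea_sample(np.sort(values)[::-1].copy(), mask, alpha=0.75)
    scores = []
    for _ in range(1000):
        perm = rng.permutation(values)
        scores.append(_ssgsea_sample(perm, mask, alpha=0.75))
    assert abs(np.mean(scores)) < 0.1 * abs(extreme)


def test_ssgsea_interface_validation(default_normalized):
    with pytest.raises(ValueError, match="< 2 genes"):
        g.ssgsea(default_normalized, {"bad": ["NOPE1", "NOPE2"]})
    sets = {"ok": list(default_normalized.gene_ids[:10])}
    results = g.ssgsea(default_normalized, sets)
    assert len(results) == len(default_normalized.sample_ids)
    assert all(np.isfinite(r.score) for r in results)


# ---------------------------------------------------------------------------
# differential expression / resistance signature
# ---------------------------------------------------------------------------


def _null_groups(n_genes=200, n_per_group=10, seed=0):
    rng = np.random.default_rng(seed)
    m = make_matrix(rng.normal(size=(n_genes, 2 * n_per_group)))
    labels = {f"S{j}": j < n_per_group for j in range(2 * n_per_group)}
    return m, labels


def test_identical_groups_have_zero_fold_change():
    m0, _ = _null_groups()
    doubled = make_matrix(np.hstack([m0.values, m0.values]))
    labels = {f"S{j}": j < m0.values.shape[1] for j in range(2 * m0.values.shape[1])}
    de = g.differential_expression(doubled, labels)
    assert np.allclose(de["log2_fc"], 0.0)


def test_planted_shift_detected_with_correct_sign_and_size():
    """A 0.301 log10 shift (= 1 on the log2 scale) in responders is
    estimated near 1 with small p-values at n=50 per group."""
    rng = np.random.default_rng(5)
    n = 50
    base = rng.normal(1.0, 0.1, size=(100, 2 * n))
    base[:10, :n] += np.log10(2.0)
    labels = {f"S{j}": j < n for j in range(2 * n)}
    de = g.differential_expression(make_matrix(base), labels)
    planted = de.iloc[:10]
    # se of each estimate is ~0.066 on the log2 scale; 3 sigma margin
    assert np.allclose(planted["log2_fc"], 1.0, atol=0.2)
    assert (planted["p_value"] < 0.01).all()
    assert (volcano_classes(de)[:10] == "up").all()


def test_de_pvalues_uniform_under_null():
    """KS distance of null p-values from U(0,1) below 0.05 at 5000 genes."""
    rng = np.random.default_rng(6)
    m = make_matrix(rng.normal(size=(5000, 50)))
    labels = {f"S{j}": j < 25 for j in range(50)}
    de = g.differential_expression(m, labels)
    ks = stats.kstest(de["p_value"], "uniform").statistic
    assert ks < 0.05


def test_de_requires_two_samples_per_group():
    m, _ = _null_groups()
    with pytest.raises(ValueError, match=">= 2 samples"):
        g.differential_expression(m, {"S0": True, "S1": False, "S2": False})


def test_resistance_signature_cutoffs_and_errors():
    rng = np.random.default_rng(7)
    n = 30
    base = rng.normal(1.0, 0.1, size=(50, 2 * n))
    base[:5, n:] += 0.5  # up in non-responders
    labels = {f"S{j}": j < n for j in range(2 * n)}
    de = g.differential_expression(make_matrix(base), labels)
    sig = g.derive_resistance_signature(de, max_genes=3)
    assert sig.direction == "up"
    assert len(sig.genes) == 3
    assert sig.genes <= {"G0", "G1", "G2", "G3", "G4"}
    with pytest.raises(EmptySignatureError):
        g.derive_resistance_signature(de, fc_cutoff=50.0)


def test_resistance_signature_recovered_from_strong_cohort(strong_cohort):
    """>= 90% of the planted non-responder program is recovered under
    strong-effect conditions."""
    norm = g.normalize_expression(strong_cohort.expression)
    responder = {
        r.sample_id: r.response_category in ("CR", "PR")
        for r in strong_cohort.clinical
    }
    de = g.differential_expression(norm, responder)
    sig = g.derive_resistance_signature(de)
    truth = set(strong_cohort.truth.resistant_genes)
    sensitivity = len(sig.genes & truth) / len(truth)
    assert sensitivity >= 0.9
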