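"""Expression normalization, signature scoring, ssGSEA and differential
expression.

The normalization pipeline mirrors common bulk RNA-seq practice for
FPKM-quantified cohorts: log10 transform with a pseudocount, then quantile
normalization across samples so every sample shares the same empirical
value distribution. Signature scores are per-sample means of member-gene
expression, either on the normalized log scale (arithmetic) or as the
geometric average of raw intensities. ssGSEA produces a per-sample
enrichment score for a gene set via a weighted running-sum statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger("gctrial")

LOG2_PER_LOG10 = 1.0 / np.log10(2.0)


@dataclass
class GeneSignature:
    """A named gene set with an optional direction of effect."""

    name: str
    genes: frozenset[str]
    direction: str = "unsigned"  # up | down | unsigned

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if self.direction not in ("up", "down", "unsigned"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class EnrichmentResult:
    sample_id: str
    set_name: str
    score: float


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a matrix.

    The reference distribution is the mean of the column-sorted value
    vectors. Tied values within a column receive the mean of the reference
    values at their tied ranks, so the map is well defined and symmetric
    under reordering.
    """
    values = np.asarray(values, dtype=float)
    n_genes, _ = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # average reference values over runs of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_genes]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    return out


def normalize_expression(
    m: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log10(FPKM + pseudocount) followed by column quantile normalization.

    Accepts a matrix in ``raw_fpkm`` state only and returns a new matrix
    in ``log10_quantile_normalized`` state. After the transform every
    sample column has the identical sorted value vector.
    """
    if m.state != "raw_fpkm":
        raise ValueError(f"expected raw_fpkm state, got {m.state!r}")
    if np.any(m.values < 0):
        raise ValueError("raw FPKM values must be nonnegative")
    logged = np.log10(m.values + pseudocount)
    normalized = quantile_normalize(logged)
    return ExpressionMatrix(
        list(m.gene_ids), list(m.sample_ids), normalized,
        state="log10_quantile_normalized",
    )


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------


def _present_genes(m: ExpressionMatrix, sig: GeneSignature,
                   min_fraction: float) -> list[int]:
    index = {g: i for i, g in enumerate(m.gene_ids)}
    present = [index[g] for g in sorted(sig.genes) if g in index]
    if not present:
        raise ValueError(f"no genes of signature {sig.name!r} in the matrix")
    if len(present) < min_fraction * len(sig.genes):
        raise ValueError(
            f"only {len(present)}/{len(sig.genes)} genes of signature "
            f"{sig.name!r} present (need >= {min_fraction:.0%})"
        )
    return present


def score_signature(
    m: ExpressionMatrix, sig: GeneSignature, min_fraction: float = 0.5
) -> pd.Series:
    """Arithmetic mean of member-gene expression per sample.

    Intended for log-scale normalized matrices; requires at least
    ``min_fraction`` of the signature's genes to be present.
    """
    rows = _present_genes(m, sig, min_fraction)
    scores = m.values[rows].mean(axis=0)
    return pd.Series(scores, index=m.sample_ids, name=sig.name)


def score_geometric(
    m: ExpressionMatrix, sig: GeneSignature,
    pseudocount: float = 0.0, min_fraction: float = 0.5,
) -> pd.Series:
    """Geometric-average signature score: mean log10 intensity per sample.

    Operates on raw-intensity matrices; equals :func:`score_signature`
    applied to the log10-transformed values.
    """
    rows = _present_genes(m, sig, min_fraction)
    vals = m.values[rows]
    if np.any(vals + pseudocount <= 0):
        raise ValueError("nonpositive intensity; use a pseudocount")
    scores = np.log10(vals + pseudocount).mean(axis=0)
    return pd.Series(scores, index=m.sample_ids, name=sig.name)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def _ssgsea_sample(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Weighted running-sum enrichment score for one sample.

    Genes are ranked by decreasing expression; in-set genes contribute
    increments proportional to |value|^alpha (normalized to sum 1 over the
    set), out-of-set genes uniform decrements. The statistic is the sum of
    the running difference over all rank positions (integrated difference).
    """
    order = np.argsort(-values, kind="stable")
    inset_ordered = in_set[order]
    weights = np.abs(values[order]) ** alpha
    w_in = np.where(inset_ordered, weights, 0.0)
    total_in = w_in.sum()
    if total_in == 0:  # all in-set values zero: fall back to uniform steps
        w_in = inset_ordered.astype(float)
        total_in = w_in.sum()
    p_in = np.cumsum(w_in) / total_in
    n_out = len(values) - int(inset_ordered.sum())
    p_out = np.cumsum(~inset_ordered) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    m: ExpressionMatrix,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.75,
    normalize: bool = True,
) -> list[EnrichmentResult]:
    """Single-sample gene-set enrichment scores.

    Every set must share at least 2 genes with the matrix, and at least
    one gene must be outside each set. With ``normalize=True`` all scores
    are divided by the global score range across samples and sets.
    """
    index = {g: i for i, g in enumerate(m.gene_ids)}
    results: list[EnrichmentResult] = []
    masks: dict[str, np.ndarray] = {}
    for name, genes in gene_sets.items():
        rows = [index[g] for g in genes if g in index]
        if len(rows) < 2:
            raise ValueError(f"gene set {name!r} shares < 2 genes with the matrix")
        if len(rows) >= len(m.gene_ids):
            raise ValueError(f"gene set {name!r} covers the entire matrix")
        mask = np.zeros(len(m.gene_ids), dtype=bool)
        mask[rows] = True
        masks[name] = mask
    for j, sample in enumerate(m.sample_ids):
        col = m.values[:, j]
        for name, mask in masks.items():
            results.append(
                EnrichmentResult(sample, name, _ssgsea_sample(col, mask, alpha))
            )
    if normalize and results:
        scores = np.array([r.score for r in results])
        rng = scores.max() - scores.min()
        if rng > 0:
            for r in results:
                r.score /= rng
    return results


# ---------------------------------------------------------------------------
# differential expression and the resistance signature
# ---------------------------------------------------------------------------


def differential_expression(
    m: ExpressionMatrix,
    responder: dict[str, bool],
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-gene responder vs non-responder comparison.

    ``responder`` maps sample ids to True (responder) / False
    (non-responder); samples absent from the mapping (e.g. not evaluable)
    are excluded. Fold changes are responder minus non-responder group
    means expressed on the log2 scale (normalized log10 values are
    rescaled by 1/log10(2)); p-values come from the two-sided Wilcoxon
    rank-sum test by default (``test="welch"`` for Welch's t).

    Returns a DataFrame with columns ``gene, log2_fc, p_value,
    adjusted_p`` (Benjamini-Hochberg).
    """
    cols_r = [j for j, s in enumerate(m.sample_ids) if responder.get(s) is True]
    cols_n = [j for j, s in enumerate(m.sample_ids) if responder.get(s) is False]
    if len(cols_r) < 2 or len(cols_n) < 2:
        raise ValueError("need >= 2 samples per group for differential expression")
    xr = m.values[:, cols_r]
    xn = m.values[:, cols_n]
    log2_fc = (xr.mean(axis=1) - xn.mean(axis=1)) * LOG2_PER_LOG10
    if test == "wilcoxon":
        stat = stats.mannwhitneyu(xr, xn, axis=1, alternative="two-sided")
        p = np.asarray(stat.pvalue, dtype=float)
    elif test == "welch":
        stat = stats.ttest_ind(xr, xn, axis=1, equal_var=False)
        p = np.asarray(stat.pvalue, dtype=float)
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adjusted = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": m.gene_ids,
            "log2_fc": log2_fc,
            "p_value": p,
            "adjusted_p": adjusted,
        }
    )


def volcano_classes(
    de: pd.DataFrame, fc_cutoff: float = 0.5, p_cutoff: float = 0.05
) -> pd.Series:
    """Classify DE rows as 'up' (responder-high), 'down' or 'ns' using the
    conventional volcano thresholds |log2FC| > cutoff and raw p < cutoff."""
    up = (de["log2_fc"] > fc_cutoff) & (de["p_value"] < p_cutoff)
    down = (de["log2_fc"] < -fc_cutoff) & (de["p_value"] < p_cutoff)
    out = pd.Series("ns", index=de.index)
    out[up] = "up"
    out[down] = "down"
    return out


class EmptySignatureError(ValueError):
    """No gene passed the resistance-signature cutoffs."""


def derive_resistance_signature(
    de: pd.DataFrame,
    fc_cutoff: float = 0.5,
    p_cutoff: float = 0.05,
    max_genes: int = 200,
    name: str = "treatment_resistant",
) -> GeneSignature:
    """Genes overexpressed in non-responders: log2_fc <= -fc_cutoff and
    raw p < p_cutoff, ordered by ascending p and capped at ``max_genes``."""
    hits = de[(de["log2_fc"] <= -fc_cutoff) & (de["p_value"] < p_cutoff)]
    if hits.empty:
        logger.warning("no gene passed the resistance-signature cutoffs")
        raise EmptySignatureError(
            f"no gene with log2_fc <= -{fc_cutoff} and p < {p_cutoff}"
        )
    hits = hits.sort_values(["p_value", "gene"], kind="stable").head(max_genes)
    return GeneSignature(name, frozenset(hits["gene"]), direction="up")
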