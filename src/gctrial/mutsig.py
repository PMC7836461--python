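"""Trinucleotide mutation catalogs and known-signature deconvolution.

Somatic single-base substitutions are summarized as 96-channel catalogs
(six pyrimidine-reference substitution classes x 4 five-prime x 4
three-prime bases). Catalogs can be re-weighted from the trinucleotide
composition of the captured exome to a target composition, and decomposed
into nonnegative mixtures of known signature profiles by constrained least
squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger("gctrial")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Channel labels in conventional order: substitution-major, then 5' base,
#: then 3' base, e.g. ``A[C>A]A``.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

#: The 32 pyrimidine-centered trinucleotide contexts, e.g. ``ACA``.
CONTEXTS_32 = tuple(
    f"{five}{center}{three}"
    for center in ("C", "T")
    for five in BASES
    for three in BASES
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_32)}

#: context index (into CONTEXTS_32) of each of the 96 channels
CHANNEL_CONTEXT = np.array(
    [_CONTEXT_INDEX[f"{c[0]}{c[2]}{c[6]}"] for c in CHANNELS_96]
)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class MutationCatalog:
    """Per-sample 96-channel substitution counts (pyrimidine reference)."""

    sample_id: str
    channel_counts: np.ndarray

    def __post_init__(self) -> None:
        self.channel_counts = np.asarray(self.channel_counts, dtype=int)
        if self.channel_counts.shape != (96,):
            raise ValueError("channel_counts must be a 96-vector")
        if np.any(self.channel_counts < 0):
            raise ValueError("negative channel count")

    @property
    def n_snvs(self) -> int:
        return int(self.channel_counts.sum())

    def frequencies(self) -> np.ndarray:
        total = self.channel_counts.sum()
        if total == 0:
            return np.zeros(96)
        return self.channel_counts / total


@dataclass
class SignatureMatrix:
    """Known mutational-signature profiles: 96 x K column-stochastic matrix."""

    signature_ids: list[str]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (96, len(self.signature_ids)):
            raise ValueError("probabilities must be 96 x n_signatures")
        if np.any(self.probabilities < 0):
            raise ValueError("signature probabilities must be nonnegative")
        sums = self.probabilities.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError("signature columns must each sum to 1")

    def subset(self, ids: list[str]) -> "SignatureMatrix":
        idx = [self.signature_ids.index(s) for s in ids]
        return SignatureMatrix(list(ids), self.probabilities[:, idx])


@dataclass
class ExposureVector:
    """Fitted signature weights for one sample.

    ``weights`` aligns with the signature matrix columns; ``unexplained``
    is ``1 - sum(weights)`` and ``residual`` the L2 norm of the profile
    reconstruction error.
    """

    sample_id: str
    signature_ids: list[str]
    weights: np.ndarray
    unexplained: float
    residual: float


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------


def channel_of(ref: str, alt: str, context: str) -> int:
    """Map one SNV with its 3-base context to the 96-channel index.

    Purine-reference variants are folded onto the reverse-complement
    strand so every channel carries a pyrimidine (C/T) reference.
    """
    ref, alt = ref.upper(), alt.upper()
    context = context.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if any(b not in _COMPLEMENT for b in context) or len(context) != 3:
        raise ValueError(f"bad trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValueError(f"context {context!r} center does not match ref {ref!r}")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = reverse_complement(context)
    return _CHANNEL_INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


def build_catalog(variants: pd.DataFrame, sample_id: str | None = None) -> MutationCatalog:
    """Count a sample's SNVs into the 96 trinucleotide channels.

    ``variants`` is the mutation table dialect of :mod:`gctrial.io`
    (columns ``sample_id, gene, chrom, pos, ref, alt, context``).
    Indels and multi-base variants are skipped with a logged count;
    unknown context bases raise.
    """
    if sample_id is None:
        ids = variants["sample_id"].unique() if len(variants) else []
        if len(ids) > 1:
            raise ValueError("variants span multiple samples; pass sample_id")
        sample_id = ids[0] if len(ids) else ""
    else:
        variants = variants[variants["sample_id"] == sample_id]

    counts = np.zeros(96, dtype=int)
    skipped = 0
    for ref, alt, ctx in zip(variants["ref"], variants["alt"], variants["context"]):
        ref, alt = ref.upper(), alt.upper()
        if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
            skipped += 1  # indel or multi-base event
            continue
        counts[channel_of(ref, alt, ctx)] += 1
    if skipped:
        logger.info(
            "build_catalog(%s): skipped %d non-SNV variants", sample_id, skipped
        )
    return MutationCatalog(sample_id, counts)


def build_catalogs(variants: pd.DataFrame) -> list[MutationCatalog]:
    return [
        build_catalog(group, sample_id=sid)
        for sid, group in variants.groupby("sample_id", sort=True)
    ]


# ---------------------------------------------------------------------------
# exome-composition normalization
# ---------------------------------------------------------------------------


def normalize_catalog(
    cat: MutationCatalog,
    exome_tri_counts: np.ndarray,
    target_tri_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Re-weight a catalog from the capture-region trinucleotide
    composition to a target composition.

    Each channel is scaled by the ratio of the target to source frequency
    of its trinucleotide context; the output is renormalized to sum to 1.
    With ``target_tri_counts=None`` a uniform target composition is used.
    """
    source = np.asarray(exome_tri_counts, dtype=float)
    if source.shape != (32,):
        raise ValueError("exome_tri_counts must be a 32-vector")
    if np.any(source <= 0):
        raise ValueError("every exome trinucleotide count must be positive")
    if target_tri_counts is None:
        target = np.ones(32)
    else:
        target = np.asarray(target_tri_counts, dtype=float)
        if target.shape != (32,):
            raise ValueError("target_tri_counts must be a 32-vector")
    ratio = (target / target.sum()) / (source / source.sum())
    scaled = cat.channel_counts * ratio[CHANNEL_CONTEXT]
    total = scaled.sum()
    if total == 0:
        return np.zeros(96)
    return scaled / total


# ---------------------------------------------------------------------------
# constrained deconvolution
# ---------------------------------------------------------------------------


def _project_capped_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {w >= 0, sum(w) <= 1}."""
    w = np.clip(v, 0.0, None)
    if w.sum() <= 1.0:
        return w
    # cap binds: project onto the probability simplex
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / np.arange(1, len(u) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.clip(v - theta, 0.0, None)


def _solve_capped_nnls(S: np.ndarray, p: np.ndarray, tol: float = 1e-12,
                       max_iter: int = 20000) -> np.ndarray:
    """min ||p - S w||^2 subject to w >= 0 and sum(w) <= 1.

    Unconstrained-sum NNLS is tried first; if its solution already
    satisfies the cap it is optimal (the constraint is inactive).
    Otherwise projected gradient descent with step 1/L is run, which
    decreases the objective monotonically.
    """
    w, _ = nnls(S, p)
    if w.sum() <= 1.0 + 1e-12:
        return w
    L = np.linalg.norm(S, 2) ** 2
    w = _project_capped_simplex(w)
    StS, Stp = S.T @ S, S.T @ p
    prev = np.inf
    for _ in range(max_iter):
        grad = StS @ w - Stp
        w_new = _project_capped_simplex(w - grad / L)
        obj = 0.5 * w_new @ StS @ w_new - Stp @ w_new
        if prev - obj < tol and np.max(np.abs(w_new - w)) < 1e-10:
            return w_new
        w, prev = w_new, obj
    return w


def deconvolve(
    profile: np.ndarray,
    sigs: SignatureMatrix,
    min_contribution: float = 0.06,
) -> ExposureVector:
    """Decompose a normalized 96-channel profile into known signatures.

    Solves nonnegative least squares with the total exposure capped at 1,
    then iteratively drops signatures whose fitted weight falls below
    ``min_contribution`` and refits on the survivors until the active set
    is stable (the convention of reference signature-refitting tools).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (96,):
        raise ValueError("profile must be a 96-vector")
    if len(sigs.signature_ids) == 0:
        raise ValueError("signature matrix has no columns")
    if not np.isclose(profile.sum(), 1.0, atol=1e-6):
        raise ValueError("profile must sum to 1 (normalize the catalog first)")

    active = list(range(len(sigs.signature_ids)))
    weights = np.zeros(len(sigs.signature_ids))
    while active:
        S = sigs.probabilities[:, active]
        w = _solve_capped_nnls(S, profile)
        keep = [a for a, wi in zip(active, w) if wi >= min_contribution]
        if len(keep) == len(active):
            weights = np.zeros(len(sigs.signature_ids))
            weights[active] = w
            break
        active = keep
    residual = float(np.linalg.norm(profile - sigs.probabilities @ weights))
    return ExposureVector(
        sample_id="",
        signature_ids=list(sigs.signature_ids),
        weights=weights,
        unexplained=float(1.0 - weights.sum()),
        residual=residual,
    )


def deconvolve_catalog(
    cat: MutationCatalog,
    sigs: SignatureMatrix,
    exome_tri_counts: np.ndarray | None = None,
    target_tri_counts: np.ndarray | None = None,
    min_contribution: float = 0.06,
) -> ExposureVector:
    """Normalize a catalog (uniform composition if no table given) and
    deconvolve it; convenience wrapper used by the CLI."""
    if exome_tri_counts is None:
        profile = cat.frequencies()
    else:
        profile = normalize_catalog(cat, exome_tri_counts, target_tri_counts)
    exp = deconvolve(profile, sigs, min_contribution=min_contribution)
    exp.sample_id = cat.sample_id
    return exp


def synthetic_signature_matrix(k: int = 30, seed: int = 20160526,
                               concentration: float = 0.08) -> SignatureMatrix:
    """A synthetic stand-in signature matrix with k peaked columns.

    Columns are sparse Dirichlet draws mimicking the shape of curated
    single-base-substitution signature catalogs (a few dominant channels
    per process). Purely synthetic: use it for simulation and testing, and
    supply a real signature table via TSV for actual analyses.
    """
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(96, concentration), size=k).T
    ids = [f"Signature.{i + 1}" for i in range(k)]
    return SignatureMatrix(ids, cols)


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a signature TSV: first column channel label, one column per
    signature; rows may be in any order but must cover all 96 channels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS_96) - set(df.index)
    if missing:
        raise ValueError(f"signature table missing channels, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(CHANNELS_96)]
    return SignatureMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_signature_matrix(sigs: SignatureMatrix, path) -> None:
    pd.DataFrame(
        sigs.probabilities, index=list(CHANNELS_96), columns=sigs.signature_ids
    ).rename_axis("channel").to_csv(path, sep="\t")
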