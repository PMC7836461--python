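"""Synthetic cohort generator.

Generates complete trial cohorts with the statistical structure the
downstream analysis assumes — clinical annotation with RECIST responses
and survival endpoints, an FPKM expression matrix with planted response
signatures, somatic SNV tables drawn from known mutational-signature
mixtures, copy-number segment profiles separating chromosomally unstable
from genomically stable tumors, and microsatellite marker panels — plus a
ground-truth record that makes parameter-recovery testing possible.

Default parameters emulate a ~60-patient metastatic gastric-cancer
cohort treated with an anti-angiogenic doublet: EBV prevalence ~5% with
universal response among EBV(+) tumors, no MSI-H tumors, a GS-dominated
GS/CIN mixture, a planted mutation (GNAQ) that raises the odds of
response, and a treatment-resistant expression program that is elevated
in non-responders and carries a proportional-hazards survival effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .io import (ClinicalRecord, CopyNumberProfile, ExpressionMatrix,
                 MicrosatellitePanel, MSI_MARKERS)
from .mutsig import (CHANNELS_96, MutationCatalog, SignatureMatrix,
                     reverse_complement, synthetic_signature_matrix)
from .response import recist_category


class ConfigError(ValueError):
    """Invalid cohort configuration."""


# approximate autosome lengths (bp), used for segment and variant placement
CHROM_LENGTHS = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 103_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000,
}

# fixed child-stream offsets: adding a component never perturbs the draws
# of existing components
_STREAMS = {
    "subtype": 0, "response": 1, "expression": 2, "mutation": 3,
    "copy_number": 4, "survival": 5, "msi_panel": 6, "clinical": 7,
}


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults are the emulated trial
    conditions (cohort size, prevalences, planted effect sizes)."""

    n_patients: int = 62
    seed: int = 0
    ebv_prevalence: float = 0.048
    msi_prevalence: float = 0.0
    cin_fraction: float = 0.375
    response_rate_baseline: float = 0.30
    ebv_response_rate: float = 1.0
    gnaq_mut_rate: float = 0.16
    gnaq_response_odds_multiplier: float = 6.0
    resistant_signature_hazard_ratio: float = 2.0
    mutation_burden_mean: float = 75.0
    signature_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "Signature.1": 0.6, "Signature.17": 0.25, "Signature.3": 0.15,
        }
    )
    censoring_rate: float = 0.25
    n_genes: int = 2000
    n_mutation_genes: int = 6000  # exome-scale pool; first n_genes are expressed
    n_resistant_genes: int = 40
    n_responder_up_genes: int = 15
    resistant_shift: float = 0.15  # log10 units added in non-responders
    responder_shift: float = 0.15  # log10 units added in responders
    ebv_reduction_shift: float = -30.0   # extra tumor shrinkage (% points)
    gnaq_reduction_shift: float = -12.0

    def __post_init__(self) -> None:
        probs = {
            "ebv_prevalence": self.ebv_prevalence,
            "msi_prevalence": self.msi_prevalence,
            "cin_fraction": self.cin_fraction,
            "response_rate_baseline": self.response_rate_baseline,
            "ebv_response_rate": self.ebv_response_rate,
            "gnaq_mut_rate": self.gnaq_mut_rate,
            "censoring_rate": self.censoring_rate,
        }
        for name, value in probs.items():
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must be a probability, got {value}")
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_mutation_genes < self.n_genes:
            raise ConfigError("n_mutation_genes must be >= n_genes")
        if self.seed < 0:
            raise ConfigError("seed must be a nonnegative integer")
        if self.gnaq_response_odds_multiplier <= 0:
            raise ConfigError("gnaq_response_odds_multiplier must be positive")
        if self.resistant_signature_hazard_ratio <= 0:
            raise ConfigError("resistant_signature_hazard_ratio must be positive")
        if self.mutation_burden_mean <= 0:
            raise ConfigError("mutation_burden_mean must be positive")
        weights = np.array(list(self.signature_mixture.values()), dtype=float)
        if len(weights) == 0 or np.any(weights < 0):
            raise ConfigError("signature_mixture weights must be nonnegative")
        if not np.isclose(weights.sum(), 1.0, atol=1e-8):
            raise ConfigError("signature_mixture weights must sum to 1")


@dataclass
class GroundTruth:
    """What the generator planted; the recovery targets for tests."""

    subtype: dict[str, str]
    responder: dict[str, bool]
    gnaq_mutant: dict[str, bool]
    signature_weights: dict[str, float]
    resistant_genes: list[str]
    responder_up_genes: list[str]
    resistant_score: dict[str, float]
    hazard_ratio: float
    effects: dict[str, float]


@dataclass
class CohortBundle:
    """A complete synthetic cohort; all components share sample ids."""

    clinical: list[ClinicalRecord]
    expression: ExpressionMatrix
    variants: pd.DataFrame
    catalogs: list[MutationCatalog]
    copy_number: list[CopyNumberProfile]
    msi_panels: list[MicrosatellitePanel]
    truth: GroundTruth

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.clinical]


def _rng(config_seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([config_seed, _STREAMS[component]])


def generate_microsatellite_panel(
    sample_status: str, seed: int | np.random.Generator,
    sample_id: str = "",
) -> MicrosatellitePanel:
    """Marker panel consistent with an MSI call: MSI-H samples show
    instability in at least 3 of the 5 markers, MSS in at most 2."""
    if sample_status not in ("MSI-H", "MSS"):
        raise ValueError(f"unknown MSI status {sample_status!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if sample_status == "MSI-H":
        n_unstable = rng.choice([3, 4, 5], p=[0.45, 0.35, 0.20])
    else:
        n_unstable = rng.choice([0, 1, 2], p=[0.85, 0.12, 0.03])
    unstable = set(rng.choice(len(MSI_MARKERS), size=n_unstable, replace=False))
    return MicrosatellitePanel(
        sample_id,
        {m: ("unstable" if i in unstable else "stable")
         for i, m in enumerate(MSI_MARKERS)},
    )


def _generate_copy_number(
    sample_id: str, subtype: str, rng: np.random.Generator
) -> CopyNumberProfile:
    """Segment profile whose fraction of genome altered separates CIN
    (0.35-0.60) from the other subtypes (< 0.12)."""
    target = (rng.uniform(0.35, 0.60) if subtype == "CIN"
              else rng.uniform(0.0, 0.12))
    segments: list[tuple[str, int, int, float]] = []
    for chrom, length in CHROM_LENGTHS.items():
        n_seg = rng.integers(2, 5)
        cuts = np.sort(rng.integers(1, length, size=n_seg - 1))
        bounds = np.concatenate(([1], cuts + 1))
        ends = np.concatenate((cuts, [length]))
        for s, e in zip(bounds, ends):
            if e >= s:
                segments.append((chrom, int(s), int(e), 0.0))
    total = sum(e - s + 1 for _, s, e, _ in segments)
    order = rng.permutation(len(segments))
    altered_bp = 0
    out: list[tuple[str, int, int, float]] = [None] * len(segments)  # type: ignore
    for i in order:
        chrom, s, e, _ = segments[i]
        if altered_bp / total < target:
            ratio = rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0])
            altered_bp += e - s + 1
        else:
            ratio = float(np.clip(rng.normal(0.0, 0.05), -0.25, 0.25))
        out[i] = (chrom, s, e, float(ratio))
    return CopyNumberProfile(sample_id, out)


# per-channel lookup tables for variant emission
_CH_REF = [c[2] for c in CHANNELS_96]
_CH_ALT = [c[4] for c in CHANNELS_96]
_CH_CTX = [f"{c[0]}{c[2]}{c[6]}" for c in CHANNELS_96]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _emit_variants(
    sample_id: str,
    channel_counts: np.ndarray,
    gene_pool: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    channels = np.repeat(np.arange(96), channel_counts)
    n = len(channels)
    flip = rng.random(n) < 0.5  # report half the variants on the purine strand
    chroms = list(CHROM_LENGTHS)
    lengths = np.array(list(CHROM_LENGTHS.values()), dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[chrom_idx]).astype(int) + 1
    refs, alts, ctxs = [], [], []
    for ch, fl in zip(channels, flip):
        ref, alt, ctx = _CH_REF[ch], _CH_ALT[ch], _CH_CTX[ch]
        if fl:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            ctx = reverse_complement(ctx)
        refs.append(ref)
        alts.append(alt)
        ctxs.append(ctx)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "gene": rng.choice(gene_pool, size=n),
            "chrom": [chroms[i] for i in chrom_idx],
            "pos": pos,
            "ref": refs,
            "alt": alts,
            "context": ctxs,
        }
    )


def generate_cohort(
    config: CohortConfig,
    signatures: SignatureMatrix | None = None,
) -> CohortBundle:
    """Generate a full cohort; bit-identical for identical configs.

    ``signatures`` defaults to the bundled synthetic signature matrix;
    all ids in ``config.signature_mixture`` must be among its columns.
    """
    if signatures is None:
        signatures = synthetic_signature_matrix()
    for sig_id in config.signature_mixture:
        if sig_id not in signatures.signature_ids:
            raise ConfigError(f"unknown signature id {sig_id!r} in mixture")

    n = config.n_patients
    sample_ids = [f"GC{i + 1:04d}" for i in range(n)]

    # --- subtype assignment (precedence EBV > MSI > CIN/GS) -------------
    # EBV/MSI counts are fixed at round(prevalence * n): the generator
    # emulates a cohort composition, not an open-ended sampling process
    rng_sub = _rng(config.seed, "subtype")
    n_ebv = int(round(config.ebv_prevalence * n))
    n_msi = int(round(config.msi_prevalence * n))
    assignment = rng_sub.permutation(n)
    ebv = np.zeros(n, dtype=bool)
    msi = np.zeros(n, dtype=bool)
    ebv[assignment[:n_ebv]] = True
    msi[assignment[n_ebv:n_ebv + n_msi]] = True
    cin = (~ebv) & (~msi) & (rng_sub.random(n) < config.cin_fraction)
    subtype = np.where(ebv, "EBV", np.where(msi, "MSI", np.where(cin, "CIN", "GS")))

    # --- response ------------------------------------------------------
    rng_resp = _rng(config.seed, "response")
    gnaq = rng_resp.random(n) < config.gnaq_mut_rate
    base = config.response_rate_baseline
    odds = base / (1 - base) if base < 1 else np.inf
    odds_vec = np.where(gnaq, odds * config.gnaq_response_odds_multiplier, odds)
    p_resp = odds_vec / (1 + odds_vec)
    p_resp = np.where(ebv, config.ebv_response_rate, p_resp)
    responder = rng_resp.random(n) < p_resp
    # best change: responders shrink >= 30%, non-responders SD/PD range;
    # the planted drivers also deepen the shrinkage itself, clipped so the
    # RECIST category drawn above is preserved
    reduction = np.where(
        responder,
        rng_resp.uniform(-65.0, -31.0, size=n),
        rng_resp.uniform(-25.0, 35.0, size=n),
    )
    reduction += ebv * config.ebv_reduction_shift
    reduction += gnaq * config.gnaq_reduction_shift
    reduction = np.where(
        responder,
        np.clip(reduction, -95.0, -31.0),
        np.clip(reduction, -29.0, 35.0),
    )

    # --- expression ------------------------------------------------------
    rng_expr = _rng(config.seed, "expression")
    gene_ids = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    baseline = rng_expr.normal(1.0, 0.5, size=config.n_genes)
    # planted program sizes are capped on very small gene panels so toy
    # configurations stay valid
    n_res = min(config.n_resistant_genes, max(1, config.n_genes // 5))
    n_up = min(config.n_responder_up_genes, max(1, config.n_genes // 10))
    special = rng_expr.choice(config.n_genes, size=n_res + n_up, replace=False)
    resistant_idx = special[:n_res]
    responder_idx = special[n_res:]
    # keep planted genes comfortably expressed so the log signal survives
    # the FPKM floor at zero
    baseline[special] = np.clip(baseline[special], 0.8, None)
    log_expr = (
        baseline[:, None] + rng_expr.normal(0.0, 0.35, size=(config.n_genes, n))
    )
    log_expr[np.ix_(resistant_idx, np.flatnonzero(~responder))] += config.resistant_shift
    log_expr[np.ix_(responder_idx, np.flatnonzero(responder))] += config.responder_shift
    fpkm = np.clip(10.0 ** log_expr - 1.0, 0.0, None)
    expression = ExpressionMatrix(gene_ids, sample_ids, fpkm, state="raw_fpkm")

    # realized resistant-signature score: mean log10(FPKM + 1) over the
    # planted genes, standardized within the cohort (signatures enter the
    # hazard model as z-scores)
    raw_score = np.log10(fpkm[resistant_idx] + 1.0).mean(axis=0)
    score = (raw_score - raw_score.mean()) / raw_score.std()

    # --- survival with the planted proportional-hazards effect ----------
    rng_surv = _rng(config.seed, "survival")
    log_hr = math.log(config.resistant_signature_hazard_ratio)
    rel_hazard = np.exp(log_hr * score)
    os_base = 10.0 / math.log(2)    # median OS ~10 months at the mean score
    pfs_base = 4.4 / math.log(2)    # median PFS ~4.4 months
    os_time = rng_surv.exponential(os_base, size=n) / rel_hazard
    pfs_time = np.minimum(rng_surv.exponential(pfs_base, size=n) / rel_hazard, os_time)
    os_cens = rng_surv.random(n) < config.censoring_rate
    pfs_cens = rng_surv.random(n) < config.censoring_rate
    os_obs = np.where(os_cens, rng_surv.random(n) * os_time, os_time)
    pfs_obs = np.where(pfs_cens, rng_surv.random(n) * pfs_time, pfs_time)

    # --- mutations -------------------------------------------------------
    rng_mut = _rng(config.seed, "mutation")
    sig_ids = list(config.signature_mixture)
    weights = np.array([config.signature_mixture[s] for s in sig_ids])
    cols = [signatures.signature_ids.index(s) for s in sig_ids]
    channel_probs = signatures.probabilities[:, cols] @ weights
    channel_probs = channel_probs / channel_probs.sum()
    # overdispersed burden: lognormal rate mixing preserves the mean and
    # puts roughly a quarter of samples above 100 mutations at the default
    sigma = 0.8
    rates = config.mutation_burden_mean * rng_mut.lognormal(
        -sigma**2 / 2, sigma, size=n
    )
    burdens = rng_mut.poisson(rates)
    gene_pool = [f"GENE{i + 1:05d}" for i in range(config.n_mutation_genes)]
    frames = []
    catalogs = []
    for i, sid in enumerate(sample_ids):
        counts = rng_mut.multinomial(burdens[i], channel_probs)
        frame = _emit_variants(sid, counts, gene_pool, rng_mut)
        if gnaq[i]:
            frame = pd.concat(
                [frame, pd.DataFrame(
                    {"sample_id": [sid], "gene": ["GNAQ"], "chrom": ["9"],
                     "pos": [80_409_488], "ref": ["C"], "alt": ["T"],
                     "context": ["TCG"]}
                )],
                ignore_index=True,
            )
            counts = counts.copy()
            counts[CHANNELS_96.index("T[C>T]G")] += 1
        frames.append(frame)
        catalogs.append(MutationCatalog(sid, counts))
    variants = pd.concat(frames, ignore_index=True)

    # --- copy number -----------------------------------------------------
    rng_cnv = _rng(config.seed, "copy_number")
    copy_number = [
        _generate_copy_number(sid, st, rng_cnv)
        for sid, st in zip(sample_ids, subtype)
    ]

    # --- MSI marker panels ----------------------------------------------
    rng_msi = _rng(config.seed, "msi_panel")
    panels = [
        generate_microsatellite_panel(
            "MSI-H" if st == "MSI" else "MSS", rng_msi, sample_id=sid
        )
        for sid, st in zip(sample_ids, subtype)
    ]

    # --- clinical annotation --------------------------------------------
    rng_clin = _rng(config.seed, "clinical")
    ages = np.clip(np.round(rng_clin.normal(59, 11, size=n)), 27, 81)
    sexes = np.where(rng_clin.random(n) < 0.726, "M", "F")
    her2 = rng_clin.random(n) < 0.161
    sites = rng_clin.choice(
        ["stomach", "liver", "peritoneum", "lung", "lymph_node", "soft_tissue"],
        size=n, p=[0.76, 0.13, 0.06, 0.02, 0.02, 0.01],
    )
    clinical = [
        ClinicalRecord(
            sample_id=sid,
            age=float(ages[i]),
            sex=str(sexes[i]),
            response_category=recist_category(float(reduction[i])),
            tumor_reduction=float(reduction[i]),
            pfs_months=float(pfs_obs[i]),
            pfs_event=bool(~pfs_cens[i]),
            os_months=float(os_obs[i]),
            os_event=bool(~os_cens[i]),
            ebv_status="positive" if ebv[i] else "negative",
            msi_status="MSI-H" if subtype[i] == "MSI" else "MSS",
            her2_status="positive" if her2[i] else "negative",
            biopsy_site=str(sites[i]),
        )
        for i, sid in enumerate(sample_ids)
    ]

    truth = GroundTruth(
        subtype={s: str(t) for s, t in zip(sample_ids, subtype)},
        responder={s: bool(r) for s, r in zip(sample_ids, responder)},
        gnaq_mutant={s: bool(g) for s, g in zip(sample_ids, gnaq)},
        signature_weights=dict(config.signature_mixture),
        resistant_genes=[gene_ids[i] for i in sorted(resistant_idx)],
        responder_up_genes=[gene_ids[i] for i in sorted(responder_idx)],
        resistant_score={s: float(v) for s, v in zip(sample_ids, score)},
        hazard_ratio=config.resistant_signature_hazard_ratio,
        effects={
            "response_rate_baseline": config.response_rate_baseline,
            "ebv_response_rate": config.ebv_response_rate,
            "gnaq_response_odds_multiplier": config.gnaq_response_odds_multiplier,
            "resistant_shift": config.resistant_shift,
            "responder_shift": config.responder_shift,
        },
    )
    return CohortBundle(
        clinical, expression, variants, catalogs, copy_number, panels, truth
    )


def expected_response_rate(config: CohortConfig) -> float:
    """Analytic marginal response probability implied by a configuration."""
    base = config.response_rate_baseline
    odds = base / (1 - base)
    odds_g = odds * config.gnaq_response_odds_multiplier
    p_non_ebv = (
        (1 - config.gnaq_mut_rate) * base
        + config.gnaq_mut_rate * odds_g / (1 + odds_g)
    )
    return (
        config.ebv_prevalence * config.ebv_response_rate
        + (1 - config.ebv_prevalence) * p_non_ebv
    )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write every component in the formats the io module reads, plus the
    truth record as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_clinical(bundle.clinical, outdir / "clinical.tsv")
    gio.write_expression(bundle.expression, outdir / "expression.tsv")
    gio.write_mutations(bundle.variants, outdir / "mutations.tsv")
    gio.write_segments(bundle.copy_number, outdir / "segments.seg")
    gio.write_msi_panels(bundle.msi_panels, outdir / "msi_panels.tsv")
    gio.write_json(asdict(bundle.truth), outdir / "truth.json")
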