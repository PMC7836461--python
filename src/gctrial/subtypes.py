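"""Molecular subtype calling for gastric tumors.

Two classification systems are implemented:

- TCGA-style: a precedence rule. Tumors are first called EBV (from the
  EBER in-situ hybridization assay result), then MSI (from the
  mononucleotide-repeat marker panel), and the remainder split into CIN
  versus GS by the degree of aneuploidy (fraction of the covered genome in
  copy-number-altered segments).
- ACRG-style: MSI-H tumors are MSI; microsatellite-stable tumors are
  MSS/EMT when the EMT expression signature is active, otherwise
  MSS/TP53+ or MSS/TP53- by the p53-activity signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import GeneSignature, score_signature
from .io import (ClinicalRecord, CopyNumberProfile, ExpressionMatrix,
                 MicrosatellitePanel)

TCGA_SUBTYPES = ("EBV", "MSI", "CIN", "GS")
ACRG_SUBTYPES = ("MSI", "MSS/EMT", "MSS/TP53+", "MSS/TP53-")


@dataclass
class SubtypeCall:
    sample_id: str
    tcga: str
    acrg: str
    aneuploidy_score: float
    emt_score: float
    tp53_score: float


def call_msi(panel: MicrosatellitePanel, min_unstable: int = 3) -> str:
    """MSI-H when at least ``min_unstable`` of the five markers show
    allelic size variation ("more than two" => 3), else MSS."""
    return "MSI-H" if panel.n_unstable >= min_unstable else "MSS"


def aneuploidy_score(
    profile: CopyNumberProfile,
    amp_threshold: float = 0.3,
    del_threshold: float = -0.3,
) -> float:
    """Fraction of the covered genome in copy-number-altered segments.

    A segment is altered when its log2 ratio is >= ``amp_threshold`` or
    <= ``del_threshold``; lengths are 1-based inclusive base pairs.
    """
    if not profile.segments:
        raise ValueError(f"empty copy-number profile for {profile.sample_id}")
    total = 0
    altered = 0
    for _chrom, start, end, ratio in profile.segments:
        length = end - start + 1
        total += length
        if ratio >= amp_threshold or ratio <= del_threshold:
            altered += length
    if total == 0:
        raise ValueError("zero covered length")
    return altered / total


def classify_tcga(
    ebv_status: str,
    msi_status: str,
    aneuploidy: float,
    cin_cutoff: float = 0.2,
) -> str:
    """Precedence classification: EBV > MSI > (CIN if aneuploid else GS)."""
    if ebv_status not in ("positive", "negative"):
        raise ValueError(f"unknown EBV status {ebv_status!r}")
    if msi_status not in ("MSI-H", "MSS"):
        raise ValueError(f"unknown MSI status {msi_status!r}")
    if ebv_status == "positive":
        return "EBV"
    if msi_status == "MSI-H":
        return "MSI"
    return "CIN" if aneuploidy >= cin_cutoff else "GS"


def classify_acrg(
    msi_status: str,
    emt_score: float,
    tp53_score: float,
    emt_cutoff: float,
    tp53_cutoff: float,
) -> str:
    """MSI first; then MSS tumors split by EMT activity, then p53 activity."""
    if msi_status not in ("MSI-H", "MSS"):
        raise ValueError(f"unknown MSI status {msi_status!r}")
    for score, label in ((emt_score, "EMT"), (tp53_score, "TP53")):
        if score is None or not np.isfinite(score):
            raise ValueError(f"missing {label} score")
    if msi_status == "MSI-H":
        return "MSI"
    if emt_score >= emt_cutoff:
        return "MSS/EMT"
    return "MSS/TP53+" if tp53_score >= tp53_cutoff else "MSS/TP53-"


def call_subtypes(
    clinical: list[ClinicalRecord],
    expression: ExpressionMatrix,
    profiles: list[CopyNumberProfile],
    emt_signature: GeneSignature,
    tp53_signature: GeneSignature,
    cin_cutoff: float = 0.2,
    amp_threshold: float = 0.3,
    del_threshold: float = -0.3,
    emt_cutoff: float | None = None,
    tp53_cutoff: float | None = None,
) -> list[SubtypeCall]:
    """Run both classifiers over a cohort.

    EBV and MSI statuses are taken from the clinical assay annotations.
    EMT/p53 cutoffs default to the cohort medians of the respective
    signature scores (the classifiers use signature "activity" without a
    published absolute threshold).
    """
    prof_by_id = {p.sample_id: p for p in profiles}
    emt = score_signature(expression, emt_signature)
    tp53 = score_signature(expression, tp53_signature)
    if emt_cutoff is None:
        emt_cutoff = float(emt.median())
    if tp53_cutoff is None:
        tp53_cutoff = float(tp53.median())
    calls = []
    for rec in clinical:
        sid = rec.sample_id
        if sid not in prof_by_id:
            raise ValueError(f"no copy-number profile for sample {sid}")
        fga = aneuploidy_score(prof_by_id[sid], amp_threshold, del_threshold)
        calls.append(
            SubtypeCall(
                sample_id=sid,
                tcga=classify_tcga(rec.ebv_status, rec.msi_status, fga, cin_cutoff),
                acrg=classify_acrg(
                    rec.msi_status, float(emt[sid]), float(tp53[sid]),
                    emt_cutoff, tp53_cutoff,
                ),
                aneuploidy_score=fga,
                emt_score=float(emt[sid]),
                tp53_score=float(tp53[sid]),
            )
        )
    return calls


def subtype_counts(calls: list[SubtypeCall]) -> dict[str, dict[str, int]]:
    tcga = pd.Series([c.tcga for c in calls]).value_counts().to_dict()
    acrg = pd.Series([c.acrg for c in calls]).value_counts().to_dict()
    return {
        "tcga": {s: int(tcga.get(s, 0)) for s in TCGA_SUBTYPES},
        "acrg": {s: int(acrg.get(s, 0)) for s in ACRG_SUBTYPES},
    }
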