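# gctrial

Integrative molecular analysis for single-arm phase II gastric-cancer
trials, built as a reusable, fully tested pipeline. It implements the
analysis stack typically wrapped around a ~60-patient trial of an
anti-angiogenic doublet (ramucirumab plus paclitaxel) with pre-treatment
whole-exome and whole-transcriptome profiling:

- **Molecular subtyping** — TCGA-style precedence calls
  (EBV → MSI → CIN/GS by fraction of genome altered) and ACRG-style calls
  (MSI, MSS/EMT, MSS/TP53±) from assay statuses, copy-number segments and
  expression-signature activity; the literal "more than two of five
  unstable mononucleotide markers" MSI rule.
- **Expression signatures** — log10 + quantile normalization of FPKM,
  arithmetic and geometric signature scores, single-sample GSEA
  (weighted running-sum enrichment, weight exponent α), responder vs
  non-responder differential expression (Wilcoxon rank-sum,
  Benjamini–Hochberg), and derivation of a treatment-resistant signature
  from genes up in non-responders (|log2FC| > 0.5, p < 0.05).
- **Mutational signatures** — 96-channel trinucleotide catalogs
  (pyrimidine-reference), exome-composition re-weighting, and exposure
  fitting by nonnegative least squares under a total-exposure cap with
  iterative dropping of contributions below 6%.
- **Response statistics** — RECIST best-change categorization, response
  rates with Wald confidence intervals, 2×2 chi-squared association
  tests, and exact binomial operating characteristics of two-stage
  designs (for the trial's design n1=30/r1=4, n=58/r=13: one-sided
  α = 4.35% at p0 = 0.15, power 86% at p1 = 0.30).
- **Survival** — Kaplan–Meier, log-rank, and Cox proportional hazards
  (Breslow ties, damped Newton–Raphson).
- **Integrative selection** — elastic-net stability selection
  (coordinate descent with soft-thresholding; penalized Cox via IRLS):
  100 random 80% subsamples per endpoint, features ranked by appearance
  count and average weight.
- **Synthetic cohorts** — a generator that plants the structure the
  analysis assumes (EBV(+) and GNAQ-mutant response effects, a resistant
  expression program with a proportional-hazards survival effect,
  COSMIC-style signature mixtures, CIN/GS aneuploidy regimes) so every
  stage is testable without patient data, which cannot be publicly
  shared for such trials.

## Worked example

```python
import numpy as np
import gctrial as g

# a 62-patient synthetic cohort at the default (trial-like) conditions
bundle = g.generate_cohort(g.CohortConfig(n_patients=62, seed=1, n_genes=400))

# response rate with Wald CI
responders = sum(r.response_category in ("CR", "PR") for r in bundle.clinical)
print(g.orr_with_ci(responders, 62))
# -> 35.5% (22/62; 95% CI 23.6-47.4)

# two-stage design operating characteristics (exact)
design = g.TwoStageDesign(n1=30, r1=4, n_total=58, r_total=13, p0=0.15, p1=0.30)
alpha, _, _ = g.two_stage_operating_characteristics(design, 0.15)
power, _, _ = g.two_stage_operating_characteristics(design, 0.30)
print(f"type I error {100*alpha:.2f}%, power {100*power:.1f}%")
# -> type I error 4.35%, power 86.1%

# mutational-signature exposures for the highest-burden sample
sigs = g.synthetic_signature_matrix()
cat = max(bundle.catalogs, key=lambda c: c.n_snvs)
exposure = g.deconvolve(cat.frequencies(), sigs)
top = {s: round(float(w), 2) for s, w in zip(exposure.signature_ids, exposure.weights) if w > 0}
print(top)
# -> {'Signature.1': 0.57, 'Signature.3': 0.12, 'Signature.17': 0.31}
```

The first line is the simulated cohort's objective response rate (the
generator plants a ~35% marginal rate; this seed draws 22 responders of
62, with the Wald interval the package uses throughout); the last line
shows fitted signature exposures recovering the generator's
0.6/0.25/0.15 mixture from 284 substitutions.

A command-line interface mirrors the library:

```bash
gctrial simulate --seed 1 --out cohort/
gctrial classify --clinical cohort/clinical.tsv --expression cohort/expression.tsv \
    --segments cohort/segments.seg --gene-sets sets.gmt --out calls/
gctrial integrate --cohort cohort/ --endpoint tumor_reduction --out selection/
```

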