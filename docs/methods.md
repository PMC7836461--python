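# Methods

This note documents the models implemented in `gctrial`, the defaults
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices behind each solver.

## Molecular subtyping

TCGA-style classification is a precedence rule over assay results and a
copy-number summary: tumors positive by EBER in-situ hybridization are
EBV; of the rest, MSI-H tumors (≥3 of the 5 mononucleotide-repeat markers
BAT-25, BAT-26, NR-21, NR-24, NR-27 unstable — the literal "more than
two" convention; the more common ≥2 rule is available via the
`min_unstable` parameter) are MSI; the remainder are CIN when the
fraction of genome altered (FGA) is at least the CIN cutoff, else GS.
FGA is the base-pair fraction of covered genome in segments with
|log2 ratio| beyond the amplification/deletion thresholds (±0.3 by
default); the CIN cutoff defaults to 0.2. Neither threshold has a
published canonical value for this rule, so all three are exposed in
configuration; the defaults cleanly separate the generator's two
aneuploidy regimes and are in the range used for FGA-based chromosomal
instability calls generally.

ACRG-style classification checks MSI first, then EMT signature activity,
then p53 activity. Published descriptions use signature "activity"
without absolute thresholds, so the cutoffs default to cohort medians of
the respective scores and are configurable.

## Expression

FPKM matrices are normalized by `log10(FPKM + 1)` followed by quantile
normalization against the mean of the column-sorted vectors. FPKM can be
exactly zero, hence the pseudocount of 1 (configurable). Ties within a
column receive the mean of the reference values at their tied ranks; as
a consequence, exact equality of per-sample sorted vectors holds for
tie-free data, while tied data (e.g. many zero FPKMs) deviates only at
the tied ranks.

Signature scores are per-sample means of member-gene values: arithmetic
on the normalized log scale (`score_signature`), or the geometric
average — mean log10 of raw intensities (`score_geometric`). Scoring
requires at least 50% of a signature's genes to be present
(configurable).

ssGSEA ranks a sample's genes by decreasing expression and walks the
ranking: in-set genes add increments proportional to |value|^α
(normalized to sum to one over the set), out-of-set genes subtract
uniform steps; the score is the integrated difference of the two
cumulative processes. α defaults to 0.75, the weighting of the method
this implementation follows. By default scores are rescaled by the
global score range across samples and sets (`normalize=False` to
disable).

Differential expression compares confirmed responders (PR; no CR arises
in the emulated setting) against non-responders (SD/PD); non-evaluable
samples are excluded. Because fold changes are conventionally reported
in log2 units, the normalized log10 group-mean differences are rescaled
by 1/log10(2). The test is the two-sided Wilcoxon rank-sum (robust at
group sizes around 20–30; Welch's t available), with Benjamini–Hochberg
adjusted p-values reported alongside raw ones. Volcano-style calls and
the resistant-signature derivation use raw p < 0.05 and |log2FC| > 0.5,
matching the usual presentation of such analyses; the resistant
signature is the set of genes up in non-responders under those cutoffs,
ordered by ascending p and capped (default 200 genes).

## Mutational signatures

Single-base substitutions are counted into 96 channels (six
pyrimidine-reference substitution classes × 16 flanking-base
combinations); purine-reference records are folded onto the reverse
complement. Indels and multi-base events are skipped with a logged
count. Catalog re-weighting multiplies each channel by the ratio of
target to source frequency of its trinucleotide context (32-context
tables; uniform target by default) and renormalizes — this expresses
either exome→genome or exome→uniform conventions depending on the
tables supplied.

Exposure fitting solves min ‖p − Sw‖² subject to w ≥ 0 and Σw ≤ 1.
`scipy.optimize.nnls` solves the uncapped problem; when its solution
violates the cap, projected gradient descent (step 1/L, L the squared
spectral norm; projection onto the capped simplex) takes over and is
monotone in the objective. Signatures with fitted weight below
`min_contribution = 0.06` are dropped and the fit repeated until the
active set is stable — the convention of established signature-refitting
tools. Note that dropping a signature restricts the feasible set, so the
refit objective may rise slightly; monotonicity holds within the solver,
not across drops. A 30-column synthetic signature matrix (peaked
Dirichlet draws; clearly labelled synthetic) ships for simulation and
testing; real catalogs are supplied as TSV.

## Response statistics

RECIST best-overall-response categories use −100 → CR, ≤ −30 → PR,
≥ +20 → PD, else SD. Response rates carry Wald normal-approximation
intervals clipped to [0, 100] — the interval form that reproduces the
reference arithmetic for 22/62 exactly; Fisher's exact test is available
for small cells, and the chi-squared test defaults to no continuity
correction. Two-stage design operating characteristics are exact
binomial sums (no normal approximation): accept iff X1 > r1 and
X1 + X2 > r_total. The mutational-burden stratification threshold is
"more than 100" non-synonymous mutations.

## Survival

Kaplan–Meier and the two-group log-rank test are standard. The Cox model
maximizes the Breslow-ties partial likelihood by Newton–Raphson with
step-halving, converging at gradient ∞-norm < 1e-8 (max 100 iterations);
standard errors come from the inverse observed information.
Zero-variance covariates get coefficient 0; coefficient blow-up beyond
|β| > 50 is flagged as likely separation. Signature–survival analyses
dichotomize scores at the cohort median by default (configurable
quantile), and both log-rank and Cox outputs are produced.

## Integrative stability selection

The feature table stacks standardized blocks: the top-V most variable
genes of the normalized expression matrix (default 2000, far fewer in
small-cohort analyses — n ≈ 50–150 cannot support whole-transcriptome
fitting), 0/1 indicators for genes somatically mutated in at least 3
samples, the fraction of genome altered, and the EBV/HER2 assay
indicators. Constant features are dropped.

The linear elastic net minimizes
(1/2n)Σ(yᵢ − β₀ − xᵢβ)² + λ[α‖β‖₁ + (1−α)/2‖β‖₂²]
by cyclic coordinate descent with soft-thresholding and active-set
sweeps; convergence is declared when a full sweep changes no coefficient
by more than `tol` (1e-6 by default; tests tighten it to 1e-13 when
matching closed forms). Survival endpoints use the penalized Cox
variant: IRLS re-linearization of the Breslow partial likelihood with
the same inner loop. At λ = 0 its fixed point solves the unpenalized
score equations exactly, which the tests verify against the
Newton–Raphson fit.

Stability selection draws ⌈0.8n⌉ samples without replacement (a
with-replacement option exists) 100 times, fits at a fixed penalty, and
reports each feature's appearance count and its mean coefficient over
the iterations where it was selected (features never selected report
weight 0 with a flag). Ranking is by appearance count, ties broken by
|mean weight|. The penalty is chosen once on the full cohort and held
fixed so counts are comparable across iterations. Three choices are
implemented: a fixed value, 5-fold cross-validation with the
one-standard-error rule, and the default for selection —
tuning λ so the full-cohort fit keeps about 15 features. The model-size
calibration is the standard prescription for stability selection:
cross-validated-minimum penalties optimize prediction, not selection,
and at these sample sizes they admit so many features that appearance
counts saturate at 100 and lose their ranking value, while the
one-standard-error rule is too variable at n ≈ 60–150 (occasionally
keeping a single feature). α defaults to 0.5.

## The synthetic cohort generator

The generator emulates a ~60-patient metastatic gastric-cancer trial
cohort: EBV(+) and MSI-H counts fixed at round(prevalence·n) (defaults
4.8% and 0 — composition is a design fact of the emulated cohort, not a
sampling outcome), CIN assigned among the rest at 37.5%, baseline
response probability 0.30 with EBV(+) tumors responding at rate 1.0 and
GNAQ-mutant tumors (rate 0.16) at 6× the baseline odds. Responders draw
best tumor reductions uniformly in [−65, −31] and non-responders in
[−25, +35]; the planted drivers additionally deepen the reduction
(EBV −30 points, GNAQ −12, clipped so RECIST categories are preserved) —
the planted clinical drivers are deliberately the dominant predictors,
which is the cohort structure the selector is asserted to recover.

Expression is log-normal per gene (baseline log10 mean ~N(1, 0.5²),
per-sample noise SD 0.35); a 40-gene resistant program is shifted up
+0.15 log10 in non-responders and a 15-gene responder program up in
responders (strong-effect test configurations raise these to 0.6).
Survival times are exponential with hazard multiplied by HR^z where z is
the cohort-standardized resistant-signature score (realized from the
emitted FPKM, so recovery tests fit exactly the planted covariate) and
HR defaults to 2.0; median OS ~10 months and PFS ~4.4 months at the mean
score, PFS capped at OS. Censoring is administrative: each endpoint is
censored with the configured probability at a uniform fraction of its
event time. Mutation burdens are Poisson with a lognormal rate
(σ = 0.8) around mean 75 — the overdispersion places roughly a quarter
of samples above 100 mutations, matching the high/low-burden split the
cohort is modeled on; channels are multinomial draws from the configured
signature mixture, written as variant rows over an exome-scale gene pool
(6000 genes) with random strand presentation, plus one GNAQ missense
variant per carrier. Copy-number profiles target FGA 0.35–0.60 for CIN
and < 0.12 otherwise, with neutral segments jittered well inside the
±0.3 thresholds. All draws come from per-component child streams of the
root seed (fixed offsets), so adding a component never perturbs existing
ones and identical configs are byte-identical.

What the generator does **not** emulate: read-level data, germline
variation, gene-gene correlation structure beyond the planted programs,
subtype-specific expression programs, indel/doublet mutational
processes, informative censoring, or any separation of the two drugs'
effects. Passing tests therefore demonstrate correctness of the
*procedures* and recoverability of *planted* structure, not performance
on real cohorts. GNAQ mutation and EBV status are generated
independently (their joint distribution in real cohorts is unknown).

## Problem sizes in the default suite

The default test run uses cohorts of 62–150 patients with 400 genes
(1000 patients for hazard-ratio recovery), 10 round-trip fixtures per
format, 100 deconvolution mixtures, 1000-replicate null calibrations for
the log-rank test, and 20 cohorts for stability-selection recovery —
sizes chosen to exercise every code path at meaningful statistical
resolution while keeping the suite fast to iterate on.

## Known limitations

- The exposure solver's drop-and-refit loop uses an absolute weight
  threshold; with many near-duplicate signature columns the selected
  support can differ from the truth while fitting the profile equally
  well (the tests' synthetic matrix has well-separated columns; real
  catalogs with collinear signatures inherit the usual identifiability
  caveats).
- The penalized Cox IRLS uses the diagonal Hessian approximation for its
  working weights; convergence is to the exact stationary point but can
  be slow near separation.
- Wald intervals degenerate at observed rates of 0% or 100%; they are
  clipped rather than replaced (Wilson/Clopper–Pearson are deliberately
  not silently substituted, to keep the arithmetic the reference uses).
- The MSI caller implements the literal ≥3-of-5 rule; panels from other
  marker sets are out of scope.
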