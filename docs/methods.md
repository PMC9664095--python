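# Methods

`stromasig` implements a subtype-specific prognostic-signature discovery
pipeline for bulk transcriptomics of localised colon cancer, together with a
synthetic-cohort generator that plants the exact statistical structure the
pipeline is designed to detect. This note records the models, the defaults
and why, the numerical choices, and what the synthetic experiments do and do
not establish about real data.

## The scientific problem

Stroma-rich (high-fibroblast, "HiFi") colon tumours are a poor-prognosis
subgroup, yet roughly half of them never relapse. The pipeline asks what
separates relapsing from non-relapsing tumours *within* the stroma-rich
stratum — biology that is invisible to unstratified analyses because it
carries no prognostic information in the stroma-low ("LoFi") majority. The
working model, encoded in the simulator, is that an interferon/STAT1-like
immune program is protective only where the stromal context makes it matter.

## Single-sample gene-set scoring (ssGSEA)

For sample *j*, genes are ordered by decreasing expression (ties broken by
gene symbol, so scores are reproducible to the bit). A gene at position *i*
of *N* carries rank value *N − i + 1*. With gene set *S* and exponent α, the
score is

    ES_j(S) = Σ_i [ P_hit(i) − P_miss(i) ],

where P_hit is the empirical CDF over members of *S* weighted by rank^α
(normalised to 1) and P_miss is the uniform CDF over non-members. α defaults
to 0.25, the common ssGSEA convention; it is exposed in every interface.
Because the statistic depends only on within-sample ranks, it is invariant
under any strictly monotone transform of one sample's values — the property
that makes the score portable across platforms, and which the tests assert
directly. Global (max−min) normalisation of a score matrix is available but
off by default: every downstream use here (median splits, Pearson
correlations, cutoff searches) is invariant to positive rescaling.

The composite **fibroblast score** is the ssGSEA score of the MCP-style
fibroblast signature augmented with the canonical myofibroblast markers
ACTA2 and FAP.

**Signature application** uses `mean_z` by default: the mean over present
signature genes of within-cohort z-scored expression. How "signature
expression" should be aggregated before a median split is genuinely
underspecified in this literature; mean-z was chosen because it is robust to
platform-specific gene-level scale differences. `sum` (cumulative log2
expression) and ssGSEA scoring of the signature are available alternatives;
on a median split all three produce very similar dichotomies when the
signature genes are positively correlated.

## Survival machinery

Kaplan–Meier estimation, the two-group log-rank test, Cox
proportional-hazards fits with Efron tie handling and the
scaled-Schoenfeld-residual proportional-hazards diagnostic (against
Kaplan–Meier-transformed time) are delegated to `lifelines`. A Breslow-ties
fit is provided by an in-house partial-likelihood maximiser (BFGS with a
numeric Hessian for Wald standard errors); with no tied event times the two
agree, which the tests verify. The PH diagnostic always uses the Efron-fit
residuals, whichever tie correction produced the point estimates.

Stratification methods:

- **Optimal prognostic cutoff**: every observed score value that leaves at
  least 10% of samples on each side is evaluated as a `High = score ≥ c`
  split; the log-rank chi-square is maximised, with ties broken toward the
  cutoff nearest the score median. The selected statistic is reported
  *unadjusted* and the function emits an explicit selection-inflation
  warning: a maximally selected statistic is not a nominal test and must be
  validated out-of-cohort.
- **Top-fraction split**: exactly ⌈f·n⌉ samples labelled High, ordering by
  descending score then sample id so the count is exact under ties (the
  validation-cohort convention, f = 0.20).
- **Median split**: High = score ≥ median. Degenerate tie patterns that put
  every sample on one side raise an error rather than returning a vacuous
  split. The ≥ rule is configurable in spirit but fixed here and documented.
- **Youden/ROC cutoff**: AUROC by rank statistic; the cutoff maximising
  sensitivity + specificity − 1, placed midway between adjacent observed
  scores. When AUROC < 0.5 (a protective score), the rule is oriented the
  other way before maximising, otherwise the "optimum" collapses to a
  boundary cutoff.

**Relapse labelling** for the supervised contrast: relapse = event within
the horizon (default 60 months); non-relapse = event-free at any follow-up
length. Patients censored early therefore count as non-relapse but are
flagged as low-follow-up; events after the horizon are excluded and listed.
This is the "never relapsed" reading of the contrast; it slightly dilutes
the non-relapse class with short-follow-up patients, which is conservative
for discovery.

## Two-class GSEA and leading-edge analysis

Genes are ranked by the signal-to-noise metric (μ_A − μ_B)/(σ_A + σ_B),
each class standard deviation floored at max(0.2·|μ|, 0.2) (the standard
convention preventing low-variance genes from dominating). The enrichment
score is the signed maximum deviation of the weighted running sum (hits
weighted |metric|^p, p = 1 by default; misses uniform). Because the running
sum is piecewise linear between hits, its extrema are evaluated only at
hit boundaries, which makes the permutation null cheap without changing the
statistic; the tests compare against a position-by-position oracle.

The null is built from seeded phenotype-label permutations. NES = ES divided
by the mean |permuted ES| of the same sign; nominal p is the same-sign tail
fraction with an add-one correction; FDR q follows the GSEA convention of
comparing each NES against the pooled permuted-NES distribution (a BH
alternative on nominal p is available behind a flag). With fewer than 7
samples in a class, phenotype permutation is too coarse and the engine falls
back to gene-set (random member) permutation, with a warning.

**Leading-edge overlap**: sets passing q < 0.15 in the stated direction
contribute their leading edges; genes appearing in ≥ 2 of them become
candidate genes. The q < 0.15 threshold mirrors the adjusted-p convention
used for set-level screening in this literature and is configurable.

## Two-stage Cox filter

Each candidate gene is dichotomised at its median expression within the
analysis stratum. Stage 1 keeps genes with univariate Cox likelihood-ratio
p < 0.20; stage 2 keeps those whose gene-term Wald p in the
covariate-adjusted model (age, sex, pT stage, tumour location,
differentiation grade, mucinous subtype, lymphovascular invasion, lymph-node
count) is < 0.05. Thresholds are applied raw — no multiplicity correction —
matching common practice for this filtering style; the selection is
anticonservative by construction, which is why validation is always
out-of-stratum and ideally out-of-cohort. The published 7-gene signature
(FGL2, PSME1, SP110, WARS, CCND2, CCND3, PNPT1) ships as a read-only GMT
fixture so validation-mode runs need no discovery step; it is data, not a
computed result.

The direction convention — high signature expression is protective (HR < 1)
— is asserted by sign-checking the fitted hazard ratios and reported; a
discovered signature with HR > 1 is flagged, never silently flipped.

## Differential expression and the threshold signature builder

Per-gene Welch t-tests on log2 values, BH adjustment across all tested
genes; genes flat in both groups get p = 1 with a flag. Cross-cohort
intersection requires BH-adjusted p below threshold in *both* cohorts and a
consistent direction; discordant genes are reported, not dropped. The
threshold-based signature builder (default log2FC > 2 and adjusted
p < 0.001, sized for a strong treatment contrast such as a TLR3-agonist
stimulation) filters a DE table into a signature, with an optional
two-column orthology table for cross-species use; "logFC" is interpreted as
log2 fold change.

## The synthetic cohort generator

Per sample *i*: a binary stromal factor s_i (1 for a fraction 0.35 of
samples — the discovery cohort's stroma-rich share; a continuous variant is
available) and an interferon factor f_i ~ N(0,1). Expression on log2 scale:

    x_gi = μ_g + a_g·s_i + b_g·f_i + ε_gi,   ε ~ N(0, 1),  μ_g ~ N(7, 1.5²)

with a_g = 1.5 on a 25-gene stromal program (including ACTA2 and FAP),
b_g = 1.0 on 7 planted signature genes and 0.6 on a 60-gene
interferon-response pool, zero elsewhere (2000 genes total, 400 samples).
The gene-set collection emitted alongside contains the stromal set, six
overlapping interferon-response sets (all seven signature genes plus random
pool draws — so leading-edge overlap is non-trivial) and twelve random decoy
sets.

Relapse times are exponential with per-sample rate

    h_i = h0 · exp(β_s·s_i + β_f·f_i + β_int·s_i·f_i),

censored by the minimum of a 120-month administrative horizon and
exponential dropout (rate 0.003/month). Defaults: h0 = 0.0025/month,
β_s = 1.0, β_f = 0, β_int = −0.8. The interaction-only interferon effect is
the core design: the protective program carries prognostic information in
the stromal-high stratum and none in the stromal-low stratum. These effect
sizes are this package's own choice — no published values exist for the
latent program — and were set so that (a) per-stratum event fractions land
near the relapse rates reported for real stroma-rich vs stroma-poor stage II
cohorts (~48% vs ~24% here), and (b) recovery by the pipeline is neither
trivial nor impossible. One consequence worth knowing: the interferon
interaction acts as a frailty inside the stromal-high stratum, which
genuinely flattens the log-rank landscape around the stratum boundary; with
a weaker stromal contrast the maximally selected cutoff wanders tens of
samples from the planted boundary.

Everything derives from one seed via `numpy.random.SeedSequence` spawning,
so identical configs give byte-identical cohorts. The exponential/uniform
censoring structure gives every event-fraction a closed form that the tests
check by numeric integration.

**What the simulator does not emulate**: microarray probe-level artefacts,
batch effects, platform differences, correlated covariates (an optional
age-confounding mode exists but is off by default), non-proportional
hazards, and the cellular heterogeneity underlying real deconvolution
scores. Passing recovery tests therefore demonstrate that the pipeline's
statistics behave as designed under its own model assumptions — calibrated
nulls, correct oracles, recoverable planted effects — not that the
biological findings of any particular cohort are reproduced.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the heavy batteries at sizes
chosen for a single CPU: end-to-end discovery uses 200 GSEA permutations per
cohort (the `analysis/` drivers use 500, and 1000 is the pipeline default),
8–20 seeded replicate cohorts per battery, and 100-replicate Cox coverage
simulations. All randomness flows
from explicit seeds; derived seeds stay below 2³¹.

## Known limitations

- The GSEA-style FDR uses the pooled permuted-NES distribution; with few
  gene sets the q estimate is coarse (the BH alternative is steadier there).
- The Breslow Cox path computes Wald intervals from a numeric Hessian; for
  large designs the Efron/lifelines path is both faster and better tested.
- The maximally selected cutoff reports an unadjusted statistic; no
  selection-corrected p-value (e.g. improved Bonferroni bounds for maximally
  selected rank statistics) is implemented.
- `validate_signature` skips strata with fewer than 10 samples rather than
  attempting a fit.
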