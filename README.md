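# stromasig

Prognostic-signature discovery for stroma-rich colon cancer, as a tested,
reusable Python pipeline.

Stroma-rich ("high-fibroblast", HiFi) tumours are the worst-prognosis
subgroup of localised colon cancer, yet about half of them never relapse.
This package implements the analysis chain that asks *what distinguishes the
relapsing from the non-relapsing tumours inside that stratum*:

1. **Fibroblast scoring** — single-sample GSEA (ssGSEA) of a fibroblast
   signature augmented with ACTA2/FAP gives every sample a stromal-content
   score from expression alone.
2. **Stratification** — an optimal prognostic cutoff (maximally selected
   log-rank statistic on relapse-free survival), a top-fraction split
   (e.g. top 20%), or a median split divides the cohort into High/Low
   fibroblast strata.
3. **Supervised GSEA + leading-edge analysis** — within the High stratum,
   relapse-within-5-years vs never-relapsed samples are contrasted by
   signal-to-noise ranking; a phenotype-permutation GSEA finds gene sets
   associated with outcome, and genes shared by ≥2 leading edges become
   candidates.
4. **Two-stage Cox filter** — each candidate, median-dichotomised, must pass
   a univariate Cox likelihood test (p < 0.20) and then a covariate-adjusted
   multivariate Cox test (p < 0.05) to enter the final signature.
5. **Validation** — the signature is scored in an independent cohort,
   median-split within each stratum, and tested by log-rank/Cox; the
   expected pattern is strong protection (HR < 1) in the High stratum and a
   null result in the Low stratum. Differential expression with BH
   correction, cross-cohort intersection, and a threshold-based signature
   builder (log2FC and adjusted-p cutoffs) complete the validation toolkit.

Because the real cohorts behind such analyses are external accessions, the
package ships a first-class **synthetic cohort generator** that plants the
assumed structure — a stromal expression program, an interferon/STAT1-like
program, and relapse hazards in which the interferon factor is protective
*only* in stromal-high samples — with a full ground-truth ledger, so every
stage of the pipeline is testable at desk scale. The published 7-gene
signature (FGL2, PSME1, SP110, WARS, CCND2, CCND3, PNPT1) is included as a
read-only GMT fixture for validation-mode runs.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts. From the repository root:

```bash
python analysis/01_simulate_cohorts.py   --seed 1 --out results
python analysis/02_score_and_stratify.py --out results
python analysis/03_discover_signature.py --seed 1 --out results
python analysis/04_validate_signature.py --out results
python analysis/05_de_intersection.py    --out results
```

which prints (seed 1):

```
discovery: 400 samples, 119 events; event rate stromal-high 0.450 vs stromal-low 0.215
validation: 400 samples, 118 events; event rate stromal-high 0.464 vs stromal-low 0.204
discovery (optimal_cox): High 140 / Low 260; stratum log-rank p=8.72e-07; truth-label agreement 1.000
validation (top_fraction): High 80 / Low 320; stratum log-rank p=8.25e-04; truth-label agreement 0.850
GSEA: 7 gene sets at q<0.15; LEA candidates: 38; signature: 30 genes (6/7 planted recovered)
High stratum (n=80, events=33): log-rank p=0.002345, HR=0.329, adjusted HR=0.293
Low stratum (n=320, events=85): log-rank p=0.08039, HR=0.683, adjusted HR=0.684
cross-cohort intersection: 58 up, 0 down, 0 discordant
```

Reading this: the fibroblast score recovers the planted stromal stratum
essentially perfectly in the discovery cohort; the stromal-high group
relapses at roughly twice the rate of the stromal-low group; supervised GSEA
inside the High stratum finds the planted interferon-response sets; the Cox
filter recovers 6 of the 7 planted prognostic genes (plus correlated pool
genes); and in the *independent* validation cohort the discovered signature
splits the High stratum strongly (HR ≈ 0.33, high expression protective)
while remaining non-significant in the Low stratum — the stratum-specific
pattern the pipeline exists to detect.

The same stages are available as a CLI (`stromasig simulate|score|stratify|
gsea|discover|validate|de|report`) driven by flags or a YAML config, and as
plain library calls:

```python
import stromasig as sg

cohort = sg.generate_cohort(sg.CohortConfig(seed=1))
score  = sg.ssgsea_score(cohort.expression,
                         sg.fibroblast_geneset(cohort.genesets["MCP_FIBROBLAST"]))
strata = sg.optimal_cox_cutoff(score, cohort.clinical)
report = sg.discover_signature(cohort.expression, cohort.clinical,
                               cohort.genesets, strata, seed=1)
print(report.signature.genes)
```

## File formats

Expression: gene-by-sample TSV or GCT 1.2, log2 scale, unique uppercase
symbols. Clinical: TSV with `sample`, `rfs_months`, `event` plus covariate
columns. Gene sets: GMT. All outputs (scores, strata, KM curves, Cox
tables, DE tables, manifests) are TSV/JSON.

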