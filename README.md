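# radscreen

Screening genes for **radio-sensitivity** from expression + survival
cohorts: which genes mark patients who actually benefit from radiotherapy?

Oncology cohorts (e.g. TCGA tumor collections) record gene expression,
overall survival, whether each patient received radiotherapy, and clinical
covariates with missingness.  A naive comparison of treated vs untreated
survival within one expression group confounds prognosis with benefit.
`radscreen` implements an *interaction-model* screen instead: for each gene
it splits the cohort at the median expression, crosses the split with the
treatment indicator (HRT / LRT / HNRT / LNRT), and requires a coherent
pattern across four adjusted Cox proportional-hazards analyses before
calling a gene radio-sensitive (RS).

## The model

For a gene g with median-split indicator `High`, the screen asks, on
multivariate Cox models h(t|x) = h0(t)·exp(βᵀx) adjusted for a frozen
covariate set:

- **A**: within `High = 1`, is radiotherapy retained by AIC fast-backward
  selection with HR < 1?
- **B**: the same within `High = 0`;
- **C**: within the treated arm, is `High` associated with OS (Wald
  p < 0.05)?
- **D**: the same within the untreated arm.

A gene is RS iff (A or B) and *exactly one* of {C, D} holds.  C alone ⇒
**Type I** (expression modifies the treatment effect but carries no
prognostic signal on its own); D alone ⇒ **Type II** (prognostic without
treatment; radiotherapy erases the disadvantage).  A ⇒ **RGH** (the
high-expression group captures the benefit), B ⇒ **RGL**.

Around this core the package provides the full pipeline: eligibility
filtering (tumor samples, complete survival/treatment data, survival ≥ 5
days) and a dataset-level screen that only admits cohorts where
radiotherapy is protective (HR < 1, p < 0.05); chained-equation multiple
imputation of clinical covariates (< 20% missing) with *stacking* — M
completed copies concatenated at weight 1/M and analyzed by one weighted
Cox fit with subject-clustered sandwich errors; a fast exact Cox solver
(Efron ties, weights, warm starts) with AIC backward elimination;
Kaplan–Meier / log-rank / Wilcoxon / categorized Pearson utilities; patient
clustering on gene panels with per-cluster treatment benefit tests; and a
synthetic-cohort generator that plants known Type I / Type II / null genes
so the whole pipeline can be validated against ground truth.

## Worked example

`python examples/03_discover_rs_genes.py` generates the standard recovery
cohort (n = 1500; 50 null, 10 Type I, 10 Type II genes; treatment HR 0.6;
~20% censoring; 10% missingness on two covariates), runs the screen and the
per-gene discovery, and scores the calls against the planted truth:

```
radiotherapy screen: HR 0.67 (p 9.7e-12) -> keep
adjusters retained at cohort level: ['age_group', 'chemotherapy', 'stage']
25/70 genes called radio-sensitive
  NULL001: Type II both (C HR 1.02 p 0.796; D HR 0.80 p 0.00754)
  ...
sensitivity 0.95, false-positive rate 0.12, type accuracy 1.00
```

Reading the numbers: the cohort passes the protective screen (marginal
treatment HR 0.67); all three planted confounders survive backward
selection; 19 of the 20 planted RS genes are recovered with their Type I/II
labels correct, at the cost of 6 false positives among the 50 null genes —
each a gene whose C/D p-value crossed 0.05 by chance, the expected order of
magnitude since the call requires exactly one of two 5%-level tests to
reject.

## Layout

```
src/radscreen/
  config.py      run configuration, clinical schema declarations
  io.py          TSV readers/writers (expression, clinical, RS calls)
  synthetic.py   cohort generator with planted effects + recovery scoring
  prep.py        tumor filtering, eligibility, protective screen
  engine.py      Cox solver, AIC fast-backward, KM, log-rank, Wilcoxon
  impute.py      chained-equation imputation, stacking, weighted fits
  discovery.py   dichotomization, scenarios A-D, Type I/II classification
  downstream.py  correlation, clustering, extreme-survivor contrast
  cli.py         thin command-line front end
docs/methods.md  model, assumptions, numerical choices, limitations
```
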