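# Methods

`radscreen` screens genes for *radio-sensitivity*: a gene is called
radio-sensitive (RS) when patients with different expression levels of that
gene obtain discrepantly sized survival benefits from radiotherapy.  This
note records the statistical model, the decision rules, the synthetic data
the package validates itself on, and the numerical choices a maintainer
would want to know about.

## The interaction model and the scenario rules

For each gene the cohort is dichotomized at the within-cohort median of that
gene's expression (high iff strictly above the median; values exactly at the
median go to the low group).  Crossing the split with the radiotherapy
indicator yields four groups: HRT, LRT, HNRT, LNRT.  Four subgroup analyses
follow, all on multivariate Cox proportional-hazards models with a frozen
cohort-level adjuster set (below):

- **Scenario A** — within the *high* subset, radiotherapy is offered to AIC
  fast-backward selection together with the adjusters; A holds when
  radiotherapy is *retained* with hazard ratio < 1.
- **Scenario B** — the same within the *low* subset.
- **Scenario C** — within the *treated* subset, the high-vs-low indicator is
  added to the adjusters and C holds when its two-sided Wald p < alpha
  (default 0.05).
- **Scenario D** — the same within the *untreated* subset.

A gene is RS iff (A or B) holds and *exactly one* of C/D holds.  C alone
marks **Type I** (expression matters only under radiotherapy — no prognostic
effect without treatment); D alone marks **Type II** (prognostic without
treatment, the disadvantage erased by radiotherapy).  A holding makes the
gene **RGH** (the high-expression group captures the benefit), B **RGL**,
both "both".  Genes with C and D both holding are not called and are flagged
ambiguous.  The asymmetry between the retention criterion (A/B) and the Wald
criterion (C/D) is deliberate and mirrors how the two questions differ:
A/B ask whether treatment still earns its place in the model inside a
subgroup; C/D ask whether expression carries independent prognostic signal
inside a treatment arm.

Two open choices are exposed as config switches and default to the rule set
above: `require_p_for_ab` additionally demands Wald p < alpha for A/B
(retention-only by default), and `reselect_cd` re-runs backward selection
inside the C/D subsets instead of using the frozen adjusters.

No multiple-testing correction is applied across the gene panel by default
(`bh_correction` enables Benjamini–Hochberg on the C/D p-values).  The RS
call already conjoins several significance events, which makes it
conservative: on all-null panels the call rate is close to
2·alpha·(1−alpha), not alpha.

### Adjuster selection and missing data

Clinical covariates with missingness in (0, 20%) are multiply imputed by
chained equations: missing cells are initialized by random draws from the
observed values, then covariates are cycled ten times, continuous targets
imputed by predictive-mean matching (5 donors) and categorical targets by
draws from a multinomial logistic model on the other covariates plus the
outcome (event indicator and log survival time) — the standard predictor
set for survival imputation.  Covariates at or above the 20% cap leave the
covariate pool.  Survival time, the event indicator and radiotherapy are
never imputed; samples missing them were removed at eligibility.

The M (default 10) completed copies are *stacked*: concatenated with weight
1/M and the subject id carried through.  Analysis models are weighted Cox
fits on the stack with subject-clustered sandwich standard errors — the
stacking alternative to pooling M separate fits by combining rules.  The
cohort-level adjuster set is selected once, before the per-gene loop, by AIC
fast-backward over radiotherapy plus all imputable covariates on the stack;
one stack per cohort is reused for every gene, which makes a discovery run
deterministic given the seed (imputation is the only stochastic step).

### Eligibility and the dataset-level screen

Cohort preparation retains tumor samples (TCGA barcode sample-type codes
01–09, one aliquot per participant, or an explicit annotation), drops
samples missing survival or radiotherapy information, then drops samples
surviving less than five days (survival of exactly five days is eligible;
the threshold converts via 1 month = 30.44 days when times are in months).
Filters are idempotent and their per-rule removal counts partition the
input.  A dataset enters discovery only when univariate Cox shows
radiotherapy protective: HR < 1 *and* p < alpha; `discover_all` refuses to
run otherwise.

## The survival engine

The Cox solver maximizes the weighted partial likelihood by Newton
iterations from zero (or a warm start), with Efron handling of tied event
times and step-halving whenever a step would decrease the likelihood.
Numerical contract:

- convergence when the max-norm of the score falls below 1e-7 × the total
  event weight (a *relative* criterion: the score scales with the number
  and weight of events, and an absolute cutoff either thrashes at float
  precision on large stacks or is vacuous on small ones); cap of 100
  iterations, after which the fit is returned with `converged=False` rather
  than raising;
- suspected complete separation (|coef| > 20) is flagged and warned, never
  raised;
- constant design columns are dropped with a warning; a categorical term's
  reference-coded indicators enter and leave selection together;
- the line search evaluates only the likelihood (cheap single cumulative
  sum) and accepts any non-decrease up to 1e-9 relative roundoff; gradient
  and Hessian are recomputed once per accepted iterate via one fused
  suffix-cumsum over (S0, S1, upper-triangular S2).

Standard errors are inverse-information Wald by default; with a cluster
column they are sandwich estimates aggregated over subjects, using
Breslow-form score residuals.  On tie-free data (and on Breslow-fitted
stacks) those residuals are exact; under Efron fits of genuinely tied data
they are the standard approximation.

Stacked fits use **Breslow** tie handling: stacking duplicates every event M
times at the same instant, and Efron's correction would treat those artifact
copies as real ties.  With Breslow, the stacked weighted likelihood equals
the unstacked one exactly, so a zero-missingness stack reproduces the plain
fit coefficient-for-coefficient — a fixed point the tests assert exactly.

Backward elimination refits every candidate model exactly (no score-based
approximation): at each step the term group whose removal most decreases AIC
(= −2·logPL + 2·k) leaves; elimination stops when no removal decreases AIC.
Candidate fits skip variance estimation and warm-start from the incumbent;
the retained model is refit once with full variance.  At these model sizes
(≤ ~10 terms) exact refitting is cheap and testable; its AIC trace is
strictly decreasing by construction.

Kaplan–Meier estimation and the (unweighted) log-rank test are delegated to
`lifelines`, the Wilcoxon rank-sum to `scipy` (exact null distribution for
small tie-free samples, tie-corrected normal approximation otherwise), and
Pearson correlation to `scipy`, each behind a thin engine function that
enforces this package's conventions.  Correlation strength categories use
|r| > 0.8 strong, 0.3 < |r| ≤ 0.8 moderate, |r| ≤ 0.3 weak; the boundary
values fall to the lower category because strict inequalities on both sides
would leave them undefined.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every recovery claim is made.  One cohort consists of:

- binary clinical confounders imitating a retained breast-cancer covariate
  set — age group (prevalence 0.5, HR 2.0), chemotherapy (0.6, HR 0.5),
  stage (0.3, HR 2.0) — with configurable per-covariate missingness
  (default 10% on chemotherapy and stage, 0% on age);
- a radiotherapy indicator assigned by a logistic model of the confounders
  (default: mild confounding by age), giving a ~50/50 split; a degenerate
  assignment (an empty arm) is rejected as non-identifiable;
- per-gene expression, normal on the log2 scale (gene means ~N(8, 1.5),
  sd 1), with an optional equicorrelated block among Type II genes
  (`type2_block_rho`) emulating the co-expression structure such gene sets
  show in real tumors;
- event times drawn from an exponential proportional-hazards model
  h0·exp(beta_clin·Z + beta_rt·RT + Σ_g [beta_main_g·c_g +
  beta_int_g·c_g·RT]), censored by a 3650-day administrative horizon plus
  independent exponential dropout (5e-5/day).

The effect carrier c_g is the gene's median-split indicator **centered to
high − 1/2** by default.  Centering matters when many genes share one
hazard: uncentered indicators pile every negative interaction onto the
treated arm, which drags the marginal treatment effect and the censoring
level far from the configured values, while the centered version keeps each
gene's high-vs-low and interaction *contrasts* exactly as planted and the
aggregate treatment effect at beta_rt.  Setting `center_carriers=False`
recovers the raw-indicator parameterization, in which the marginal treatment
hazard ratio inside a Type I gene's low group equals exp(beta_rt) exactly —
the single-gene consistency checks use that mode.  A further switch
(`continuous_effects`) makes effects act on z-scored continuous expression
instead of the indicator, turning the dichotomized analysis into a
misspecified model for robustness stress-testing.

Planted classes follow the interaction taxonomy: null (both betas 0),
Type I (beta_main = 0, beta_interaction ≠ 0, default log 0.4), Type II
(beta_main ≠ 0, default log 2, with beta_interaction = −beta_main).  The
standard recovery scenario is n = 1500, beta_rt = log 0.6, 70 genes
(50 null / 10 Type I / 10 Type II), ~20% censoring (baseline hazard
1e-3/day was calibrated once to realize this), and 10% missing cells on two
confounders.

What the generator does *not* emulate: count-based expression noise and
library-size artifacts, multi-level or continuous clinical covariates,
informative censoring, non-proportional hazards, and gene–gene interactions
beyond the optional correlation block.  Passing recovery tests therefore
demonstrates that the *pipeline implements its rules correctly and has the
claimed power under a correctly specified model* — not that the procedure is
robust to the many ways real cohort data violate those assumptions.

## Recovery performance and calibration

Under the standard scenario, pooled over 25 seeds, the pipeline recovers
planted RS genes with sensitivity ≈ 0.95, false-positive rate ≈ 0.08–0.09 on
null genes, and essentially perfect Type I/II assignment among true
positives; the test suite asserts the floors 0.70 / 0.10 / 0.80.  The
false-positive rate sits near its theoretical ceiling 2·alpha·(1−alpha)
≈ 0.095 because for a null gene the RS call reduces to "exactly one of two
independent 5%-level tests rejects" (the treatment-benefit scenarios A/B
almost always hold when the treatment is genuinely protective).

AIC backward selection is calibrated against the chi-square(1) > 2 retention
law for a single noise covariate (≈ 15.7%); stacked multiple imputation is
checked for exactness at zero missingness and for |mean bias| < 0.05 on a
log 2 covariate effect under 10% MCAR.

## Downstream analyses

Patient clustering standardizes each panel gene across patients (z-score),
then cuts a complete-linkage Euclidean dendrogram into k = 2 clusters —
the defaults of the heatmap tooling this analysis style comes from; the
partition is invariant to gene and patient order.  Per cluster, treated and
untreated survival is compared by log-rank; a radio-sensitive cluster is
reported when the benefit is significant in exactly one cluster.  Genes with
extreme expression can be excluded via an explicit exclusion list — no
automatic outlier rule is applied, since any threshold would be arbitrary.

The extreme-survivor contrast compares, within one treatment stratum,
expression between patients whose follow-up exceeds a long cut (they
demonstrably survived past it, whether or not they died later — the reading
that maximizes usable patients) and patients who died before a short cut,
by two-sided Wilcoxon per gene.  All-cause death defines the early-death
group.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations to make
their points with modest Monte-Carlo error: 25 seeds × n = 1500 for the
recovery floors (pooling 1750 gene-level decisions), 200 replicates at
n = 2000 for selection calibration, 100 replicates at n = 500, M = 10 for
imputation bias, and 5 tied toy datasets (≤ 25 records) for oracle
equivalence at 1e-6.  The acceptance script re-measures the same quantities
at 8 seeds (plus 2 all-null panels) — these sizes are the package's choice
of a reasonable precision/effort trade-off.

## Known limitations

- The fast-backward implementation is exact refit-per-candidate backward
  elimination; the approximate single-fit shortcut some software uses would
  differ only negligibly at these model sizes but is not provided.
- Only stacking inference is implemented for multiple imputation (no
  combining-rules pooling path); the stack can be exported for external
  pooling.
- No time-varying covariates, stratified baselines, or proportionality
  diagnostics.
- The replication path for external cohorts (TCGA/METABRIC exports) is
  exercised in tests on synthetic files of the same shape; no network access
  or download tooling is included.
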