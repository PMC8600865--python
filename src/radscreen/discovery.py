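"""Radio-sensitive gene discovery: median dichotomization, scenario A-D
evaluation with covariate adjustment on the imputation stack, and the
Type I / Type II + RGH / RGL classification.

Per gene, patients are split at the within-cohort median of that gene's
expression (high iff strictly above; ties go low) and crossed with the
radiotherapy indicator into the four groups HRT / LRT / HNRT / LNRT.  Four
scenario tests follow:

  A  within the high-expression subset, radiotherapy is retained by AIC
     fast-backward selection with HR < 1;
  B  the same within the low-expression subset;
  C  within the radiotherapy subset, the high-vs-low indicator is
     significantly associated with OS after adjustment (Wald p < alpha);
  D  the same within the no-radiotherapy subset.

A gene is radio-sensitive when (A or B) holds and *exactly one* of C / D
holds: C alone marks a Type I gene (expression matters only under
radiotherapy), D alone a Type II gene (prognostic effect erased by
radiotherapy).  A holding makes the gene RGH (benefit within high
expression), B holding RGL, both "both".  Genes with C and D both holding
are not called and are flagged ambiguous.

The cohort-level adjuster set is frozen once, before the per-gene loop, by
fast-backward selection over all eligible clinical covariates plus
radiotherapy on the cohort's imputation stack; one stack per cohort is
reused for every gene (expression is fully observed, so only clinical
covariates are ever imputed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ClinicalSchema, RunConfig
from .engine import Covariate, CoxFit, CoxModelSpec, fast_backward_aic, fit_cox
from .impute import (
    SUBJECT_COL,
    WEIGHT_COL,
    ImputationStack,
    mice_impute,
    select_imputable,
    stack,
)
from .prep import CohortDataset, screen_rt_protective

logger = logging.getLogger(__name__)

HIGH_COL = "high_expression"


@dataclass
class GeneDichotomy:
    """Median split of one gene plus the four-group sizes."""

    gene_id: str
    threshold: float
    labels: pd.Series  # per-sample "H" / "L"
    group_sizes: dict[str, int]  # HRT / LRT / HNRT / LNRT


@dataclass
class ScenarioResult:
    holds: bool
    hr: float = float("nan")
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")
    p: float = float("nan")
    evaluable: bool = True
    reason: str = ""
    retained: bool | None = None  # A/B only: radiotherapy retained by selection


@dataclass
class ScenarioPanel:
    gene_id: str
    scenarios: dict[str, ScenarioResult]
    adjusters: list[str] = field(default_factory=list)


@dataclass
class RSGeneCall:
    gene_id: str
    is_rs: bool
    rs_type: str  # "I" | "II" | "none"
    direction: str  # "RGH" | "RGL" | "both" | "none"
    panel: ScenarioPanel
    ambiguous: bool = False
    warning: str = ""


@dataclass
class DiscoveryResult:
    calls: list[RSGeneCall]
    adjusters: list[str]
    screen_hr: float
    screen_p: float
    excluded_covariates: list[str]
    skipped_genes: list[str]
    stack: ImputationStack | None = None
    adjuster_fit: CoxFit | None = None


def dichotomize_gene(cohort: CohortDataset, gene_id: str) -> GeneDichotomy:
    """Split the cohort at the within-cohort median of one gene.

    High iff expression strictly above the median (ties labeled low).
    """
    if gene_id not in cohort.expression.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    values = cohort.expression.loc[gene_id]
    if values.nunique() <= 1:
        raise ValueError(f"degenerate gene {gene_id!r}: constant expression")
    threshold = float(np.median(values.to_numpy()))
    labels = pd.Series(np.where(values > threshold, "H", "L"), index=values.index)
    rt = cohort.clinical[cohort.schema.rt_col]
    sizes = {
        "HRT": int(((labels == "H") & (rt == 1)).sum()),
        "LRT": int(((labels == "L") & (rt == 1)).sum()),
        "HNRT": int(((labels == "H") & (rt == 0)).sum()),
        "LNRT": int(((labels == "L") & (rt == 0)).sum()),
    }
    return GeneDichotomy(gene_id, threshold, labels, sizes)


def encode_covariates(
    data: pd.DataFrame, names: list[str], schema: ClinicalSchema
) -> tuple[Covariate, ...]:
    """Pre-encode covariates as numeric design columns, in place.

    Categorical covariates become reference-coded indicator columns tied
    into one selection group; repeated model fits then skip string handling.
    Covariates constant in the data are dropped with a warning.
    """
    out = []
    for name in names:
        decl = schema.covariate(name)
        if decl.kind == "continuous":
            data[name] = pd.to_numeric(data[name])
            out.append(Covariate(name, "continuous"))
            continue
        vals = data[name].astype(str)
        members = []
        for lv in sorted(vals.unique()):
            if lv == str(decl.reference):
                continue
            col = f"{name}[{lv}]"
            data[col] = (vals == lv).to_numpy(dtype=float)
            members.append(col)
        if not members:
            logger.warning("covariate %r is constant; dropped from the model pool", name)
            continue
        out.append(Covariate(name, "group", columns=tuple(members)))
    return tuple(out)


def _not_evaluable(reason: str) -> ScenarioResult:
    return ScenarioResult(False, evaluable=False, reason=reason)


def _eval_retention(sub: pd.DataFrame, schema, adjusters, config) -> ScenarioResult:
    """Scenario A/B: fast-backward over {radiotherapy + adjusters}; holds iff
    radiotherapy is retained with HR < 1 (optionally also Wald p < alpha)."""
    rt = schema.rt_col
    if sub.empty or sub[schema.event_col].sum() < 1:
        return _not_evaluable("no events in subset")
    if sub[rt].nunique() < 2:
        return _not_evaluable("single radiotherapy arm in subset")
    covs = (Covariate(rt, "continuous"),) + tuple(adjusters)
    spec = CoxModelSpec(
        schema.time_col, schema.event_col, covs,
        weight_col=WEIGHT_COL, cluster_col=SUBJECT_COL,
    )
    try:
        kept_spec, fit, _ = fast_backward_aic(sub, spec, ties="breslow")
    except Exception as exc:  # unfittable subset
        return _not_evaluable(f"unfittable: {exc}")
    retained = any(c.name == rt for c in kept_spec.covariates) and rt in fit.summary.index
    if retained:
        hr, lo, hi, p = (
            fit.hr(rt),
            float(fit.summary.loc[rt, "ci_lower"]),
            float(fit.summary.loc[rt, "ci_upper"]),
            fit.p(rt),
        )
    else:
        # report the full-model statistics for the dropped treatment term
        full = fit_cox(sub, spec, ties="breslow")
        hr, lo, hi, p = (
            full.hr(rt),
            float(full.summary.loc[rt, "ci_lower"]),
            float(full.summary.loc[rt, "ci_upper"]),
            full.p(rt),
        )
    holds = retained and hr < 1
    if config.require_p_for_ab:
        holds = holds and p < config.alpha
    return ScenarioResult(bool(holds), hr, lo, hi, p, retained=retained)


def _eval_association(sub: pd.DataFrame, schema, adjusters, config) -> ScenarioResult:
    """Scenario C/D: weighted Cox of OS on {high indicator + adjusters};
    holds iff the indicator's two-sided Wald p < alpha."""
    if sub.empty or sub[schema.event_col].sum() < 1:
        return _not_evaluable("no events in subset")
    if sub[HIGH_COL].nunique() < 2:
        return _not_evaluable("single expression group in subset")
    covs = (Covariate(HIGH_COL, "continuous"),) + tuple(adjusters)
    spec = CoxModelSpec(
        schema.time_col, schema.event_col, covs,
        weight_col=WEIGHT_COL, cluster_col=SUBJECT_COL,
    )
    try:
        if config.reselect_cd:
            kept_spec, fit, _ = fast_backward_aic(sub, spec, ties="breslow")
            if HIGH_COL not in fit.summary.index:
                fit = fit_cox(sub, spec, ties="breslow")
        else:
            fit = fit_cox(sub, spec, ties="breslow")
    except Exception as exc:
        return _not_evaluable(f"unfittable: {exc}")
    hr = fit.hr(HIGH_COL)
    p = fit.p(HIGH_COL)
    return ScenarioResult(
        bool(p < config.alpha),
        hr,
        float(fit.summary.loc[HIGH_COL, "ci_lower"]),
        float(fit.summary.loc[HIGH_COL, "ci_upper"]),
        p,
    )


def evaluate_scenarios(
    stack_data: pd.DataFrame,
    dichotomy: GeneDichotomy,
    adjusters: list[Covariate] | tuple[Covariate, ...],
    schema: ClinicalSchema,
    config: RunConfig,
) -> ScenarioPanel:
    """Evaluate scenarios A-D for one gene on the cohort's imputation stack.

    ``adjusters`` are the frozen cohort-level covariate terms (see
    discover_all); they may reference pre-encoded indicator columns.
    """
    data = stack_data.copy()
    data[HIGH_COL] = (
        data[SUBJECT_COL].map(dichotomy.labels).eq("H").astype(float)
    )
    rt = schema.rt_col
    scenarios = {
        "A": _eval_retention(data[data[HIGH_COL] == 1], schema, adjusters, config),
        "B": _eval_retention(data[data[HIGH_COL] == 0], schema, adjusters, config),
        "C": _eval_association(data[data[rt] == 1], schema, adjusters, config),
        "D": _eval_association(data[data[rt] == 0], schema, adjusters, config),
    }
    return ScenarioPanel(dichotomy.gene_id, scenarios, [c.name for c in adjusters])


_EXPECTED_DIRECTION = {
    # (benefit scenario, association scenario) -> expected HR side of the
    # high-vs-low term: A&C below 1 (high favored under RT), B&C above 1,
    # A&D above 1 (high disadvantaged without RT), B&D below 1.
    ("A", "C"): "below",
    ("B", "C"): "above",
    ("A", "D"): "above",
    ("B", "D"): "below",
}


def classify_rs(panel: ScenarioPanel) -> RSGeneCall:
    """Apply the classification rules to a complete scenario panel."""
    a = panel.scenarios["A"].holds
    b = panel.scenarios["B"].holds
    c = panel.scenarios["C"].holds
    d = panel.scenarios["D"].holds
    ambiguous = bool((a or b) and c and d)
    is_rs = bool((a or b) and (c != d))
    rs_type = "I" if (is_rs and c) else ("II" if (is_rs and d) else "none")
    if is_rs:
        direction = "both" if (a and b) else ("RGH" if a else "RGL")
    else:
        direction = "none"
    warning = ""
    if is_rs:
        assoc = "C" if c else "D"
        hr = panel.scenarios[assoc].hr
        for ben in ("A", "B"):
            if panel.scenarios[ben].holds:
                side = _EXPECTED_DIRECTION[(ben, assoc)]
                if not math.isnan(hr) and (
                    (side == "below" and hr >= 1) or (side == "above" and hr <= 1)
                ):
                    warning = (
                        f"direction inconsistency: scenario {assoc} HR {hr:.3f} "
                        f"opposes the benefit group of scenario {ben}"
                    )
    return RSGeneCall(panel.gene_id, is_rs, rs_type, direction, panel, ambiguous, warning)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * n / (rank + 1))
        adj[i] = running
    return adj


def discover_all(
    cohort: CohortDataset,
    gene_list: list[str],
    config: RunConfig,
    keep_stack: bool = False,
) -> DiscoveryResult:
    """Run the full per-cohort discovery pipeline.

    Refuses to run when the dataset-level screen finds radiotherapy not
    protective.  The imputation stack and the adjuster set are built once and
    reused for every gene, so results are deterministic given config.seed.
    """
    schema = cohort.schema
    verdict = screen_rt_protective(cohort, config)
    if not verdict.keep:
        raise ValueError(
            "cohort fails the radiotherapy-protective screen "
            f"(HR={verdict.hr:.3f}, p={verdict.p:.3g}, {verdict.reason}); "
            "RS discovery is only defined for cohorts with a protective "
            "radiotherapy effect"
        )
    usable = [g for g in gene_list if g in cohort.expression.index]
    skipped = [g for g in gene_list if g not in cohort.expression.index]
    if skipped:
        logger.warning("skipping %d genes absent from expression: %s", len(skipped), skipped[:5])
    if not usable:
        raise ValueError("no usable genes: none of the requested genes are in the matrix")

    imputable, excluded = select_imputable(
        cohort.clinical, schema.covariate_names, config.missingness_cap
    )
    copies = mice_impute(
        cohort.clinical, schema, config.n_imputations, config.seed, imputable
    )
    stk = stack(copies, original=cohort.clinical)

    # freeze the cohort-level adjuster set: backward selection over
    # radiotherapy + all imputable covariates on the (pre-encoded) stack
    encoded = stk.data.copy()
    enc_covs = encode_covariates(encoded, imputable, schema)
    candidates = (Covariate(schema.rt_col, "continuous"),) + enc_covs
    full_spec = CoxModelSpec(
        schema.time_col, schema.event_col, candidates,
        weight_col=WEIGHT_COL, cluster_col=SUBJECT_COL,
    )
    kept_spec, adj_fit, _ = fast_backward_aic(encoded, full_spec, ties="breslow")
    adjusters = [c for c in kept_spec.covariates if c.name != schema.rt_col]
    logger.info("cohort-level adjusters: %s", [c.name for c in adjusters])

    calls = []
    for gene in usable:
        dichotomy = dichotomize_gene(cohort, gene)
        panel = evaluate_scenarios(encoded, dichotomy, adjusters, schema, config)
        calls.append(classify_rs(panel))

    if config.bh_correction:
        for scen in ("C", "D"):
            ps = np.array([c.panel.scenarios[scen].p for c in calls])
            ok = ~np.isnan(ps)
            adj = ps.copy()
            adj[ok] = _bh_adjust(ps[ok])
            for call, q in zip(calls, adj):
                res = call.panel.scenarios[scen]
                if res.evaluable:
                    res.p = float(q)
                    res.holds = bool(q < config.alpha)
        calls = [classify_rs(c.panel) for c in calls]

    return DiscoveryResult(
        calls,
        [c.name for c in adjusters],
        verdict.hr,
        verdict.p,
        excluded,
        skipped,
        stack=stk if keep_stack else None,
        adjuster_fit=adj_fit,
    )


def four_group_km(cohort: CohortDataset, gene_id: str) -> pd.DataFrame:
    """Unadjusted Kaplan-Meier coordinates for the four groups of one gene.

    Tidy output (gene, group, time, survival, at_risk) suitable for plotting
    the HRT / LRT / HNRT / LNRT curves.
    """
    from .engine import km_estimate

    d = dichotomize_gene(cohort, gene_id)
    sch = cohort.schema
    rt = cohort.clinical[sch.rt_col]
    group = d.labels.to_numpy() + np.where(rt.to_numpy() == 1, "RT", "NRT")
    curves = km_estimate(
        cohort.clinical[sch.time_col].to_numpy(),
        cohort.clinical[sch.event_col].to_numpy(),
        group,
    )
    rows = []
    for g, c in curves.items():
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            rows.append(
                {"gene": gene_id, "group": g, "time": t, "survival": s, "at_risk": r}
            )
    return pd.DataFrame(rows)


def intersect_calls(
    call_tables: dict[str, list[RSGeneCall]], which: str = "rs"
) -> dict:
    """Set intersections of genes passing a filter in every dataset.

    which: "rs", "type_i", "type_ii", "rgh" or "rgl".  Returns the per-table
    sets, all pairwise intersections, and the common core.
    """
    if len(call_tables) < 2:
        raise ValueError("need at least 2 call tables to intersect")
    predicates = {
        "rs": lambda c: c.is_rs,
        "type_i": lambda c: c.rs_type == "I",
        "type_ii": lambda c: c.rs_type == "II",
        "rgh": lambda c: c.is_rs and c.direction in ("RGH", "both"),
        "rgl": lambda c: c.is_rs and c.direction in ("RGL", "both"),
    }
    try:
        pred = predicates[which]
    except KeyError:
        raise ValueError(f"unknown filter {which!r}; choose from {sorted(predicates)}")
    per_table = {
        name: {c.gene_id for c in calls if pred(c)} for name, calls in call_tables.items()
    }
    names = sorted(per_table)
    pairwise = {
        (x, y): per_table[x] & per_table[y]
        for i, x in enumerate(names)
        for y in names[i + 1 :]
    }
    common = set.intersection(*per_table.values())
    return {"per_table": per_table, "pairwise": pairwise, "common": common}
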