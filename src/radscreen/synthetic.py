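"""Synthetic expression + survival cohorts with planted gene-radiotherapy
interactions.

The generator draws clinical confounders, assigns a binary radiotherapy
indicator whose probability may depend on the confounders, samples gene
expression on a log2 scale, and draws exponential proportional-hazards event
times whose linear predictor combines clinical effects, a protective
treatment main effect, and per-gene effects acting on the gene's
median-split indicator:

    h(t) = h0 * exp(beta_clin . Z + beta_rt * RT
                    + sum_g [beta_main_g * High_g + beta_int_g * High_g * RT])

Two planted interaction shapes are supported.  A Type I gene has no
prognostic main effect but modifies the treatment effect (beta_main = 0,
beta_int != 0): expression matters only under radiotherapy.  A Type II gene
is prognostic without treatment but radiotherapy erases the disadvantage
(beta_main != 0, beta_main + beta_int = 0).  Effects act on the within-cohort
median-split indicator so the dichotomized downstream analysis is correctly
specified; a config switch makes them act on the continuous z-scored
expression instead (a model-misspecification stress test).

Censoring is administrative (fixed horizon) plus independent exponential
dropout.  Covariate cells are masked at configured rates, optionally
missing-at-random with the masking probability depending on the (always
observed) age group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ClinicalSchema, CovariateDecl


@dataclass(frozen=True)
class GeneEffectSpec:
    """Planted effect of one gene, on the log-hazard scale."""

    gene_id: str
    effect_class: str  # "null" | "type1" | "type2"
    beta_main: float = 0.0
    beta_interaction: float = 0.0

    def __post_init__(self):
        ec = self.effect_class
        if ec == "null":
            if self.beta_main != 0 or self.beta_interaction != 0:
                raise ValueError(f"null gene {self.gene_id} must have zero betas")
        elif ec == "type1":
            if self.beta_main != 0 or self.beta_interaction == 0:
                raise ValueError(
                    f"type1 gene {self.gene_id} needs beta_main = 0, beta_interaction != 0"
                )
        elif ec == "type2":
            if self.beta_main == 0 or not math.isclose(
                self.beta_main + self.beta_interaction, 0.0, abs_tol=1e-12
            ):
                raise ValueError(
                    f"type2 gene {self.gene_id} needs beta_main != 0 and "
                    "beta_main + beta_interaction = 0"
                )
        else:
            raise ValueError(f"unknown effect class {ec!r}")

    @staticmethod
    def null(gene_id: str) -> "GeneEffectSpec":
        return GeneEffectSpec(gene_id, "null")

    @staticmethod
    def type1(gene_id: str, beta_interaction: float) -> "GeneEffectSpec":
        return GeneEffectSpec(gene_id, "type1", 0.0, beta_interaction)

    @staticmethod
    def type2(gene_id: str, beta_main: float) -> "GeneEffectSpec":
        return GeneEffectSpec(gene_id, "type2", beta_main, -beta_main)


@dataclass(frozen=True)
class ClinicalCovariateSim:
    """One simulated binary clinical confounder.

    prevalence: P(level "1"); beta: log-hazard of level "1" vs "0";
    missing_rate: fraction of cells masked after generation.
    """

    name: str
    prevalence: float
    beta: float
    missing_rate: float = 0.0
    rt_logit: float = 0.0  # contribution of level "1" to the RT-assignment logit

    def __post_init__(self):
        if not (0 < self.prevalence < 1):
            raise ValueError(f"{self.name}: prevalence must be in (0,1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError(f"{self.name}: missing rate must be in [0,1)")


#: defaults imitate the retained covariate set of a breast-cancer cohort:
#: dichotomized age (strong adverse), chemotherapy (protective), late stage
#: (adverse); chemotherapy and stage carry the configurable missingness.
DEFAULT_COVARIATES = (
    ClinicalCovariateSim("age_group", 0.5, math.log(2.0), 0.0, rt_logit=-0.4),
    ClinicalCovariateSim("chemotherapy", 0.6, math.log(0.5), 0.10),
    ClinicalCovariateSim("stage", 0.3, math.log(2.0), 0.10),
)


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic cohort.

    Defaults encode the standard recovery scenario: n = 1500 patients, a
    protective treatment main effect HR 0.6, exponential baseline hazard with
    a ~1.9-year median baseline survival, a ten-year administrative horizon
    plus slow dropout giving roughly 20% censoring, and 10% missingness on
    two of the three confounders.
    """

    n_patients: int = 1500
    gene_specs: tuple[GeneEffectSpec, ...] = ()
    beta_rt: float = math.log(0.6)
    clinical_covariates: tuple[ClinicalCovariateSim, ...] = DEFAULT_COVARIATES
    baseline_hazard: float = 1e-3  # per day
    censor_horizon: float = 3650.0  # administrative cut, days
    dropout_rate: float = 5e-5  # exponential dropout, per day
    rt_intercept: float = 0.2  # RT-assignment logit intercept
    expr_mean_loc: float = 8.0  # per-gene mean on the log2 scale
    expr_mean_scale: float = 1.5
    expr_sd: float = 1.0
    type2_block_rho: float = 0.0  # equicorrelation among type2 genes
    mar_on_age: bool = False  # make masking probability depend on age group
    continuous_effects: bool = False  # misspecification stress test
    center_carriers: bool = True  # see generate_cohort
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not (0 <= self.type2_block_rho < 1):
            raise ValueError("type2_block_rho must be in [0,1)")
        names = [g.gene_id for g in self.gene_specs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene ids in gene_specs")

    @property
    def schema(self) -> ClinicalSchema:
        return ClinicalSchema(
            covariates=tuple(
                CovariateDecl(c.name, "categorical", "0") for c in self.clinical_covariates
            )
        )


@dataclass
class SyntheticTruth:
    """Ground truth for recovery scoring."""

    effect_class: dict[str, str]  # gene -> null | type1 | type2
    group_sizes: dict[str, dict[str, int]] = field(default_factory=dict)
    n_rt: int = 0
    n_events: int = 0


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression matrix, clinical table, truth).

    Deterministic given config.seed.  Raises if the radiotherapy assignment
    is degenerate (all treated or all untreated), which would make every
    interaction non-identifiable.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sample_ids = [f"SYN{i:05d}" for i in range(n)]

    # clinical confounders
    cov_values = {}
    for cov in config.clinical_covariates:
        cov_values[cov.name] = rng.binomial(1, cov.prevalence, n)

    # treatment assignment (confounding via rt_logit terms)
    logit = np.full(n, config.rt_intercept, dtype=float)
    for cov in config.clinical_covariates:
        logit += cov.rt_logit * cov_values[cov.name]
    p_rt = 1.0 / (1.0 + np.exp(-logit))
    rt = rng.binomial(1, p_rt)
    if rt.sum() in (0, n):
        raise ValueError("degenerate radiotherapy assignment: one arm is empty")

    # expression: per-gene normal on the log2 scale, optional equicorrelated
    # type2 block (shared factor) for heatmap realism
    genes = [g.gene_id for g in config.gene_specs]
    expr = np.empty((len(genes), n))
    rho = config.type2_block_rho
    shared = rng.normal(size=n)
    for i, g in enumerate(config.gene_specs):
        mu = rng.normal(config.expr_mean_loc, config.expr_mean_scale)
        noise = rng.normal(size=n)
        if g.effect_class == "type2" and rho > 0:
            z = math.sqrt(rho) * shared + math.sqrt(1 - rho) * noise
        else:
            z = noise
        expr[i] = mu + config.expr_sd * z

    # linear predictor
    lp = config.beta_rt * rt.astype(float)
    for cov in config.clinical_covariates:
        lp += cov.beta * cov_values[cov.name]
    group_sizes: dict[str, dict[str, int]] = {}
    # With many planted genes, uncentered indicators would pile their
    # interaction terms onto the treatment arm and distort the marginal
    # treatment effect and censoring level far from the configured values;
    # centering the carrier (high - 1/2) keeps every gene's high-vs-low and
    # interaction *contrasts* exactly as planted while the aggregate stays
    # mean-zero, so beta_rt remains the average treatment effect.
    offset = 0.5 if config.center_carriers else 0.0
    for i, g in enumerate(config.gene_specs):
        if config.continuous_effects:
            carrier = (expr[i] - expr[i].mean()) / expr[i].std()
        else:
            carrier = (expr[i] > np.median(expr[i])).astype(float) - offset
        if g.effect_class != "null":
            lp += g.beta_main * carrier + g.beta_interaction * carrier * rt
        high = (expr[i] > np.median(expr[i])).astype(float)
        group_sizes[g.gene_id] = {
            "HRT": int(np.sum((high == 1) & (rt == 1))),
            "LRT": int(np.sum((high == 0) & (rt == 1))),
            "HNRT": int(np.sum((high == 1) & (rt == 0))),
            "LNRT": int(np.sum((high == 0) & (rt == 0))),
        }

    # exponential event times under the proportional-hazards model
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.full(n, config.censor_horizon)
    if config.dropout_rate > 0:
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / config.dropout_rate, n))
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    clin = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event.astype(float),
            "radiotherapy": rt.astype(float),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    age = cov_values.get("age_group")
    for cov in config.clinical_covariates:
        col = pd.Series(cov_values[cov.name].astype(str), index=clin.index, dtype=object)
        if cov.missing_rate > 0:
            if config.mar_on_age and age is not None and cov.name != "age_group":
                # masking probability depends on the observed age group but
                # keeps the configured marginal rate when P(age=1) = 0.5
                p_miss = cov.missing_rate * (0.6 + 0.8 * age)
            else:
                p_miss = np.full(n, cov.missing_rate)
            mask = rng.random(n) < p_miss
            col[mask] = np.nan
        clin[cov.name] = col

    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=sample_ids)
    truth = SyntheticTruth(
        effect_class={g.gene_id: g.effect_class for g in config.gene_specs},
        group_sizes=group_sizes,
        n_rt=int(rt.sum()),
        n_events=int(os_event.sum()),
    )
    return expr_df, clin, truth


def standard_gene_panel(
    n_null: int = 50,
    n_type1: int = 10,
    n_type2: int = 10,
    beta_int_type1: float = math.log(0.4),
    beta_main_type2: float = math.log(2.0),
) -> tuple[GeneEffectSpec, ...]:
    """The 70-gene recovery panel: 50 null, 10 Type I, 10 Type II."""
    specs = [GeneEffectSpec.null(f"NULL{i:03d}") for i in range(n_null)]
    specs += [GeneEffectSpec.type1(f"T1G{i:03d}", beta_int_type1) for i in range(n_type1)]
    specs += [GeneEffectSpec.type2(f"T2G{i:03d}", beta_main_type2) for i in range(n_type2)]
    return tuple(specs)


def standard_recovery_config(seed: int, n_patients: int = 1500) -> SyntheticConfig:
    """The standard recovery scenario all calibration claims refer to."""
    return SyntheticConfig(
        n_patients=n_patients, gene_specs=standard_gene_panel(), seed=seed
    )


@dataclass
class RecoveryMetrics:
    sensitivity: float
    false_positive_rate: float
    type_accuracy: float
    n_true_effect: int
    n_null: int
    n_true_positive: int

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "false_positive_rate": self.false_positive_rate,
            "type_accuracy": self.type_accuracy,
        }


def score_recovery(calls, truth: SyntheticTruth) -> RecoveryMetrics:
    """Score RS calls against the planted truth.

    sensitivity: P(called RS | planted type1 or type2); false-positive rate:
    P(called RS | null); type accuracy: among true-positive calls, fraction
    whose Type I/II label matches the planted class.
    """
    call_map = {c.gene_id: c for c in calls}
    if set(call_map) != set(truth.effect_class):
        raise ValueError(
            "gene sets differ between calls and truth: "
            f"{sorted(set(call_map) ^ set(truth.effect_class))[:5]} ..."
        )
    expected_type = {"type1": "I", "type2": "II"}
    n_eff = n_null = tp = fp = type_ok = 0
    for gene, klass in truth.effect_class.items():
        called = call_map[gene].is_rs
        if klass == "null":
            n_null += 1
            fp += called
        else:
            n_eff += 1
            if called:
                tp += 1
                type_ok += call_map[gene].rs_type == expected_type[klass]
    return RecoveryMetrics(
        sensitivity=tp / n_eff if n_eff else float("nan"),
        false_positive_rate=fp / n_null if n_null else float("nan"),
        type_accuracy=type_ok / tp if tp else float("nan"),
        n_true_effect=n_eff,
        n_null=n_null,
        n_true_positive=tp,
    )
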