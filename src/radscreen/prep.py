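"""Eligibility filtering and the dataset-level radiotherapy-protective screen.

The screen mirrors the study-selection step of the source cohorts: a dataset
enters the per-gene analysis only when univariate Cox shows radiotherapy to
be protective (HR < 1, p < alpha).  Eligibility removes samples with missing
survival or radiotherapy information and samples surviving less than five
days (converted to the declared time unit), in that order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ClinicalSchema, RunConfig
from .engine import Covariate, CoxModelSpec, fit_cox

logger = logging.getLogger(__name__)

# TCGA aliquot barcode: project-TSS-participant-sample[vial]-...
_TCGA_BARCODE = re.compile(r"^TCGA-\w{2}-\w{4}-(\d{2})[A-Z]?")


@dataclass
class CohortDataset:
    """Joined expression + clinical records for eligible patients."""

    expression: pd.DataFrame  # genes x samples
    clinical: pd.DataFrame  # samples x variables
    schema: ClinicalSchema
    eligibility_log: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.clinical)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical.index)


@dataclass
class ScreenVerdict:
    keep: bool
    hr: float
    p: float
    reason: str = ""


def _barcode_code(sample_id: str) -> int | None:
    m = _TCGA_BARCODE.match(sample_id)
    return int(m.group(1)) if m else None


def filter_tumor_samples(
    expr: pd.DataFrame, sample_types: pd.Series | None = None
) -> pd.DataFrame:
    """Retain tumor samples.

    With TCGA barcodes, tumor means sample-type code 01-09; one aliquot per
    participant is kept (the lexicographically first barcode).  A supplied
    sample-type annotation ("tumor"/"normal") overrides barcode parsing.
    Non-barcode ids without annotation pass through with a warning.
    """
    if sample_types is not None:
        keep = [s for s in expr.columns if str(sample_types.get(s, "tumor")).lower() == "tumor"]
        dropped = expr.shape[1] - len(keep)
        if dropped:
            logger.info("dropped %d non-tumor samples by annotation", dropped)
        return expr[keep]
    codes = {s: _barcode_code(s) for s in expr.columns}
    if all(c is None for c in codes.values()):
        logger.warning(
            "sample ids are not TCGA barcodes and no sample-type annotation "
            "was given: retaining all %d samples",
            expr.shape[1],
        )
        return expr
    tumor = [s for s, c in codes.items() if c is not None and 1 <= c <= 9]
    dropped = expr.shape[1] - len(tumor)
    if dropped:
        logger.info("dropped %d non-tumor / unparseable samples by barcode", dropped)
    # one aliquot per participant: lexicographically first barcode
    by_patient: dict[str, str] = {}
    for s in sorted(tumor):
        patient = "-".join(s.split("-")[:3])
        by_patient.setdefault(patient, s)
    kept = [s for s in expr.columns if s in set(by_patient.values())]
    if len(kept) < len(tumor):
        logger.info("collapsed %d extra aliquots to one per participant", len(tumor) - len(kept))
    return expr[kept]


def apply_eligibility(
    expr: pd.DataFrame,
    clin: pd.DataFrame,
    config: RunConfig,
    schema: ClinicalSchema | None = None,
) -> CohortDataset:
    """Apply the eligibility filters in order and log per-rule removals.

    1. samples not present in both expression and clinical tables;
    2. samples missing survival time, event indicator, or radiotherapy;
    3. samples with survival time below the minimum-survival threshold
       (five days by default, converted to the declared unit).
    """
    schema = schema or ClinicalSchema()
    log: dict[str, int] = {}
    shared = [s for s in clin.index if s in set(expr.columns)]
    log["clinical_without_expression"] = len(clin) - len(shared)
    log["expression_without_clinical"] = expr.shape[1] - len(shared)
    if len(shared) < 2:
        raise ValueError("expression and clinical tables share fewer than 2 samples")
    clin = clin.loc[shared]

    complete = clin[[schema.time_col, schema.event_col, schema.rt_col]].notna().all(axis=1)
    log["missing_survival_or_radiotherapy"] = int((~complete).sum())
    clin = clin[complete]

    threshold = config.min_survival_in_unit
    long_enough = clin[schema.time_col] >= threshold
    log["short_survival"] = int((~long_enough).sum())
    clin = clin[long_enough]

    if clin[schema.event_col].sum() < 2:
        raise ValueError("fewer than 2 events remain after eligibility filtering")
    expr = expr[list(clin.index)]
    logger.info("eligibility removals: %s (n=%d retained)", log, len(clin))
    return CohortDataset(expr, clin, schema, log)


def screen_rt_protective(cohort: CohortDataset, config: RunConfig) -> ScreenVerdict:
    """Univariate Cox of OS on radiotherapy: keep iff HR < 1 and p < alpha."""
    sch = cohort.schema
    clin = cohort.clinical
    events_by_arm = clin.groupby(sch.rt_col)[sch.event_col].sum()
    if len(events_by_arm) < 2 or (events_by_arm < 1).any():
        return ScreenVerdict(False, float("nan"), float("nan"), "degenerate")
    spec = CoxModelSpec(sch.time_col, sch.event_col, (Covariate(sch.rt_col, "continuous"),))
    fit = fit_cox(clin, spec)
    hr = fit.hr(sch.rt_col)
    p = fit.p(sch.rt_col)
    keep = bool(hr < 1 and p < config.alpha)
    return ScreenVerdict(keep, hr, p, "" if keep else "radiotherapy not protective")
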