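"""Chained-equation multiple imputation of clinical covariates, stacking of
the completed datasets, and weighted Cox fitting on the stack.

Missing covariate cells are imputed by chained equations: missing cells are
initialized by random draws from the observed values, then the covariates are
cycled (10 cycles by default), imputing continuous cells by predictive-mean
matching (5 donors) and categorical cells by draws from a multinomial
logistic model fitted on the other covariates plus the outcome (event
indicator and log survival time), the standard predictor set for survival
imputation.  The M completed copies are concatenated with weight 1/M and the
analysis model is a weighted Cox fit with subject-clustered sandwich
standard errors — the stacking alternative to Rubin's-rules pooling.

Survival time, the event indicator and radiotherapy are never imputed:
samples missing them were removed at eligibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .config import ClinicalSchema
from .engine import CoxFit, CoxModelSpec, fit_cox

logger = logging.getLogger(__name__)

N_CYCLES = 10
K_PMM = 5

WEIGHT_COL = "mi_weight"
SUBJECT_COL = "subject_id"


@dataclass
class ImputationStack:
    """M completed copies of the cohort, concatenated.

    Every record carries weight 1/M and its subject id; originally observed
    cells are identical across copies.
    """

    data: pd.DataFrame
    m: int
    n_subjects: int

    @property
    def weights(self) -> pd.Series:
        return self.data[WEIGHT_COL]


def select_imputable(
    clin: pd.DataFrame, covariates: list[str], cap: float
) -> tuple[list[str], list[str]]:
    """Split covariates into imputable and excluded by missing fraction.

    Covariates missing at a fraction in (0, cap) are imputable; those at or
    above the cap are excluded from the covariate pool (logged); fully
    observed covariates pass through as imputable no-ops.
    """
    imputable, excluded = [], []
    for name in covariates:
        frac = float(clin[name].isna().mean())
        if frac >= cap:
            logger.warning(
                "covariate %r excluded: %.1f%% missing (cap %.0f%%)",
                name, 100 * frac, 100 * cap,
            )
            excluded.append(name)
        else:
            imputable.append(name)
    return imputable, excluded


def _predictor_matrix(
    clin: pd.DataFrame, schema: ClinicalSchema, covariates: list[str], target: str
) -> np.ndarray:
    """Numeric predictors for one chained-equation step: all other covariates
    (categoricals one-hot) plus event indicator and log time."""
    cols = [
        np.log(clin[schema.time_col].to_numpy(dtype=float)),
        clin[schema.event_col].to_numpy(dtype=float),
        clin[schema.rt_col].to_numpy(dtype=float),
    ]
    for name in covariates:
        if name == target:
            continue
        decl = schema.covariate(name)
        if decl.kind == "continuous":
            cols.append(clin[name].to_numpy(dtype=float))
        else:
            vals = clin[name].astype(str)
            for lv in sorted(vals.unique()):
                if lv == str(decl.reference):
                    continue
                cols.append((vals == lv).to_numpy(dtype=float))
    return np.column_stack(cols)


def _impute_one(
    clin: pd.DataFrame,
    schema: ClinicalSchema,
    targets: list[str],
    miss_masks: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    work = clin.copy()
    # initialize by random draws from the observed values
    for name in targets:
        mask = miss_masks[name]
        observed = work.loc[~mask, name].to_numpy()
        work.loc[mask, name] = rng.choice(observed, size=int(mask.sum()), replace=True)
    for _ in range(N_CYCLES):
        for name in targets:
            mask = miss_masks[name]
            X = _predictor_matrix(work, schema, targets, name)
            decl = schema.covariate(name)
            if decl.kind == "continuous":
                y = work[name].to_numpy(dtype=float)
                Xo, yo = X[~mask], y[~mask]
                A = np.column_stack([np.ones(len(Xo)), Xo])
                coef, *_ = np.linalg.lstsq(A, yo, rcond=None)
                pred_obs = A @ coef
                pred_mis = np.column_stack([np.ones(mask.sum()), X[mask]]) @ coef
                # predictive-mean matching: draw one of the K nearest donors
                order = np.argsort(pred_obs)
                pos = np.searchsorted(pred_obs[order], pred_mis)
                draws = np.empty(int(mask.sum()))
                for j, p in enumerate(pos):
                    lo = max(0, p - K_PMM)
                    hi = min(len(order), p + K_PMM)
                    window = order[lo:hi]
                    d = np.abs(pred_obs[window] - pred_mis[j])
                    donors = window[np.argsort(d)[:K_PMM]]
                    draws[j] = yo[donors[rng.integers(0, len(donors))]]
                work.loc[mask, name] = draws
            else:
                y = work[name].astype(str).to_numpy()
                levels = np.array(sorted(np.unique(y[~mask])))
                if len(levels) == 1:
                    work.loc[mask, name] = levels[0]
                    continue
                clf = LogisticRegression(max_iter=500)
                clf.fit(X[~mask], y[~mask])
                proba = clf.predict_proba(X[mask])
                cum = np.cumsum(proba, axis=1)
                u = rng.random(len(cum))
                idx = (u[:, None] > cum).sum(axis=1)
                work.loc[mask, name] = clf.classes_[idx]
    return work


def mice_impute(
    clin: pd.DataFrame,
    schema: ClinicalSchema,
    m: int,
    seed: int,
    covariates: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Produce M completed copies of the clinical table.

    M independent imputation streams are spawned from the seed; identical
    seeds give identical copies.  A table with no missing cells returns M
    identical copies (the no-op fixed point).
    """
    covariates = covariates if covariates is not None else schema.covariate_names
    for name in covariates:
        if clin[name].notna().sum() == 0:
            raise ValueError(f"covariate {name!r} has no observed values to impute from")
    miss_masks = {name: clin[name].isna().to_numpy() for name in covariates}
    targets = [name for name in covariates if miss_masks[name].any()]
    if not targets:
        return [clin.copy() for _ in range(m)]
    streams = np.random.SeedSequence(seed).spawn(m)
    return [
        _impute_one(clin, schema, targets, miss_masks, np.random.default_rng(s))
        for s in streams
    ]


def stack(
    imputations: list[pd.DataFrame], original: pd.DataFrame | None = None
) -> ImputationStack:
    """Concatenate M completed copies with weight 1/M and subject ids.

    When the pre-imputation table is supplied, verifies that no originally
    observed cell was altered by any copy.
    """
    m = len(imputations)
    if m < 1:
        raise ValueError("need at least one imputation")
    base = imputations[0]
    for copy in imputations[1:]:
        if not copy.index.equals(base.index) or list(copy.columns) != list(base.columns):
            raise ValueError("imputed copies disagree on samples or columns")
    if original is not None:
        observed = original.notna()
        for i, copy in enumerate(imputations):
            changed = observed & (copy.astype(object) != original.astype(object)) & original.notna()
            if changed.to_numpy().any():
                raise ValueError(f"imputation copy {i} altered an observed cell")
    frames = []
    for i, copy in enumerate(imputations):
        f = copy.copy()
        f[SUBJECT_COL] = f.index
        f[WEIGHT_COL] = 1.0 / m
        f["imputation"] = i
        frames.append(f)
    data = pd.concat(frames, ignore_index=True)
    return ImputationStack(data, m, len(base))


def export_stack(stk: ImputationStack, path) -> None:
    """Write the stacked records to TSV for external audit (e.g. pooling by
    combining rules outside this package)."""
    stk.data.to_csv(path, sep="\t", index=False)


def weighted_cox_on_stack(stk: ImputationStack, spec: CoxModelSpec) -> CoxFit:
    """Weighted Cox fit on the stacked data with subject-clustered sandwich
    variance.

    Breslow tie handling is used: stacking duplicates every event M times at
    the same time, and those co-incident copies are artifacts of stacking,
    not real ties — Breslow reproduces the unstacked weighted likelihood
    exactly, so a zero-missingness stack recovers the plain fit exactly.
    """
    full_spec = CoxModelSpec(
        spec.time_col,
        spec.event_col,
        spec.covariates,
        weight_col=WEIGHT_COL,
        cluster_col=SUBJECT_COL,
    )
    return fit_cox(stk.data, full_spec, ties="breslow")
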