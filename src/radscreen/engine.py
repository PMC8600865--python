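"""Survival-analysis core: Cox partial-likelihood fitting, AIC fast-backward
selection, Kaplan-Meier estimation, log-rank / Wilcoxon tests and categorized
Pearson correlation.

The Cox solver maximizes the weighted partial likelihood by Newton iterations
with step-halving, Efron handling of tied event times (Breslow available for
stacked data, where duplicated event times are artifacts of stacking rather
than real ties), and an optional cluster sandwich variance for weighted fits
on multiply-imputed stacks.  Everything here is pure-functional: fits depend
only on the data and spec passed in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

GRADIENT_TOL = 1e-7
MAX_NEWTON_ITER = 100
SEPARATION_COEF = 20.0


@dataclass(frozen=True)
class Covariate:
    """One model term.

    kind "continuous": the column enters as-is; "categorical": the column is
    reference-coded into indicators that move together in selection;
    "group": ``columns`` names already-encoded numeric design columns that
    form one selection group (used on pre-encoded stacks).
    """

    name: str
    kind: str = "continuous"  # "continuous" | "categorical" | "group"
    reference: str | None = None
    columns: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical", "group"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical covariate {self.name!r} needs a reference level")
        if self.kind == "group" and not self.columns:
            raise ValueError(f"group covariate {self.name!r} needs member columns")


@dataclass(frozen=True)
class CoxModelSpec:
    """Outcome columns plus an ordered list of covariate terms.

    ``weight_col`` enables weighted partial likelihood; ``cluster_col``
    switches standard errors to the subject-clustered sandwich estimate.
    """

    time_col: str
    event_col: str
    covariates: tuple[Covariate, ...] = ()
    weight_col: str | None = None
    cluster_col: str | None = None

    def __post_init__(self):
        names = [c.name for c in self.covariates]
        if len(names) != len(set(names)):
            raise ValueError("duplicate covariate terms in model spec")

    def without(self, name: str) -> "CoxModelSpec":
        return replace(self, covariates=tuple(c for c in self.covariates if c.name != name))


@dataclass
class CoxFit:
    """A fitted proportional-hazards model.

    ``summary`` has one row per estimated design column with columns
    coef / se / hr / ci_lower / ci_upper / p.  ``term_groups`` maps each
    covariate name to its design columns (a categorical's indicators move
    together in backward selection).
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    separation: bool
    term_groups: dict[str, list[str]]
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.summary)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.k

    def coef(self, column: str) -> float:
        return float(self.summary.loc[column, "coef"])

    def hr(self, column: str) -> float:
        return float(self.summary.loc[column, "hr"])

    def p(self, column: str) -> float:
        return float(self.summary.loc[column, "p"])

    def columns_of(self, term: str) -> list[str]:
        return self.term_groups[term]


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    times: np.ndarray  # ascending event times
    survival: np.ndarray  # S(t) at those times, non-increasing from 1
    at_risk: np.ndarray  # risk-set size just before each time


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    data: pd.DataFrame, covariates: tuple[Covariate, ...]
) -> tuple[pd.DataFrame, dict[str, list[str]], list[str]]:
    """Expand covariates into a numeric design matrix.

    Categorical terms are reference-coded (one indicator per non-reference
    observed level).  Constant columns are dropped with a warning, as are
    whole terms whose every indicator is constant.
    """
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for cov in covariates:
        if cov.kind == "group":
            for col in cov.columns:
                cols[col] = data[col].to_numpy(dtype=float)
            groups[cov.name] = list(cov.columns)
            continue
        if cov.name not in data.columns:
            raise KeyError(f"covariate column {cov.name!r} not in data")
        if cov.kind == "continuous":
            vals = pd.to_numeric(data[cov.name], errors="raise").to_numpy(dtype=float)
            cols[cov.name] = vals
            groups[cov.name] = [cov.name]
        else:
            observed = data[cov.name]
            levels = sorted(str(v) for v in observed.dropna().unique())
            members = []
            for lv in levels:
                if lv == str(cov.reference):
                    continue
                col = f"{cov.name}[{lv}]"
                cols[col] = (observed.astype(str) == lv).to_numpy(dtype=float)
                members.append(col)
            groups[cov.name] = members
    X = pd.DataFrame(cols, index=data.index)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        logger.warning("dropping constant design columns: %s", dropped)
        X = X.drop(columns=dropped)
        for name in list(groups):
            groups[name] = [c for c in groups[name] if c not in dropped]
            if not groups[name]:
                del groups[name]
    return X, {k: list(v) for k, v in groups.items()}, dropped


# ---------------------------------------------------------------------------
# partial likelihood internals (arrays pre-sorted ascending by time)


class _CoxProblem:
    """Precomputed sorted arrays and index structures for one model fit."""

    def __init__(self, X, times, events, w, ties):
        order = np.argsort(times, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.times = times[order]
        self.events = events[order]
        self.w = w[order]
        self.order = order
        self.n, self.p = self.X.shape
        self.first = np.searchsorted(self.times, self.times, side="left")
        self.ev = np.flatnonzero(self.events)
        self.we = self.w[self.ev]
        self.iu, self.ju = np.triu_indices(self.p)
        ev_times = self.times[self.ev]
        uniq, start, counts = np.unique(ev_times, return_index=True, return_counts=True)
        # Efron corrections apply only at event times with >= 2 tied events
        self.tie_groups = (
            [(start[i], counts[i]) for i in range(len(uniq)) if counts[i] >= 2]
            if ties == "efron"
            else []
        )

    def loglik(self, beta):
        """Cheap evaluation for the line search: log likelihood only."""
        eta = self.X @ beta
        r = self.w * np.exp(eta)
        s0 = np.cumsum(r[::-1])[::-1]
        S0 = s0[self.first[self.ev]]
        ll = float(np.sum(self.we * (eta[self.ev] - np.log(S0))))
        for st, d in self.tie_groups:
            rows = self.ev[st : st + d]
            S0g = s0[self.first[rows[0]]]
            S0D = r[rows].sum()
            wsum = self.w[rows].sum()
            ll += wsum * np.log(S0g)
            ll -= sum(
                (wsum / d) * np.log(S0g - (ell / d) * S0D) for ell in range(d)
            )
        return ll

    def loglik_grad_info(self, beta):
        """Full evaluation: likelihood, score and observed information.

        One fused suffix-cumsum covers S0, S1 and the upper triangle of the
        second-moment matrix S2, the dominant cost at large n; Efron
        corrections are applied per tied event time.
        """
        X, w, ev, we = self.X, self.w, self.ev, self.we
        n, p = self.n, self.p
        iu, ju = self.iu, self.ju
        eta = X @ beta
        r = w * np.exp(eta)
        stacked = np.empty((n, 1 + p + len(iu)))
        stacked[:, 0] = r
        stacked[:, 1 : p + 1] = r[:, None] * X
        stacked[:, p + 1 :] = r[:, None] * (X[:, iu] * X[:, ju])
        suffix = np.cumsum(stacked[::-1], axis=0)[::-1]
        at = suffix[self.first[ev]]
        S0 = at[:, 0]
        S1 = at[:, 1 : p + 1]
        m = S1 / S0[:, None]
        ll = float(np.sum(we * (eta[ev] - np.log(S0))))
        grad = (we[:, None] * (X[ev] - m)).sum(axis=0)
        tri = (we / S0) @ at[:, p + 1 :]
        info = np.zeros((p, p))
        info[iu, ju] = tri
        info[ju, iu] = tri
        info -= np.einsum("i,ij,ik->jk", we, m, m)
        for st, d in self.tie_groups:
            rows = ev[st : st + d]
            fi = self.first[rows[0]]
            S0g = suffix[fi, 0]
            S1g = suffix[fi, 1 : p + 1]
            S2g = np.zeros((p, p))
            S2g[iu, ju] = suffix[fi, p + 1 :]
            S2g[ju, iu] = suffix[fi, p + 1 :]
            rD = r[rows]
            S0D = rD.sum()
            S1D = (rD[:, None] * X[rows]).sum(axis=0)
            S2D = np.einsum("i,ij,ik->jk", rD, X[rows], X[rows])
            wD = w[rows]
            wsum = wD.sum()
            wbar = wsum / d
            # remove the Breslow denominator terms for these d events (the
            # sum_i w_i * eta_i numerator is identical under both methods)
            mB = S1g / S0g
            ll += wsum * np.log(S0g)
            grad += wsum * mB
            info -= wsum * (S2g / S0g - np.outer(mB, mB))
            # add the Efron denominator terms
            for ell in range(d):
                f = ell / d
                D0 = S0g - f * S0D
                mE = (S1g - f * S1D) / D0
                ll -= wbar * np.log(D0)
                grad -= wbar * mE
                info += wbar * ((S2g - f * S2D) / D0 - np.outer(mE, mE))
        return float(ll), grad, info


# ---------------------------------------------------------------------------
# public fitting API


def fit_cox(
    data: pd.DataFrame,
    spec: CoxModelSpec,
    ties: str = "efron",
    variance: bool = True,
    initial: dict[str, float] | None = None,
) -> CoxFit:
    """Fit a (weighted) Cox proportional-hazards model.

    Newton iterations from beta=0 with step-halving on likelihood decrease;
    convergence when the max-norm of the score drops below 1e-7.  The
    convergence flag is set False (never an exception) if the iteration cap
    is hit.  With ``cluster_col`` set, standard errors are sandwich estimates
    aggregated over clusters (subjects), as appropriate for stacked
    multiply-imputed data.

    ``variance=False`` skips standard errors (model-selection loops need only
    the likelihood); ``initial`` warm-starts Newton from named coefficients.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    times_raw = pd.to_numeric(data[spec.time_col]).to_numpy(dtype=float)
    events_raw = pd.to_numeric(data[spec.event_col]).to_numpy(dtype=float)
    n = len(data)
    n_events = int(events_raw.sum())
    if n_events == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    w_raw = (
        pd.to_numeric(data[spec.weight_col]).to_numpy(dtype=float)
        if spec.weight_col
        else np.ones(n)
    )

    X_df, groups, dropped = build_design(data, spec.covariates)
    p = X_df.shape[1]
    if p == 0:
        prob = _CoxProblem(np.empty((n, 0)), times_raw, events_raw, w_raw, ties)
        empty = pd.DataFrame(
            columns=["coef", "se", "hr", "ci_lower", "ci_upper", "p"], dtype=float
        )
        return CoxFit(empty, prob.loglik(np.empty(0)), n, n_events, True, False, {}, dropped)

    prob = _CoxProblem(X_df.to_numpy(dtype=float), times_raw, events_raw, w_raw, ties)

    beta = np.zeros(p)
    if initial:
        for j, col in enumerate(X_df.columns):
            beta[j] = initial.get(col, 0.0)
    ll, grad, info = prob.loglik_grad_info(beta)
    # the gradient scales with the total event weight; converge on the
    # relative score norm so weighted/stacked fits behave like plain ones
    scale = max(1.0, float(prob.we.sum()))
    converged = False
    for _ in range(MAX_NEWTON_ITER):
        if np.max(np.abs(grad)) < GRADIENT_TOL * scale:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # line search on the cheap likelihood; accept any non-decrease up to
        # float roundoff so a converged fit cannot thrash
        accept_tol = 1e-9 * (abs(ll) + 1.0)
        new_beta = beta + step
        new_ll = prob.loglik(new_beta)
        halvings = 0
        while new_ll < ll - accept_tol and halvings < 25:
            step = step / 2.0
            new_beta = beta + step
            new_ll = prob.loglik(new_beta)
            halvings += 1
        if halvings == 25 and new_ll < ll - accept_tol:
            break  # no ascent direction left at float precision
        beta = new_beta
        ll, grad, info = prob.loglik_grad_info(beta)
    else:
        converged = np.max(np.abs(grad)) < GRADIENT_TOL * scale
    converged = converged or np.max(np.abs(grad)) < GRADIENT_TOL * scale

    separation = bool(np.any(np.abs(beta) > SEPARATION_COEF))
    if separation:
        logger.warning(
            "possible complete separation: |coef| > %g in model %s",
            SEPARATION_COEF,
            list(X_df.columns),
        )
    if not variance:
        nan = np.full(p, np.nan)
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": nan,
                "hr": np.exp(beta),
                "ci_lower": nan,
                "ci_upper": nan,
                "p": nan,
            },
            index=list(X_df.columns),
        )
        return CoxFit(
            summary, float(ll), n, n_events, converged, separation, groups, dropped
        )

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)

    if spec.cluster_col is not None:
        resid = _score_residuals(prob, beta)
        clusters = data[spec.cluster_col].to_numpy()[prob.order]
        codes, _ = pd.factorize(clusters)
        U = np.zeros((codes.max() + 1, p))
        np.add.at(U, codes, prob.w[:, None] * resid)
        meat = U.T @ U
        cov = cov @ meat @ cov

    se = np.sqrt(np.abs(np.diag(cov)))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # degenerate fits can overflow exp()
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_lower": np.exp(beta - Z_95 * se),
                "ci_upper": np.exp(beta + Z_95 * se),
                "p": pvals,
            },
            index=list(X_df.columns),
        )
    return CoxFit(summary, float(ll), n, n_events, converged, separation, groups, dropped)


def _score_residuals(prob: "_CoxProblem", beta):
    """Per-record Cox score residuals (Breslow form), in problem sort order.

    Exact for tie-free data; for tied event times this is the standard
    Breslow-denominator approximation used for robust variances.
    """
    X, times, events, w = prob.X, prob.times, prob.events, prob.w
    eta = X @ beta
    r = w * np.exp(eta)
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    first = prob.first
    ev = prob.ev
    S0 = s0[first[ev]]
    m = s1[first[ev]] / S0[:, None]
    we = w[ev]
    # cumulative A(t) = sum_{t_k <= t} w_k / S0_k ; B(t) analogous with m
    a = np.cumsum(we / S0)
    b = np.cumsum(we[:, None] * m / S0[:, None], axis=0)
    pos = np.searchsorted(times[ev], times, side="right") - 1
    A = np.where(pos >= 0, a[np.maximum(pos, 0)], 0.0)
    B = np.where(pos[:, None] >= 0, b[np.maximum(pos, 0)], 0.0)
    U = -np.exp(eta)[:, None] * (X * A[:, None] - B)
    U[ev] += X[ev] - m
    return U


def fast_backward_aic(
    data: pd.DataFrame, spec: CoxModelSpec, ties: str = "efron"
) -> tuple[CoxModelSpec, CoxFit, list[dict]]:
    """Backward elimination of covariate groups by AIC.

    At each step every candidate model with one term removed (a categorical's
    indicators leave together) is refit exactly; the removal giving the
    largest AIC decrease is applied; stops when no removal decreases AIC.
    Returns the retained spec, its fit, and a per-step trace.

    Candidate fits skip variance estimation (AIC needs only the likelihood)
    and warm-start from the incumbent's coefficients; the retained model is
    refit once with full variance at the end.
    """
    current_spec = spec
    current_fit = fit_cox(data, current_spec, ties=ties, variance=False)
    trace: list[dict] = []
    while current_spec.covariates:
        warm = dict(current_fit.summary["coef"])
        candidates = {}
        for cov in current_spec.covariates:
            cand = current_spec.without(cov.name)
            candidates[cov.name] = fit_cox(
                data, cand, ties=ties, variance=False, initial=warm
            )
        best = min(candidates, key=lambda name: candidates[name].aic)
        if candidates[best].aic < current_fit.aic:
            trace.append(
                {
                    "removed": best,
                    "aic_before": current_fit.aic,
                    "aic_after": candidates[best].aic,
                    "candidate_aics": {k: f.aic for k, f in candidates.items()},
                }
            )
            current_spec = current_spec.without(best)
            current_fit = candidates[best]
        else:
            break
    final = fit_cox(
        data, current_spec, ties=ties, initial=dict(current_fit.summary["coef"])
    )
    return current_spec, final, trace


# ---------------------------------------------------------------------------
# nonparametric pieces


def km_estimate(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray | None = None
) -> dict[object, KMCurve]:
    """Kaplan-Meier product-limit curves per group.

    At tied times, events are processed before censorings (the standard
    convention).  Returns a mapping group label -> KMCurve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    out: dict[object, KMCurve] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tbl = kmf.event_table
        ev_rows = tbl[tbl["observed"] > 0]
        ev_times = ev_rows.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.loc[ev_times].to_numpy().ravel()
        at_risk = ev_rows["at_risk"].to_numpy(dtype=float)
        out[g] = KMCurve(ev_times, surv, at_risk)
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Unweighted log-rank test across >=2 groups; chi-square on (k-1) df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least 1 event")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's automatic policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: no evidence of shift regardless of method
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def pearson_with_category(
    x, y, thresholds: tuple[float, float] = (0.3, 0.8)
) -> tuple[float, str]:
    """Pearson r with the field's verbal strength category.

    |r| > hi: strong; lo < |r| <= hi: moderate; |r| <= lo: weak.  The
    boundary values fall to the lower category (the strict-inequality
    convention leaves them undefined otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r = float(stats.pearsonr(x, y).statistic)
    lo, hi = thresholds
    a = abs(r)
    category = "strong" if a > hi else ("moderate" if a > lo else "weak")
    return r, category
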