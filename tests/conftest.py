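"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (loops over event
times, exhaustive enumeration, closed forms) kept independent of the package
code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from radscreen import RunConfig
from radscreen.config import ClinicalSchema, CovariateDecl


# ---------------------------------------------------------------------------
# oracles


def efron_loglik_oracle(beta, X, time, event, w=None):
    """Efron partial log-likelihood by direct loop over unique event times."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    w = np.ones(len(time)) if w is None else np.asarray(w, dtype=float)
    eta = X @ beta
    r = w * np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        d = len(D)
        wbar = w[D].sum() / d
        ll += float(np.sum(w[D] * eta[D]))
        s0R = r[R].sum()
        s0D = r[D].sum()
        for ell in range(d):
            ll -= wbar * np.log(s0R - (ell / d) * s0D)
    return ll


def maximize_efron_oracle(X, time, event, w=None):
    """Brute-force maximization of the Efron partial likelihood."""
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    res = minimize(
        lambda b: -efron_loglik_oracle(b, X, time, event, w),
        np.zeros(p),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    return res.x


def km_oracle(times, events):
    """Product-limit estimate by direct loop; returns (event_times, S)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_oracle(times, events, groups):
    """Two-group log-rank chi-square via the O-E / V hand formula."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    g1 = groups == labels[0]
    O_minus_E = 0.0
    V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(O_minus_E**2 / V)


def ranksum_exact_p(x, y):
    """Two-sided exact Wilcoxon rank-sum p by complete enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    nx = len(x)
    observed = ranks[:nx].sum()
    idx = range(len(pooled))
    stats_all = [sum(ranks[list(c)]) for c in combinations(idx, nx)]
    stats_all = np.array(stats_all)
    mean = stats_all.mean()
    p = np.mean(np.abs(stats_all - mean) >= abs(observed - mean) - 1e-12)
    return float(p)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def run_config():
    return RunConfig(seed=0)


@pytest.fixture
def toy_survival():
    """25 records with tied event times and two covariates."""
    rng = np.random.default_rng(42)
    n = 25
    x1 = rng.normal(size=n)
    x2 = rng.integers(0, 2, n).astype(float)
    t = np.ceil(rng.exponential(5.0 / np.exp(0.6 * x1 - 0.4 * x2)))
    e = (rng.random(n) < 0.75).astype(float)
    return pd.DataFrame({"time": t, "event": e, "x1": x1, "x2": x2})


@pytest.fixture
def basic_schema():
    return ClinicalSchema(
        covariates=(
            CovariateDecl("age_group", "categorical", "0"),
            CovariateDecl("chemotherapy", "categorical", "0"),
            CovariateDecl("stage", "categorical", "0"),
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small eligible synthetic cohort shared by read-only tests."""
    from radscreen.prep import apply_eligibility
    from radscreen.synthetic import (
        GeneEffectSpec,
        SyntheticConfig,
        generate_cohort,
    )

    genes = (
        GeneEffectSpec.type1("T1", np.log(0.35)),
        GeneEffectSpec.type2("T2", np.log(2.2)),
        GeneEffectSpec.null("N1"),
        GeneEffectSpec.null("N2"),
    )
    sim = SyntheticConfig(n_patients=600, gene_specs=genes, seed=7)
    expr, clin, truth = generate_cohort(sim)
    cohort = apply_eligibility(expr, clin, RunConfig(seed=7), sim.schema)
    return cohort, truth, sim
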