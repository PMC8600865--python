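"""Survival-engine tests: Cox fits against brute-force and lifelines oracles,
backward selection, Kaplan-Meier, log-rank, Wilcoxon and correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radscreen.engine import (
    Covariate,
    CoxModelSpec,
    fast_backward_aic,
    fit_cox,
    km_estimate,
    logrank_test,
    pearson_with_category,
    wilcoxon_ranksum,
)

from conftest import (
    efron_loglik_oracle,
    km_oracle,
    logrank_oracle,
    maximize_efron_oracle,
    ranksum_exact_p,
)


def _toy(seed, n=20, tied=True, p=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    t = rng.exponential(3.0 / np.exp(X @ np.linspace(0.8, 0.3, p)))
    if tied:
        t = np.maximum(np.ceil(t * 2) / 2, 0.5)  # induce tied event times
    e = (rng.random(n) < 0.8).astype(float)
    if e.sum() == 0:
        e[0] = 1
    cols = {f"x{j}": X[:, j] for j in range(p)}
    return pd.DataFrame({"time": t, "event": e, **cols})


class TestCoxFit:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6])
    def test_matches_bruteforce_efron_maximizer_on_tied_toys(self, seed):
        """Coefficients agree with direct maximization of the Efron partial
        likelihood on <=25-record datasets with tied event times."""
        df = _toy(seed, n=20 + seed, tied=True)
        spec = CoxModelSpec("time", "event", (Covariate("x0"),))
        fit = fit_cox(df, spec)
        oracle = maximize_efron_oracle(
            df[["x0"]].to_numpy(), df["time"], df["event"]
        )
        assert fit.converged
        assert abs(fit.coef("x0") - oracle[0]) < 1e-6

    def test_loglik_matches_oracle_at_fit(self):
        df = _toy(11, n=24, tied=True)
        spec = CoxModelSpec("time", "event", (Covariate("x0"),))
        fit = fit_cox(df, spec)
        ll = efron_loglik_oracle(
            [fit.coef("x0")], df[["x0"]].to_numpy(), df["time"], df["event"]
        )
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_two_covariates_match_lifelines(self):
        """Independent library cross-check, including tied times and SEs."""
        from lifelines import CoxPHFitter

        df = _toy(9, n=120, tied=True, p=2)
        spec = CoxModelSpec("time", "event", (Covariate("x0"), Covariate("x1")))
        fit = fit_cox(df, spec)
        cph = CoxPHFitter().fit(df, "time", "event")
        # lifelines' own stopping rule leaves ~1e-5 slack on coefficients
        assert np.allclose(fit.summary["coef"], cph.params_.values, atol=2e-4)
        assert np.allclose(fit.summary["se"], cph.standard_errors_.values, atol=2e-4)

    def test_null_covariate_large_n(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame(
            {
                "time": rng.exponential(10, n),
                "event": np.ones(n),
                "x": rng.integers(0, 2, n).astype(float),
            }
        )
        fit = fit_cox(df, CoxModelSpec("time", "event", (Covariate("x"),)))
        se = float(fit.summary.loc["x", "se"])
        assert abs(fit.coef("x")) < 3 * se
        assert fit.hr("x") == pytest.approx(1.0, abs=0.1)

    def test_weight_invariance_under_record_duplication(self):
        """Duplicating every record with weight 1/2 leaves coefficients
        unchanged (Breslow ties, which the stacked path uses)."""
        df = _toy(5, n=22, tied=False)
        spec = CoxModelSpec("time", "event", (Covariate("x0"),))
        plain = fit_cox(df, spec, ties="breslow")
        doubled = pd.concat([df, df], ignore_index=True)
        doubled["w"] = 0.5
        specw = CoxModelSpec("time", "event", (Covariate("x0"),), weight_col="w")
        weighted = fit_cox(doubled, specw, ties="breslow")
        assert weighted.coef("x0") == pytest.approx(plain.coef("x0"), abs=1e-8)
        assert weighted.log_likelihood == pytest.approx(plain.log_likelihood, abs=1e-8)

    def test_hr_and_ci_consistent_with_coef(self):
        df = _toy(3, n=25)
        fit = fit_cox(df, CoxModelSpec("time", "event", (Covariate("x0"),)))
        row = fit.summary.loc["x0"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]), rel=1e-12)
        assert row["ci_lower"] == pytest.approx(
            np.exp(row["coef"] - 1.959963984540054 * row["se"]), rel=1e-9
        )
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.k)

    def test_zero_events_raises(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0.0, 0.0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(df, CoxModelSpec("time", "event", (Covariate("x"),)))

    def test_separation_flagged_not_raised(self):
        # a perfectly separating covariate on a small scale drives |coef|
        # past the separation threshold without raising
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 5, 6, 7, 8.0],
                "event": [1, 1, 1, 1, 1, 1, 1, 1.0],
                "x": [0.05, 0.05, 0.05, 0.05, 0, 0, 0, 0.0],
            }
        )
        fit = fit_cox(df, CoxModelSpec("time", "event", (Covariate("x"),)))
        assert fit.separation
        assert np.isfinite(fit.log_likelihood)

    def test_categorical_expansion_drops_reference(self):
        df = _toy(8, n=25)
        df["grade"] = np.random.default_rng(1).choice(["low", "mid", "hi"], len(df))
        spec = CoxModelSpec(
            "time", "event", (Covariate("grade", "categorical", "low"),)
        )
        fit = fit_cox(df, spec)
        assert set(fit.summary.index) == {"grade[hi]", "grade[mid]"}
        assert fit.term_groups["grade"] == ["grade[hi]", "grade[mid]"]

    def test_cluster_sandwich_matches_lifelines(self):
        from lifelines import CoxPHFitter

        df = _toy(12, n=200, tied=False, p=2)
        df["w"] = np.random.default_rng(2).uniform(0.5, 1.5, len(df))
        df["id"] = np.arange(len(df)) // 2
        spec = CoxModelSpec(
            "time", "event", (Covariate("x0"), Covariate("x1")),
            weight_col="w", cluster_col="id",
        )
        fit = fit_cox(df, spec)
        cph = CoxPHFitter().fit(
            df, "time", "event", weights_col="w", cluster_col="id",
            robust=True, formula="x0 + x1",
        )
        assert np.allclose(fit.summary["se"], cph.standard_errors_.values, atol=1e-4)
        assert np.allclose(fit.summary["coef"], cph.params_.values, atol=2e-4)


class TestFastBackward:
    def test_strong_covariate_retained_noise_often_dropped(self):
        rng = np.random.default_rng(3)
        n = 1500
        strong = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "time": rng.exponential(5 / np.exp(1.0 * strong)),
                "event": np.ones(n),
                "strong": strong,
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        spec = CoxModelSpec(
            "time", "event",
            (Covariate("strong"), Covariate("noise1"), Covariate("noise2")),
        )
        kept, fit, trace = fast_backward_aic(df, spec)
        assert any(c.name == "strong" for c in kept.covariates)

    def test_trace_aic_strictly_decreasing_and_final_not_worse(self):
        rng = np.random.default_rng(4)
        n = 300
        df = pd.DataFrame(
            {
                "time": rng.exponential(5, n),
                "event": np.ones(n),
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        spec = CoxModelSpec(
            "time", "event", (Covariate("a"), Covariate("b"), Covariate("c"))
        )
        kept, fit, trace = fast_backward_aic(df, spec)
        full_fit = fit_cox(df, spec)
        aics = [step["aic_before"] for step in trace] + (
            [trace[-1]["aic_after"]] if trace else []
        )
        assert all(x > y for x, y in zip(aics, aics[1:]))
        assert fit.aic <= full_fit.aic + 1e-9

    def test_all_noise_may_empty_the_model(self):
        """With pure noise the selection can remove everything; the result is
        then the null model, whose AIC is -2 * loglik."""
        rng = np.random.default_rng(12)
        n = 400
        df = pd.DataFrame(
            {
                "time": rng.exponential(5, n),
                "event": np.ones(n),
                "a": rng.normal(size=n),
            }
        )
        kept, fit, trace = fast_backward_aic(
            df, CoxModelSpec("time", "event", (Covariate("a"),))
        )
        if not kept.covariates:
            assert fit.k == 0
            assert fit.aic == pytest.approx(-2 * fit.log_likelihood)


class TestKaplanMeier:
    def test_three_events_hand_values(self):
        curves = km_estimate([1, 2, 3], [1, 1, 1])
        c = curves[0]
        assert np.allclose(c.times, [1, 2, 3])
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        curves = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(curves[0].times) == 0  # no event times: S == 1 throughout

    def test_mixed_toy_matches_hand_computation(self):
        """6 records incl. censoring: product-limit steps 5/6, 2/3, 4/9, 0."""
        times = [1, 2, 2, 3, 4, 5]
        events = [1, 0, 1, 1, 0, 1]
        c = km_estimate(times, events)[0]
        t_or, s_or = km_oracle(times, events)
        assert np.allclose(c.times, t_or)
        assert np.allclose(c.survival, s_or)
        assert np.allclose(c.survival, [5 / 6, 5 / 6 * 4 / 5, 5 / 6 * 4 / 5 * 2 / 3, 0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.5, 50), st.booleans()), min_size=2, max_size=30))
    def test_curve_invariants(self, records):
        times = [r[0] for r in records]
        events = [int(r[1]) for r in records]
        c = km_estimate(times, events)[0]
        assert np.all(np.diff(c.times) > 0)
        assert np.all(c.survival >= -1e-12) and np.all(c.survival <= 1 + 1e-12)
        assert np.all(np.diff(c.survival) <= 1e-12)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(3, 40)
        c = km_estimate(t, np.ones(40))[0]
        ecdf = np.array([(t <= ti).mean() for ti in c.times])
        assert np.allclose(c.survival, 1 - ecdf)


class TestLogrank:
    def test_duplicated_groups_give_zero_statistic(self):
        t = [1, 2, 3, 4, 5.0]
        e = [1, 0, 1, 1, 0]
        stat, p = logrank_test(t + t, e + e, [0] * 5 + [1] * 5)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_formula_on_toy(self):
        rng = np.random.default_rng(6)
        t = np.concatenate([rng.exponential(3, 15), rng.exponential(6, 15)])
        e = (rng.random(30) < 0.8).astype(int)
        g = np.repeat([0, 1], 15)
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(logrank_oracle(t, e, g), rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(3, 40)
        e = np.ones(40)
        g = rng.integers(0, 2, 40)
        s1, _ = logrank_test(t, e, g)
        s2, _ = logrank_test(t, e, 1 - g)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_null_rejection_rate_near_alpha(self):
        """Under H0 the 5%-level rejection rate is ~5% (Monte-Carlo)."""
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 200
        for _ in range(reps):
            t = rng.exponential(3, 120)
            e = (rng.random(120) < 0.8).astype(int)
            g = rng.integers(0, 2, 120)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
                continue
            _, p = logrank_test(t, e, g)
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.11

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2, 3], [1, 1, 0], [0, 0, 0])


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        _, p = wilcoxon_ranksum([1, 2, 3.0], [1, 2, 3.0])
        assert p == 1.0

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 50)
        y = rng.normal(10, 1, 50)
        _, p = wilcoxon_ranksum(x, y)
        assert p < 1e-6

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exact_enumeration_at_4_4(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(0.5, 1, size=4)
        _, p = wilcoxon_ranksum(x, y)
        assert p == pytest.approx(ranksum_exact_p(x, y), abs=1e-10)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestPearsonCategory:
    def test_perfect_and_anti_correlation_strong(self):
        x = np.arange(10.0)
        r, cat = pearson_with_category(x, x)
        assert r == pytest.approx(1.0)
        assert cat == "strong"
        r, cat = pearson_with_category(x, -x)
        assert r == pytest.approx(-1.0)
        assert cat == "strong"

    @staticmethod
    def _pair_with_exact_r(r, n=16, seed=0):
        """Construct (x, y) whose sample Pearson correlation is exactly r."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = x - x.mean()
        z = z - z.mean()
        z = z - (z @ x) / (x @ x) * x
        x = x / np.linalg.norm(x)
        z = z / np.linalg.norm(z)
        return x, r * x + np.sqrt(1 - r * r) * z

    @pytest.mark.parametrize(
        "r,expected",
        [(0.15, "weak"), (-0.15, "weak"), (0.5, "moderate"), (-0.5, "moderate"),
         (0.85, "strong"), (-0.85, "strong")],
    )
    def test_category_cuts(self, r, expected):
        x, y = self._pair_with_exact_r(r)
        got_r, cat = pearson_with_category(x, y)
        assert got_r == pytest.approx(r, abs=1e-9)
        assert cat == expected

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_with_category([1, 1, 1.0], [1, 2, 3.0])
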