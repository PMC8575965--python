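"""Survival engine oracles: brute-force partial likelihood, hand product-limit,
hand log-rank, closed-form exponential MLE, and lifelines cross-checks."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from minerva_nsclc import (
    ConvergenceError,
    DegenerateDataError,
    cox_score_test,
    fit_cox,
    km_estimate,
    km_summary,
    km_to_frame,
    logrank_test,
    wald_summary,
    z_from_printed_ci,
)
from minerva_nsclc.survival import _PartialLikelihood, CoxFit


def exact_partial_likelihood(beta, time, event, x):
    """Independent oracle: the textbook untied partial log-likelihood,
    written as explicit loops over event times and risk sets."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


TOY6 = dict(
    time=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    event=[True, True, False, True, True, False],
    x=[1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
)


class TestCoxFit:
    def test_matches_brute_force_grid_on_toy_set(self):
        """Two-stage grid maximisation of the exact partial likelihood agrees
        with the Newton fit to 1e-6 on a 6-observation tie-free instance."""
        t, e, x = TOY6["time"], TOY6["event"], TOY6["x"]
        grid = np.linspace(-5, 5, 2001)
        lls = [exact_partial_likelihood(b, t, e, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        fine = np.arange(best - 0.01, best + 0.01, 1e-7)
        lls = [exact_partial_likelihood(b, t, e, x) for b in fine]
        oracle = fine[int(np.argmax(lls))]
        fit = fit_cox(pd.DataFrame({"time": t, "event": e, "x": x}), ["x"])
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(oracle, abs=1e-6)

    def test_recovers_exponential_rate_ratio(self):
        """Uncensored two-arm exponential data with true hazard ratio 2: the
        Cox coefficient lands within 3 standard errors of ln 2 (the
        exponential MLE of the log rate ratio is the closed-form oracle)."""
        rng = np.random.default_rng(42)
        n = 1000
        t0 = rng.exponential(1.0, n)
        t1 = rng.exponential(0.5, n)
        df = pd.DataFrame(
            {
                "time": np.concatenate([t0, t1]),
                "event": True,
                "x": np.repeat([0.0, 1.0], n),
            }
        )
        fit = fit_cox(df, ["x"])
        assert abs(fit.coefficients[0] - math.log(2)) < 3 * fit.se("x")

    def test_constant_interaction_column_named_in_error(self):
        df = pd.DataFrame(
            {"time": [1.0, 2, 3, 4], "event": [1, 1, 0, 1],
             "arm": [0.0, 1, 0, 1], "arm_gene": [0.0, 0, 0, 0]}
        )
        with pytest.raises(DegenerateDataError, match="arm_gene"):
            fit_cox(df, ["arm", "arm_gene"])

    def test_zero_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False], "x": [0.0, 1.0]})
        with pytest.raises(DegenerateDataError, match="events"):
            fit_cox(df, ["x"])

    def test_perfect_separation_names_covariate(self):
        # all events carry x=1 and precede every x=0 time: beta diverges
        df = pd.DataFrame(
            {
                "time": [1.0, 2, 3, 10, 11, 12],
                "event": [True, True, True, False, False, False],
                "x": [1.0, 1, 1, 0, 0, 0],
            }
        )
        with pytest.raises(ConvergenceError) as err:
            fit_cox(df, ["x"])
        assert err.value.covariate == "x"

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines_with_ties(self, ties, adjuvant_cohort):
        """Cross-check coefficients and standard errors against lifelines on
        tied cohort data (lifelines implements Efron; Breslow is compared on
        tie-free data below)."""
        from minerva_nsclc.screen import survival_frame

        sf = survival_frame(adjuvant_cohort.clinical)
        g = adjuvant_cohort.fm.to_frame()["RB1_alt"].astype(float)
        df = sf.assign(gene=g, arm_gene=sf["arm"] * g)
        df["time"] = np.round(df["time"], 0).clip(lower=1.0)  # force ties
        if ties == "breslow":
            df["time"] = sf["time"]  # tie-free: efron == breslow
        fit = fit_cox(df, ["arm", "gene", "arm_gene"], ties=ties)
        cph = CoxPHFitter().fit(df.reset_index(drop=True), "time", "event")
        np.testing.assert_allclose(
            fit.coefficients, cph.params_[["arm", "gene", "arm_gene"]], atol=1e-4
        )
        np.testing.assert_allclose(
            [fit.se(c) for c in ("arm", "gene", "arm_gene")],
            cph.standard_errors_[["arm", "gene", "arm_gene"]],
            atol=1e-4,
        )

    def test_local_maximality(self):
        """The fitted coefficients maximise the partial likelihood locally:
        random perturbations never increase it."""
        t, e, x = TOY6["time"], TOY6["event"], TOY6["x"]
        fit = fit_cox(pd.DataFrame({"time": t, "event": e, "x": x}), ["x"])
        pl = _PartialLikelihood(
            np.array(t), np.array(e), np.array(x).reshape(-1, 1), "efron"
        )
        ll_hat = pl(fit.coefficients)[0]
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert pl(fit.coefficients + rng.normal(0, 0.2, 1))[0] <= ll_hat + 1e-12


class TestWaldSummary:
    def test_reconstruction_identity(self):
        fit = fit_cox(
            pd.DataFrame(TOY6).rename(columns={"x": "g"}).assign(
                time=TOY6["time"], event=TOY6["event"]
            ),
            ["g"],
        )
        w = wald_summary(fit, "g")
        assert w.z * fit.se("g") == pytest.approx(fit.coef("g"), abs=1e-12)
        assert w.ci_low <= w.hr <= w.ci_high

    def test_null_effect(self):
        fit = CoxFit(
            names=["g"], coefficients=np.array([0.0]), covariance=np.array([[0.25]]),
            log_partial_likelihood=0.0, n=10, n_events=5, converged=True,
            ties_method="efron",
        )
        w = wald_summary(fit, "g")
        assert (w.hr, w.z, w.p) == (1.0, 0.0, 1.0)

    def test_sign_flip_reciprocates(self):
        common = dict(covariance=np.array([[0.04]]), log_partial_likelihood=0.0,
                      n=10, n_events=5, converged=True, ties_method="efron")
        wp = wald_summary(CoxFit(names=["g"], coefficients=np.array([0.7]), **common), "g")
        wn = wald_summary(CoxFit(names=["g"], coefficients=np.array([-0.7]), **common), "g")
        assert wn.z == -wp.z
        assert wn.hr == pytest.approx(1 / wp.hr)
        assert wn.ci_low == pytest.approx(1 / wp.ci_high)

    def test_term_absent_raises(self):
        fit = fit_cox(pd.DataFrame(TOY6).assign(time=TOY6["time"]), ["x"])
        with pytest.raises(KeyError):
            wald_summary(fit, "nope")


class TestKaplanMeier:
    def test_pure_event_data_is_empirical_survivor(self):
        curve = km_estimate([1.0, 2, 3, 4], [True] * 4)
        assert curve.survival_at(2.5) == 0.5
        assert curve.survival_at(4) == 0.0
        s = km_summary(curve)
        assert s.median == 2.0  # earliest time with S <= 0.5

    def test_all_censored(self):
        curve = km_estimate([1.0, 2, 3], [False] * 3)
        assert (curve.surv == 1.0).all() and (curve.greenwood_var == 0).all()
        assert km_summary(curve).median is None

    def test_hand_product_limit(self):
        """{(1,event),(2,censored),(3,event)}: S(1) = 2/3 (3 at risk, 1
        event); the censoring at 2 leaves 1 at risk at t=3, so S(3) = 0."""
        curve = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == 0.0
        # Greenwood at t=1: S^2 * d/(n(n-d)) = (2/3)^2 * 1/(3*2)
        assert curve.variance_at(1) == pytest.approx((2 / 3) ** 2 / 6)

    def test_events_precede_censorings_at_ties(self):
        # censored subject at t=2 is still at risk for the event at t=2
        curve = km_estimate([2.0, 2.0, 3.0], [True, False, True])
        assert curve.survival_at(2) == pytest.approx(2 / 3)

    def test_matches_lifelines(self, adjuvant_cohort):
        from minerva_nsclc.screen import survival_frame

        sf = survival_frame(adjuvant_cohort.clinical)
        sf["time"] = np.round(sf["time"], 0).clip(lower=1.0)
        curve = km_estimate(sf["time"], sf["event"])
        kmf = KaplanMeierFitter().fit(sf["time"], sf["event"])
        ref = kmf.survival_function_["KM_estimate"]
        ours = [curve.survival_at(t) for t in ref.index[1:]]
        np.testing.assert_allclose(ours, ref.values[1:], atol=1e-12)

    def test_horizon_zero_collapsed_ci(self):
        curve = km_estimate([1.0, 2.0], [True, True])
        s = km_summary(curve, horizons=[0.0])
        assert s.horizons[0][1:] == (1.0, 1.0, 1.0)

    def test_monotone_nonincreasing(self, adjuvant_cohort):
        from minerva_nsclc.screen import survival_frame

        sf = survival_frame(adjuvant_cohort.clinical)
        curve = km_estimate(sf["time"], sf["event"])
        assert (np.diff(curve.surv) <= 1e-15).all()
        frame = km_to_frame(curve)
        assert (frame["ci_low"] <= frame["surv"] + 1e-12).all()
        assert (frame["surv"] <= frame["ci_high"] + 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t, e = [1.0, 2, 3], [True, True, False]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_eight_patient_oracle(self):
        """O-E and hypergeometric variance computed by hand on an 8-patient
        instance: O_A - E_A = 47/70, V = 605/490 -> chi2 = 0.365063..."""
        ta, ea = [1.0, 3.0, 5.0, 7.0], [True, False, True, True]
        tb, eb = [2.0, 4.0, 6.0, 8.0], [True, True, False, True]
        o_minus_e = 3 - (0.5 + 3 / 7 + 2 / 5 + 0.5 + 0.5)
        var = 0.25 + 12 / 49 + 6 / 25 + 0.25 + 0.25
        chi2, p = logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(o_minus_e**2 / var, abs=1e-12)
        assert 0 <= p <= 1

    def test_equals_cox_score_test_tie_free(self):
        rng = np.random.default_rng(3)
        n = 80
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1 / np.exp(0.5 * x))
        c = rng.uniform(0.2, 2.0, n)
        time, ev = np.minimum(t, c), t <= c
        chi2_lr, _ = logrank_test(time[x == 1], ev[x == 1], time[x == 0], ev[x == 0])
        chi2_sc, _ = cox_score_test(
            pd.DataFrame({"time": time, "event": ev, "x": x}), ["x"], ties="breslow"
        )
        assert chi2_lr == pytest.approx(chi2_sc, abs=1e-6)

    def test_label_swap_invariance(self):
        ta, ea = [1.0, 3.0, 5.0], [True, True, False]
        tb, eb = [2.0, 4.0, 6.0], [True, False, True]
        assert logrank_test(ta, ea, tb, eb) == logrank_test(tb, eb, ta, ea)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            logrank_test([1.0], [True], [], [])


class TestPrintedCIReconstruction:
    def test_z_from_hr_and_ci(self):
        # z = ln(hr) / se with se recovered from the CI width on the log scale
        z = z_from_printed_ci(2.0, 1.0, 4.0)
        se = (math.log(4.0) - math.log(1.0)) / (2 * 1.959964)
        assert z == pytest.approx(math.log(2.0) / se, rel=1e-6)
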