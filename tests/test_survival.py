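import numpy as np
import pandas as pd
import pytest

from stratmeta.survival import (
    cox_continuous,
    filter_survival_window,
    km_estimate,
    logrank_mh,
)


def _records(times, events):
    return pd.DataFrame({"os_months": times, "event": events})


class TestWindowFilter:
    def test_boundary_enumeration(self):
        res = filter_survival_window(_records([0.0, 5.0, 30.0, 31.0], [True] * 4))
        assert sorted(res.records["os_months"]) == [5.0, 30.0]
        assert res.n_removed_zero == 1
        assert res.n_removed_over == 1

    def test_identity_inside_window(self):
        res = filter_survival_window(_records([1.0, 15.0, 29.9], [True, False, True]))
        assert len(res.records) == 3 and res.n_removed == 0

    def test_exactly_thirty_retained(self):
        # the rule removes strictly more than 30 months, not the boundary
        res = filter_survival_window(_records([30.0], [True]))
        assert len(res.records) == 1

    def test_zero_month_censored_also_removed(self):
        res = filter_survival_window(_records([0.0], [False]))
        assert res.n_removed_zero == 1


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        km = km_estimate([1.0, 2.0], [False, False])
        assert (km["survival"] == 1.0).all()
        assert km["events"].sum() == 0

    def test_tied_event_and_censor_hand_computed(self):
        # times (1,2,2,3,4), events (1,1,0,1,0): the event at t=2 is
        # processed before the censoring, so S = 4/5, 3/5, 3/10
        km = km_estimate([1, 2, 2, 3, 4], [True, True, False, True, False])
        surv = km["survival"]
        assert surv.loc[1] == pytest.approx(0.8)
        assert surv.loc[2] == pytest.approx(0.6)
        assert surv.loc[3] == pytest.approx(0.3)

    def test_no_censoring_matches_empirical_survival(self, rng):
        t = rng.exponential(10, size=200).round(1) + 0.1
        km = km_estimate(t, np.ones(200, dtype=bool))
        for u, s in km["survival"].items():
            assert s == pytest.approx((t > u).mean())


class TestLogrankMH:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [True] * 8
        g = ["HIGH"] * 4 + ["LOW"] * 4
        res = logrank_mh(t, e, g)
        assert res.hr == pytest.approx(1.0)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_label_swap_inverts_hr(self, rng):
        t = rng.exponential(10, size=60)
        e = rng.random(60) < 0.8
        g = np.where(rng.random(60) < 0.5, "HIGH", "LOW")
        a = logrank_mh(t, e, g)
        b = logrank_mh(t, e, g, group_a="LOW", group_b="HIGH")
        assert b.hr == pytest.approx(1 / a.hr)
        assert b.p_two_tailed == pytest.approx(a.p_two_tailed)

    def test_eight_record_fixture_against_bruteforce(self):
        times = np.array([1, 3, 5, 7, 2, 4, 6, 8], dtype=float)
        events = np.array([1, 1, 0, 1, 1, 1, 1, 0], dtype=bool)
        groups = np.array(["HIGH"] * 4 + ["LOW"] * 4)
        res = logrank_mh(times, events, groups)

        # independent brute-force oracle: enumerate the 2x2 table at each event time
        O = E = V = 0.0
        for u in sorted(set(times[events])):
            risk = times >= u
            n = risk.sum()
            n_a = (risk & (groups == "HIGH")).sum()
            d = ((times == u) & events).sum()
            d_a = ((times == u) & events & (groups == "HIGH")).sum()
            O += d_a
            E += d * n_a / n
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        assert res.o_minus_e == pytest.approx(O - E)
        assert res.variance_v == pytest.approx(V)
        assert res.hr == pytest.approx(np.exp((O - E) / V))

        from lifelines.statistics import logrank_test

        lr = logrank_test(times[:4], times[4:], events[:4], events[4:])
        assert res.p_two_tailed == pytest.approx(lr.p_value)

    def test_ci_brackets_hr(self, rng):
        t = rng.exponential(10, size=80)
        e = rng.random(80) < 0.9
        g = np.where(rng.random(80) < 0.5, "HIGH", "LOW")
        res = logrank_mh(t, e, g)
        assert res.ci_low <= res.hr <= res.ci_high

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_mh([1, 2], [True, True], ["HIGH", "HIGH"])

    def test_no_events_error(self):
        with pytest.raises(ValueError, match="event"):
            logrank_mh([1, 2], [False, False], ["HIGH", "LOW"])


class TestCoxContinuous:
    def test_constant_covariate_flagged(self):
        res = cox_continuous([1, 2, 3, 4], [True, True, True, False], [2.0] * 4)
        assert not res.converged
        assert "no information" in res.flag

    def test_sign_equivariance(self, rng):
        t = rng.exponential(5, size=100)
        e = rng.random(100) < 0.8
        x = rng.normal(size=100)
        a = cox_continuous(t, e, x)
        b = cox_continuous(t, e, -x)
        assert b.beta == pytest.approx(-a.beta, rel=1e-6)

    def test_parameter_recovery_exponential_model(self, rng):
        # hazard h0*exp(beta*x) with beta = -0.5; light censoring
        n = 2000
        beta = -0.5
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
        c = rng.exponential(40.0, size=n)
        obs = np.minimum(t, c)
        e = t <= c
        res = cox_continuous(obs, e, x)
        assert res.converged
        assert res.beta == pytest.approx(beta, abs=0.1)
        assert res.ci_low <= np.exp(beta) <= res.ci_high

    def test_matches_lifelines_on_tied_data(self, rng):
        n = 150
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(1.0 / (0.2 * np.exp(0.4 * x))))  # heavy month ties
        e = rng.random(n) < 0.85
        mine = cox_continuous(t, e, x, ties="efron")

        from lifelines import CoxPHFitter

        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert mine.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert mine.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_breslow_and_efron_agree_without_ties(self, rng):
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(5, size=n)  # continuous: no ties
        e = rng.random(n) < 0.9
        a = cox_continuous(t, e, x, ties="efron")
        b = cox_continuous(t, e, x, ties="breslow")
        assert a.beta == pytest.approx(b.beta, rel=1e-8)

    def test_monotone_likelihood_flagged(self):
        # covariate perfectly ordered with event times -> divergent beta
        t = np.arange(1.0, 21.0)
        e = np.ones(20, dtype=bool)
        x = np.arange(20.0)
        res = cox_continuous(t, e, x)
        assert not res.converged or abs(res.beta) > 5
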