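import numpy as np
import pytest

from molarisk.cohort import Group, Outcome, PatientRecord
from molarisk.inference import HAZARD_PRIOR, McmcConfig, PosteriorDraws, PriorSpec, inv_logit, logit
from molarisk.simulate import SimulationParams, simulate_cohort
from molarisk.tte import (
    CumulativeIncidenceCurve,
    HazardFit,
    RiskTable,
    build_risk_table,
    cumulative_incidence,
    fit_interval_hazards,
    risk_at_time,
)

GROUPS = (Group.EARLY, Group.LATE)


def rec(pid, outcome, days_end, days_norm=10):
    return PatientRecord(pid, days_norm, outcome, days_end)


def constant_hazard_fit(hazards_per_interval, width=3.0, n_draws=40):
    """HazardFit whose pooled draws are constant at the given hazards (EARLY group)."""
    k = len(hazards_per_interval)
    edges = np.arange(k + 1, dtype=float) * width
    table = RiskTable(
        edges=edges,
        n_at_risk={g: np.full(k, 100) for g in GROUPS},
        events={g: np.zeros(k, dtype=int) for g in GROUPS},
        censored={g: np.zeros(k, dtype=int) for g in GROUPS},
    )
    draws = {
        g: [
            PosteriorDraws("a", np.full((2, n_draws // 2), float(logit(h)) if h > 0 else -745.0),
                           np.full(2, 0.4), np.ones(2))
            for h in hazards_per_interval
        ]
        for g in GROUPS
    }
    return HazardFit(
        table=table,
        prior=HAZARD_PRIOR,
        draws=draws,
        rhat={g: np.ones(k) for g in GROUPS},
        prior_only={g: np.zeros(k, dtype=bool) for g in GROUPS},
    )


class TestRiskTable:
    def test_hand_life_table(self):
        """Events at months 1 and 4, one censored at month 2, width 3."""
        cohort = [
            rec("a", Outcome.GTN, 30),
            rec("b", Outcome.GTN, 120),
            rec("c", Outcome.CENSORED, 60),
        ]
        t = build_risk_table(cohort, interval_months=3, horizon_months=6)
        assert t.n_at_risk[Group.EARLY].tolist() == [3, 1]
        assert t.events[Group.EARLY].tolist() == [1, 1]
        assert t.censored[Group.EARLY].tolist() == [1, 0]

    def test_all_censored_within_first_interval(self):
        cohort = [rec(str(i), Outcome.CENSORED, 40) for i in range(5)]
        t = build_risk_table(cohort, interval_months=3, horizon_months=9)
        assert t.events[Group.EARLY].sum() == 0
        assert t.n_at_risk[Group.EARLY].tolist() == [5, 0, 0]

    def test_censoring_at_interval_start_leaves_before_it(self):
        # censored exactly at day 90 = month 3.0: at risk in [0,3) only
        t = build_risk_table([rec("a", Outcome.CENSORED, 90)], 3, 6)
        assert t.n_at_risk[Group.EARLY].tolist() == [1, 0]

    def test_boundary_event_falls_in_later_interval(self):
        # event at exactly month 3 belongs to [3,6) and is at risk there
        t = build_risk_table([rec("a", Outcome.GTN, 90)], 3, 6)
        assert t.events[Group.EARLY].tolist() == [0, 1]
        assert t.n_at_risk[Group.EARLY].tolist() == [1, 1]

    def test_event_beyond_horizon_flagged_in_open_interval(self):
        t = build_risk_table([rec("a", Outcome.GTN, 30), rec("b", Outcome.GTN, 3000)], 3, 90)
        assert t.overflow_flagged
        assert t.n_intervals == 31  # 30 finite + open-ended
        assert t.events[Group.EARLY][-1] == 1
        frame = t.to_frame()
        assert np.isinf(frame["t_end_months"].iloc[t.n_intervals - 1])

    def test_life_table_conservation(self, default_cohort):
        records, _ = default_cohort
        t = build_risk_table(records)
        for g in GROUPS:
            n, e, c = t.n_at_risk[g], t.events[g], t.censored[g]
            assert np.array_equal(n[:-1] - e[:-1] - c[:-1], n[1:])

    def test_generator_interval_bookkeeping(self, default_cohort):
        records, truth = default_cohort
        t = build_risk_table(records)
        planted = truth.interval_event_counts(3.0, 90.0)
        for g in GROUPS:
            assert t.events[g].sum() == truth.events[g]
            assert np.array_equal(t.events[g], planted[g][: t.n_intervals])


class TestHazardFit:
    def test_prior_only_cell_returns_pushforward(self, fast_mcmc):
        t = build_risk_table([rec("a", Outcome.CENSORED, 40)], 3, 9)
        fit = fit_interval_hazards(t, config=fast_mcmc)
        assert fit.prior_only[Group.LATE].all()  # no LATE patients at all
        med = np.median(inv_logit(fit.draws[Group.LATE][0].pooled()))
        assert med == pytest.approx(float(inv_logit(-12)), rel=0.6)

    def test_cell_median_matches_quadrature(self, fast_mcmc):
        from molarisk.inference import quadrature_posterior_1d

        cohort = [rec(str(i), Outcome.CENSORED, 2700) for i in range(4999)]
        cohort.append(rec("ev", Outcome.GTN, 30))
        t = build_risk_table(cohort, 3, 6)
        assert t.n_at_risk[Group.EARLY].tolist() == [5000, 4999]
        fit = fit_interval_hazards(t, config=McmcConfig(seed=31))
        med = np.median(inv_logit(fit.draws[Group.EARLY][0].pooled()))
        quad = quadrature_posterior_1d(1, 5000, HAZARD_PRIOR).p.median
        assert med == pytest.approx(quad, rel=0.05)

    def test_seed_reproducibility(self, fast_mcmc):
        t = build_risk_table([rec("a", Outcome.GTN, 30), rec("b", Outcome.CENSORED, 200)], 3, 6)
        f1 = fit_interval_hazards(t, config=fast_mcmc)
        f2 = fit_interval_hazards(t, config=fast_mcmc)
        for g in GROUPS:
            for d1, d2 in zip(f1.draws[g], f2.draws[g]):
                assert np.array_equal(d1.draws, d2.draws)


class TestCumulativeIncidence:
    def test_zero_hazard_gives_zero_curve(self):
        curve = cumulative_incidence(constant_hazard_fit([0.0, 0.0, 0.0]), Group.EARLY)
        assert np.allclose(curve.median, 0.0)
        assert np.allclose(curve.q97_5, 0.0)

    def test_single_interval_equals_hazard(self):
        curve = cumulative_incidence(constant_hazard_fit([0.2]), Group.EARLY)
        assert curve.median[0] == pytest.approx(0.2, rel=1e-9)

    def test_two_interval_closed_form(self):
        curve = cumulative_incidence(constant_hazard_fit([0.1, 0.2]), Group.EARLY)
        assert curve.median[1] == pytest.approx(1 - 0.9 * 0.8, rel=1e-9)

    def test_centile_curves_non_decreasing(self, fast_mcmc):
        records, _ = simulate_cohort(SimulationParams(n_early=400, n_late=600, p_early=0.05, p_late=0.08, seed=9))
        t = build_risk_table(records, interval_months=9, horizon_months=90)
        fit = fit_interval_hazards(t, config=fast_mcmc)
        for g in GROUPS:
            curve = cumulative_incidence(fit, g)
            for arr in (curve.q2_5, curve.median, curve.q97_5):
                assert np.all(np.diff(arr) >= -1e-12)
                assert np.all((arr >= 0) & (arr <= 1))

    def test_mismatched_draw_counts_rejected(self):
        fit = constant_hazard_fit([0.1, 0.2])
        fit.draws[Group.EARLY][1] = PosteriorDraws(
            "a", np.zeros((2, 7)), np.full(2, 0.4), np.ones(2)
        )
        with pytest.raises(ValueError, match="pair"):
            cumulative_incidence(fit, Group.EARLY)


class TestRiskAtTime:
    def make_curve(self, medians):
        k = len(medians)
        m = np.asarray(medians, dtype=float)
        return CumulativeIncidenceCurve(
            group=Group.EARLY,
            t_end_months=np.arange(1, k + 1, dtype=float) * 3.0,
            q2_5=m * 0.5,
            median=m,
            q97_5=m * 2.0,
        )

    def test_one_in_n_phrasing(self):
        curve = self.make_curve([0.0004])
        r = risk_at_time(curve, 3.0)
        assert r.phrase == "0.04%, about 1 in 2500"
        curve = self.make_curve([0.0016])
        assert risk_at_time(curve, 3.0).one_in_n == 625

    def test_reads_last_interval_end_at_or_before(self):
        curve = self.make_curve([0.001, 0.002, 0.003])
        assert risk_at_time(curve, 7.0).summary.median == 0.002  # last end <= 7 is 6
        assert risk_at_time(curve, 9.0).summary.median == 0.003

    def test_before_first_interval_end_rejected(self):
        with pytest.raises(ValueError):
            risk_at_time(self.make_curve([0.001]), 1.0)

    def test_monotone_in_time(self, fast_mcmc):
        records, _ = simulate_cohort(SimulationParams(n_early=300, n_late=700, p_early=0.1, p_late=0.1, seed=13))
        t = build_risk_table(records, interval_months=18, horizon_months=90)
        fit = fit_interval_hazards(t, config=fast_mcmc)
        curve = cumulative_incidence(fit, Group.LATE)
        risks = [risk_at_time(curve, m).summary.median for m in (18, 36, 54, 72, 90)]
        assert all(b >= a for a, b in zip(risks, risks[1:]))


class TestKaplanMeierLimit:
    def test_flat_prior_matches_product_limit(self):
        """With a diffuse prior and large cells the posterior median curve
        approaches the classical product-limit estimate on the same table."""
        records, _ = simulate_cohort(
            SimulationParams(n_early=2000, n_late=3000, p_early=0.3, p_late=0.35, seed=17)
        )
        t = build_risk_table(records, interval_months=9, horizon_months=90)
        fit = fit_interval_hazards(t, prior=PriorSpec(-12.0, 100.0), config=McmcConfig(seed=18))
        for g in GROUPS:
            km = 1.0 - np.cumprod(1.0 - t.events[g] / t.n_at_risk[g])
            curve = cumulative_incidence(fit, g)
            assert np.allclose(curve.median, km, rtol=0.02)
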