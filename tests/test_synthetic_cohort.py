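"""Generative regimes: latency laws, race censorship, deliberation, habit."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

import choicelat as cl
from choicelat.synthetic_cohort import DEFAULT_ARCHETYPES
from choicelat.trial_data import validate_sessions


def exponential_params(rate_c=2.0, rate_s=1.0, regime="SCM"):
    return cl.RegimeParams(
        regime,
        cocaine_law=cl.LatencyLaw("exponential", rate=rate_c),
        saccharin_law=cl.LatencyLaw("exponential", rate=rate_s),
    )


class TestLatencyLaw:
    def test_degenerate_log_sd_is_deterministic(self):
        params = cl.RegimeParams(
            "SCM",
            cocaine_law=cl.LatencyLaw("lognormal", math.log(2.0), 0.0),
            saccharin_law=cl.LatencyLaw("lognormal", 0.0, 1.0),
        )
        rng = np.random.default_rng(0)
        draws = {cl.sample_latency(params, "cocaine", rng) for _ in range(20)}
        assert draws == {5.0}  # floor 3 + exp(log 2)

    def test_reaction_time_floor(self):
        rng = np.random.default_rng(1)
        law = cl.LatencyLaw("lognormal", 0.0, 1.2)
        draws = 3.0 + law.sample(rng, 100_000)
        assert draws.min() >= 3.0

    def test_lognormal_mean_matches_closed_form(self):
        rng = np.random.default_rng(2)
        mu, sd, n = 0.5, 0.8, 100_000
        law = cl.LatencyLaw("lognormal", mu, sd)
        draws = 3.0 + law.sample(rng, n)
        expected = 3.0 + math.exp(mu + sd**2 / 2)
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_invalid_laws_rejected(self):
        with pytest.raises(ValueError):
            cl.LatencyLaw("lognormal", 0.0, -1.0).validate()
        with pytest.raises(ValueError):
            cl.LatencyLaw("exponential", rate=0.0).validate()
        with pytest.raises(ValueError):
            cl.LatencyLaw("weibull").validate()


class TestChoiceTrial:
    def test_deterministic_race_always_picks_faster(self):
        params = cl.RegimeParams(
            "SCM",
            cocaine_law=cl.LatencyLaw("lognormal", math.log(2.0), 0.0),
            saccharin_law=cl.LatencyLaw("lognormal", math.log(4.0), 0.0),
        )
        rng = np.random.default_rng(3)
        for _ in range(10):
            rec = cl.simulate_choice_trial(params, rng)
            assert rec.option_chosen == "cocaine"
            assert rec.latency_s == 5.0

    def test_exponential_race_closed_forms(self):
        # min of independent exponentials: P(C wins) = rc/(rc+rs), and the
        # recorded latency is floor + Exp(rc+rs)
        params = exponential_params(rate_c=2.0, rate_s=1.0)
        rng = np.random.default_rng(4)
        n = 40_000
        recs = [cl.simulate_choice_trial(params, rng) for _ in range(n)]
        p_coc = np.mean([r.option_chosen == "cocaine" for r in recs])
        assert abs(p_coc - 2 / 3) < 3 * math.sqrt(2 / 3 * 1 / 3 / n)
        lats = np.array([r.latency_s for r in recs])
        expected_mean = 3.0 + 1 / 3.0
        assert abs(lats.mean() - expected_mean) < 3 * lats.std(ddof=1) / math.sqrt(n)
        # sampling latencies keep the un-raced mean floor + 1/rate
        samp = np.array(
            [cl.sample_latency(params, "saccharin", rng) for _ in range(n)]
        )
        assert abs(samp.mean() - 4.0) < 3 * samp.std(ddof=1) / math.sqrt(n)

    def test_habit_choice_latencies_match_sampling_law(self):
        params = exponential_params(regime="HABIT")
        rng = np.random.default_rng(5)
        n = 8000
        sampling = np.array(
            [cl.sample_latency(params, "cocaine", rng) for _ in range(n)]
        )
        choice = [cl.simulate_choice_trial(params, rng) for _ in range(3 * n)]
        chosen_coc = np.array(
            [r.latency_s for r in choice if r.option_chosen == "cocaine"]
        )
        assert stats.ks_2samp(sampling, chosen_coc).pvalue > 0.01

    def test_dcm_deliberation_lengthens_choice(self):
        params = cl.RegimeParams(
            "DCM",
            cocaine_law=cl.LatencyLaw("lognormal", 0.8, 0.8),
            saccharin_law=cl.LatencyLaw("lognormal", 0.8, 0.8),
            deliberation_law=cl.LatencyLaw("lognormal", 1.0, 0.5),
        )
        rng = np.random.default_rng(6)
        n = 5000
        sampling = np.mean(
            [cl.sample_latency(params, "cocaine", rng) for _ in range(n)]
        )
        choice = np.mean(
            [cl.simulate_choice_trial(params, rng).latency_s for _ in range(n)]
        )
        assert choice > sampling + 1.0

    def test_censorship_gap_grows_with_overlap(self):
        # recorded choice latencies are trimmed versus sampling latencies,
        # and the trimming is stronger when the option laws overlap more
        rng = np.random.default_rng(7)
        n = 30_000

        def cocaine_gap(mu_c, mu_s):
            params = cl.RegimeParams(
                "SCM",
                cocaine_law=cl.LatencyLaw("lognormal", mu_c, 0.8),
                saccharin_law=cl.LatencyLaw("lognormal", mu_s, 0.8),
            )
            sampling = np.mean(
                [cl.sample_latency(params, "cocaine", rng) for _ in range(n)]
            )
            recs = [cl.simulate_choice_trial(params, rng) for _ in range(n)]
            choice = np.mean(
                [r.latency_s for r in recs if r.option_chosen == "cocaine"]
            )
            return sampling - choice

        gap_overlapping = cocaine_gap(0.8, 0.8)  # indifferent-like
        gap_separated = cocaine_gap(0.2, 1.4)  # cocaine-preferring-like
        assert gap_overlapping > 0 and gap_separated > 0
        assert gap_overlapping > gap_separated


class TestSessionAndCohort:
    def test_session_structure(self):
        params = exponential_params()
        rng = np.random.default_rng(8)
        session = cl.simulate_session(params, rng, session_index=2, rat_id="r9")
        assert len(session) == 12
        assert [r.phase for r in session] == ["sampling"] * 4 + ["choice"] * 8
        pattern = tuple(r.option_presented for r in session[:4])
        assert pattern in (
            ("cocaine", "saccharin", "cocaine", "saccharin"),
            ("saccharin", "cocaine", "saccharin", "cocaine"),
        )
        assert all(r.session_index == 2 and r.rat_id == "r9" for r in session)
        validate_sessions(session)

    def test_sampling_trials_ignore_regime(self):
        for regime_a, regime_b in [("SCM", "HABIT"), ("SCM", "DCM")]:
            kwargs = {}
            a = exponential_params(regime=regime_a)
            b = exponential_params(regime=regime_b)
            if regime_b == "DCM":
                b = cl.RegimeParams(
                    "DCM", b.cocaine_law, b.saccharin_law,
                    deliberation_law=cl.LatencyLaw("lognormal", 1.0, 0.5),
                )
            ra, rb = np.random.default_rng(9), np.random.default_rng(9)
            trials_a = [
                cl.simulate_sampling_trial(a, "cocaine", ra) for _ in range(50)
            ]
            trials_b = [
                cl.simulate_sampling_trial(b, "cocaine", rb) for _ in range(50)
            ]
            assert trials_a == trials_b

    def test_cohort_deterministic_under_seed(self, tmp_path):
        config = cl.CohortConfig(
            regime="DCM", n_rats={"SP": 3, "CP": 2}, n_sessions=3, seed=42
        )
        a, b = cl.simulate_cohort(config), cl.simulate_cohort(config)
        assert a == b
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        cl.write_trials(a, pa)
        cl.write_trials(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_empty_cohort(self):
        config = cl.CohortConfig(n_rats={}, n_sessions=3)
        assert cl.simulate_cohort(config) == []

    def test_faster_cocaine_archetype_prefers_cocaine(self):
        config = cl.CohortConfig(
            regime="SCM", n_rats={"CP": 30}, n_sessions=3, seed=10
        )
        summaries = cl.summarize_cohort(cl.simulate_cohort(config))
        assert np.mean([s.preference_pct for s in summaries]) > 50

    def test_cohort_output_passes_validation(self, small_cohort_records):
        validate_sessions(small_cohort_records)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_sessions"):
            cl.CohortConfig(n_sessions=2).validate()
        with pytest.raises(ValueError, match="archetype"):
            cl.CohortConfig(n_rats={"XX": 3}).validate()


class TestRaceProbability:
    def test_symmetry_of_identical_laws(self):
        law = cl.LatencyLaw("exponential", rate=1.5)
        assert cl.scm_choice_probability(law, law, "analytic") == 0.5

    def test_exponential_closed_form(self):
        fast = cl.LatencyLaw("exponential", rate=2.0)
        slow = cl.LatencyLaw("exponential", rate=1.0)
        assert cl.scm_choice_probability(fast, slow, "analytic") == pytest.approx(
            2 / 3
        )

    def test_montecarlo_agrees_with_analytic(self):
        fast = cl.LatencyLaw("exponential", rate=2.0)
        slow = cl.LatencyLaw("exponential", rate=1.0)
        n_mc = 50_000
        mc = cl.scm_choice_probability(
            fast, slow, "montecarlo", n_mc=n_mc, rng=np.random.default_rng(11)
        )
        se = math.sqrt(2 / 3 * 1 / 3 / n_mc)
        assert abs(mc - 2 / 3) < 3 * se

    def test_analytic_unsupported_for_lognormal(self):
        law = cl.LatencyLaw("lognormal", 0.0, 1.0)
        with pytest.raises(ValueError, match="analytic"):
            cl.scm_choice_probability(law, law, "analytic")
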