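"""Markov engine: rate conversion, transition matrices, cohort dynamics.

The reference oracle here re-derives every transition probability straight
from the parameter table with its own scalar arithmetic and steps the cohort
with explicit update equations -- it shares no code with the engine.
"""

import math

import numpy as np
import pytest

from ricesim import (
    GeneratorConfig,
    ScenarioSpec,
    Stratum,
    build_matrix,
    build_trajectory,
    cumulative_outcomes,
    generate,
    rate_to_prob,
    run_cohort,
)


def oracle_trace(params, spec):
    """Naive per-stratum reference: scalar probability formulas + explicit
    state updates, independent of the engine implementation."""
    horizon = spec.horizon_cycles
    eff = params.effects
    results = {}
    for key, row in params.strata.iterrows():
        if spec.ramp == "immediate" or horizon == 1:
            doses = [spec.replacement_fraction * row["white_rice_g"]] * horizon
        else:
            target = spec.replacement_fraction * row["white_rice_g"]
            doses = [target * (c - 1) / (horizon - 1) for c in range(1, horizon + 1)]
        no = row["population"] * (1 - row["prevalence_t2d"])
        t2d = row["population"] * row["prevalence_t2d"]
        dead = 0.0
        occ = [(no, t2d, dead)]
        for dose in doses:
            rr = math.exp(math.log(eff.rr_t2d) * dose / eff.substitution_unit_g)
            p_inc = rr * (1 - math.exp(-row["incidence_t2d"]))
            p_die = 1 - math.exp(-row["mortality_all_cause"])
            p_die_t2d = 1 - math.exp(
                -row["hr_mortality_t2d"] * row["mortality_all_cause"]
            )
            no2 = no * (1 - p_inc - p_die)
            t2d2 = no * p_inc + t2d * (1 - p_die_t2d)
            dead2 = dead + no * p_die + t2d * p_die_t2d
            no, t2d, dead = no2, t2d2, dead2
            occ.append((no, t2d, dead))
        results[key] = np.array(occ)
    return results


class TestRateToProb:
    def test_closed_form_values(self):
        assert rate_to_prob(0.0) == 0.0
        assert rate_to_prob(0.01) == pytest.approx(0.00995016625, abs=1e-11)
        assert rate_to_prob(1000.0) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_and_bounded(self):
        rates = np.linspace(0, 5, 50)
        probs = [rate_to_prob(r) for r in rates]
        assert all(0 <= p < 1 for p in probs)
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_negative_rate_is_domain_error(self):
        with pytest.raises(ValueError):
            rate_to_prob(-0.1)


class TestBuildMatrix:
    def test_rows_sum_to_one_and_structural_zeros(self, japan_params):
        spec = ScenarioSpec("s2", 0.8)
        traj = build_trajectory(spec, japan_params)
        for stratum in japan_params.strata.index:
            m = build_matrix(Stratum(*stratum), 5, japan_params, traj)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert ((m >= 0) & (m <= 1)).all()
            assert m[1, 0] == 0.0  # no remission
            assert (m[2] == [0.0, 0.0, 1.0]).all()  # death absorbing

    def test_base_case_equals_no_substitution(self, japan_params):
        base = build_trajectory(ScenarioSpec("base", 0.0), japan_params)
        s = Stratum("male", "50-59")
        m = build_matrix(s, 3, japan_params, base)
        row = japan_params.strata.loc[s]
        assert m[0, 1] == pytest.approx(1 - math.exp(-row["incidence_t2d"]), rel=1e-14)

    def test_hand_product_incidence_cell(self, japan_params_copy):
        params = japan_params_copy
        params.strata["incidence_t2d"] = 0.01
        params.strata["incidence_low"] = 0.01
        params.strata["incidence_high"] = 0.01
        params.strata["white_rice_g"] = 50.0
        params.strata["white_rice_low"] = 50.0
        params.strata["white_rice_high"] = 50.0
        traj = build_trajectory(ScenarioSpec("x", 1.0, 10, "immediate"), params)
        # dose = 50 g -> rr exactly 0.84; cell is 0.84 x (1 - e^-0.01)
        m = build_matrix(Stratum("male", "40-49"), 1, params, traj)
        assert m[0, 1] == pytest.approx(0.84 * 0.00995016625, abs=1e-11)

    def test_unit_hazard_ratio_equalizes_death_probabilities(self, japan_params_copy):
        params = japan_params_copy
        params.strata["hr_mortality_t2d"] = 1.0
        params.strata["hr_low"] = 1.0
        params.strata["hr_high"] = 1.0
        traj = build_trajectory(ScenarioSpec("base", 0.0), params)
        m = build_matrix(Stratum("female", "60-69"), 1, params, traj)
        assert m[0, 2] == pytest.approx(m[1, 2], rel=1e-14)

    def test_impossible_row_renormalized_with_warning(self, japan_params_copy, caplog):
        params = japan_params_copy
        params.strata["incidence_t2d"] = 50.0
        params.strata["incidence_high"] = 50.0
        params.strata["incidence_low"] = 50.0
        params.strata["mortality_all_cause"] = 50.0
        traj = build_trajectory(ScenarioSpec("base", 0.0), params)
        with caplog.at_level("WARNING"):
            m = build_matrix(Stratum("male", "40-49"), 1, params, traj)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all()
        assert "renormalizing" in caplog.text


class TestRunCohort:
    def test_zero_rates_freeze_the_trace(self, japan_params_copy):
        params = japan_params_copy
        for col in ("incidence_t2d", "incidence_low", "incidence_high",
                    "mortality_all_cause"):
            params.strata[col] = 0.0
        trace = run_cohort(params, ScenarioSpec("base", 0.0))
        for c in range(11):
            assert np.allclose(trace.occupancy[:, c, :], trace.occupancy[:, 0, :])
        out = cumulative_outcomes(trace)
        assert (out[["cum_incidence", "cum_deaths", "pct_incidence", "pct_deaths"]]
                == 0).all().all()

    def test_two_cycle_toy_matches_pencil_arithmetic(self, japan_params_copy):
        """1000 people, prevalence 0.1, per-cycle probabilities 0.1/0.1/0.19."""
        params = japan_params_copy
        params.strata["population"] = 1000.0
        params.strata["prevalence_t2d"] = 0.1
        params.strata["prevalence_low"] = 0.1
        params.strata["prevalence_high"] = 0.1
        # choose rates whose 1-exp(-r) equals the toy probabilities exactly
        params.strata["incidence_t2d"] = -math.log(1 - 0.1)
        params.strata["incidence_low"] = params.strata["incidence_t2d"]
        params.strata["incidence_high"] = params.strata["incidence_t2d"]
        params.strata["mortality_all_cause"] = -math.log(1 - 0.1)
        params.strata["hr_mortality_t2d"] = math.log(1 - 0.19) / math.log(1 - 0.1)
        params.strata["hr_low"] = params.strata["hr_mortality_t2d"]
        params.strata["hr_high"] = params.strata["hr_mortality_t2d"]
        trace = run_cohort(params, ScenarioSpec("base", 0.0, horizon_cycles=2))
        expected = np.array([
            [900.0, 100.0, 0.0],
            [720.0, 171.0, 109.0],
            [576.0, 210.51, 213.49],
        ])
        for i in range(len(trace.strata)):
            assert np.allclose(trace.occupancy[i], expected, atol=1e-9)
        assert np.allclose(trace.incident_t2d[:, 0], 90.0, atol=1e-9)
        assert np.allclose(trace.incident_t2d[:, 1], 72.0, atol=1e-9)
        assert np.allclose(trace.person_time_t2d_hcc[:, 0], 135.5, atol=1e-9)

    def test_conservation_and_monotonicity(self, japan_params):
        for spec in (ScenarioSpec("base", 0.0), ScenarioSpec("s2", 0.8)):
            trace = run_cohort(japan_params, spec)
            totals = trace.occupancy.sum(axis=2)
            pop = japan_params.strata["population"].to_numpy()
            assert np.allclose(totals, pop[:, None], atol=1e-6)
            assert (trace.deaths >= 0).all()
            assert (trace.incident_t2d >= 0).all()
            assert (np.diff(trace.occupancy[:, :, 2], axis=1) >= 0).all()

    def test_neutral_fraction_reproduces_base_case_bitwise(self, japan_params):
        base = run_cohort(japan_params, ScenarioSpec("base", 0.0))
        neutral = run_cohort(japan_params, ScenarioSpec("other", 0.0))
        assert (base.occupancy == neutral.occupancy).all()
        assert (base.incident_t2d == neutral.incident_t2d).all()

    def test_stronger_protection_averts_more_cases(self, japan_params):
        spec = ScenarioSpec("s1", 0.3)
        low_rr = japan_params.with_effects(rr_t2d=0.7, rr_low=0.7)
        cum_low = cumulative_outcomes(run_cohort(low_rr, spec))["cum_incidence"].sum()
        cum_point = cumulative_outcomes(run_cohort(japan_params, spec))[
            "cum_incidence"
        ].sum()
        assert cum_low < cum_point

    @pytest.mark.parametrize("seed", range(20))
    def test_engine_matches_independent_oracle(self, seed):
        params = generate(GeneratorConfig(seed=seed, mode="random_valid"))
        spec = ScenarioSpec("s1", 0.3, 10, "linear")
        trace = run_cohort(params, spec)
        expected = oracle_trace(params, spec)
        for i, key in enumerate(trace.strata):
            ref = expected[key]
            assert np.allclose(trace.occupancy[i], ref, rtol=1e-9, atol=1e-9)

    def test_tidy_export_shape(self, japan_params):
        trace = run_cohort(japan_params, ScenarioSpec("base", 0.0, horizon_cycles=3))
        df = trace.to_frame()
        assert len(df) == 8 * 4 * 3
        assert set(df.columns) >= {
            "sex", "age_band", "cycle", "state", "occupancy",
            "incident_t2d", "deaths", "person_time_hcc",
        }


class TestCumulativeOutcomes:
    def test_percentages_relative_to_initial_population(self, japan_params):
        trace = run_cohort(japan_params, ScenarioSpec("base", 0.0))
        out = cumulative_outcomes(trace)
        pop = japan_params.strata["population"]
        assert np.allclose(
            out["pct_incidence"], 100 * out["cum_incidence"] / pop, rtol=1e-12
        )
        assert np.allclose(out["cum_incidence"], trace.incident_t2d.sum(axis=1))
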