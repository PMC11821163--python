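"""Three-state discrete-time Markov cohort engine.

States are "no T2D", "T2D" and "death" (absorbing).  Each stratum starts
split between no-T2D and T2D by prevalence and is pushed through annual
cycles by a per-cycle transition matrix built from epidemiological rates:

* no_t2d -> t2d:    rr(dose) x (1 - exp(-incidence))
* no_t2d -> death:  1 - exp(-mortality)
* t2d -> death:     1 - exp(-hr x mortality)   (HR applied on the rate scale)

Rates are converted to probabilities with the standard exponential formula,
which keeps probabilities in [0, 1) at any hazard ratio.  T2D person-time is
half-cycle corrected (trapezoid rule: the mean of start- and end-of-cycle
occupancy), which is what the cost module accrues against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet, Stratum
from .scenario import IntakeTrajectory, ScenarioSpec, build_trajectory, rr_at_dose

__all__ = [
    "STATES",
    "CohortTrace",
    "rate_to_prob",
    "build_matrix",
    "run_cohort",
    "cumulative_outcomes",
]

logger = logging.getLogger(__name__)

STATES = ("no_t2d", "t2d", "death")
_NO_T2D, _T2D, _DEATH = 0, 1, 2


def rate_to_prob(rate: float, dt: float = 1.0) -> float:
    """Convert an event rate (per person-year) to a probability over ``dt``.

    Uses 1 - exp(-rate * dt): in [0, 1), monotone in the rate, exact under a
    constant hazard within the interval.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return -np.expm1(-rate * dt)


def build_matrix(
    stratum: Stratum,
    cycle: int,
    params: ParameterSet,
    trajectory: IntakeTrajectory,
) -> np.ndarray:
    """Transition matrix for one stratum and cycle (rows: from, cols: to).

    The substitution RR multiplies the T2D-incidence probability; the T2D
    mortality excess enters as a hazard ratio on the all-cause rate before
    conversion.  If a row's off-diagonal probabilities were to exceed 1
    (unreachable with plausible inputs), they are renormalized proportionally
    and a warning names the stratum and cycle.
    """
    row = params.strata.loc[stratum]
    dose = float(trajectory.substituted_g(cycle).loc[stratum])
    rr = rr_at_dose(dose, params.effects)
    p_inc = rr * rate_to_prob(row["incidence_t2d"])
    p_die = rate_to_prob(row["mortality_all_cause"])
    p_die_t2d = rate_to_prob(row["hr_mortality_t2d"] * row["mortality_all_cause"])

    off = p_inc + p_die
    if off > 1.0:
        logger.warning(
            "off-diagonal transition probabilities sum to %.6f > 1 for "
            "stratum '%s %s', cycle %d; renormalizing proportionally",
            off, stratum[0], stratum[1], cycle,
        )
        p_inc, p_die = p_inc / off, p_die / off

    m = np.array([
        [1.0 - p_inc - p_die, p_inc, p_die],
        [0.0, 1.0 - p_die_t2d, p_die_t2d],
        [0.0, 0.0, 1.0],
    ])
    return m


@dataclass
class CohortTrace:
    """Per-stratum, per-cycle record of one cohort run.

    occupancy has shape (strata, horizon + 1, 3) with cycle 0 the initial
    split; incident_t2d, deaths and person_time_t2d_hcc have shape
    (strata, horizon) and are indexed by cycle 1..H.
    """

    strata: pd.MultiIndex
    occupancy: np.ndarray
    incident_t2d: np.ndarray
    deaths: np.ndarray
    person_time_t2d_hcc: np.ndarray
    spec: ScenarioSpec

    @property
    def horizon(self) -> int:
        return self.incident_t2d.shape[1]

    @property
    def initial_population(self) -> pd.Series:
        return pd.Series(self.occupancy[:, 0, :].sum(axis=1), index=self.strata)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export: one row per stratum x cycle x state."""
        rows = []
        for i, (sex, band) in enumerate(self.strata):
            for c in range(self.horizon + 1):
                for s, state in enumerate(STATES):
                    rows.append({
                        "sex": sex,
                        "age_band": band,
                        "cycle": c,
                        "state": state,
                        "occupancy": self.occupancy[i, c, s],
                        "incident_t2d": (
                            self.incident_t2d[i, c - 1] if (c > 0 and s == _T2D) else 0.0
                        ),
                        "deaths": (
                            self.deaths[i, c - 1] if (c > 0 and s == _DEATH) else 0.0
                        ),
                        "person_time_hcc": (
                            self.person_time_t2d_hcc[i, c - 1]
                            if (c > 0 and s == _T2D) else 0.0
                        ),
                    })
        return pd.DataFrame(rows)


def run_cohort(
    params: ParameterSet,
    spec: ScenarioSpec,
    trajectory: IntakeTrajectory | None = None,
) -> CohortTrace:
    """Run the cohort simulation for every stratum under one scenario.

    Cycle 0 splits each stratum's population between no-T2D and T2D by
    prevalence; each subsequent cycle applies that cycle's transition matrix.
    Incident T2D is counted from start-of-cycle no-T2D occupancy, so cases
    are registered before same-cycle mortality.  Occupancy is conserved to
    floating-point precision at every cycle.
    """
    if trajectory is None:
        trajectory = build_trajectory(spec, params)
    strata = params.strata.index
    n_strata = len(strata)
    horizon = spec.horizon_cycles

    occupancy = np.zeros((n_strata, horizon + 1, 3))
    incident = np.zeros((n_strata, horizon))
    deaths = np.zeros((n_strata, horizon))
    pt_hcc = np.zeros((n_strata, horizon))

    pop = params.strata["population"].to_numpy()
    prev = params.strata["prevalence_t2d"].to_numpy()
    occupancy[:, 0, _NO_T2D] = (1.0 - prev) * pop
    occupancy[:, 0, _T2D] = prev * pop

    for i, stratum in enumerate(strata):
        for cycle in range(1, horizon + 1):
            m = build_matrix(Stratum(*stratum), cycle, params, trajectory)
            state = occupancy[i, cycle - 1]
            occupancy[i, cycle] = state @ m
            incident[i, cycle - 1] = state[_NO_T2D] * m[_NO_T2D, _T2D]
            deaths[i, cycle - 1] = (
                occupancy[i, cycle, _DEATH] - state[_DEATH]
            )
            pt_hcc[i, cycle - 1] = 0.5 * (
                state[_T2D] + occupancy[i, cycle, _T2D]
            )

    return CohortTrace(
        strata=strata,
        occupancy=occupancy,
        incident_t2d=incident,
        deaths=deaths,
        person_time_t2d_hcc=pt_hcc,
        spec=spec,
    )


def cumulative_outcomes(trace: CohortTrace) -> pd.DataFrame:
    """Cumulative incident T2D cases and deaths per stratum over the horizon.

    Percentages are relative to the initial stratum population and left
    unrounded; the reporting layer rounds to one decimal for display.
    """
    pop = trace.initial_population
    cum_inc = pd.Series(trace.incident_t2d.sum(axis=1), index=trace.strata)
    cum_dth = pd.Series(trace.deaths.sum(axis=1), index=trace.strata)
    return pd.DataFrame({
        "population": pop,
        "cum_incidence": cum_inc,
        "cum_deaths": cum_dth,
        "pct_incidence": 100.0 * cum_inc / pop,
        "pct_deaths": 100.0 * cum_dth / pop,
    })
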