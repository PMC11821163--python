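"""Substitution scenarios: intake trajectories and the dose-response RR.

A scenario replaces a fraction of each stratum's mean white-rice intake with
brown rice over the simulation horizon.  The base case keeps brown rice at its
(numerically floored) 1 g/day baseline.  Substituted grams are converted to a
cycle-specific relative risk of incident T2D via a log-linear dose-response:
the published RR (0.84) applies per 50 g/day replaced, and doses compose
multiplicatively, so rr(a + b) = rr(a) * rr(b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import EffectParams, ParameterSet

__all__ = [
    "ScenarioSpec",
    "IntakeTrajectory",
    "BASE_CASE",
    "SCENARIO_1",
    "SCENARIO_2",
    "resolve_scenario",
    "build_trajectory",
    "rr_at_dose",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One substitution scenario.

    replacement_fraction: share of mean white-rice intake replaced by the end
    of the horizon (0 = base case, 0.30 = Scenario 1, 0.80 = Scenario 2).
    ramp: "linear" phases the attained intake in from baseline at cycle 1 to
    the target at the final cycle; "immediate" applies the full target from
    cycle 1 on.
    """

    name: str
    replacement_fraction: float
    horizon_cycles: int = 10
    ramp: str = "linear"

    def __post_init__(self) -> None:
        if not (0.0 <= self.replacement_fraction <= 1.0):
            raise ValueError(
                f"replacement_fraction must be in [0, 1], got "
                f"{self.replacement_fraction}"
            )
        if self.horizon_cycles < 1:
            raise ValueError(f"horizon_cycles must be >= 1, got {self.horizon_cycles}")
        if self.ramp not in ("linear", "immediate"):
            raise ValueError(f"ramp must be 'linear' or 'immediate', got {self.ramp!r}")


BASE_CASE = ScenarioSpec("base", 0.0)
SCENARIO_1 = ScenarioSpec("s1", 0.30)
SCENARIO_2 = ScenarioSpec("s2", 0.80)

_ALIASES = {
    "base": BASE_CASE,
    "s1": SCENARIO_1, "s30": SCENARIO_1, "scenario1": SCENARIO_1,
    "s2": SCENARIO_2, "s80": SCENARIO_2, "scenario2": SCENARIO_2,
}


def resolve_scenario(
    name: str | ScenarioSpec,
    horizon_cycles: int = 10,
    ramp: str = "linear",
    fraction: float | None = None,
) -> ScenarioSpec:
    """Map a scenario alias ('base', 's1', 's2', 'custom') to a spec."""
    if isinstance(name, ScenarioSpec):
        return name
    key = name.lower()
    if key == "custom":
        if fraction is None:
            raise ValueError("scenario 'custom' requires an explicit fraction")
        return ScenarioSpec("custom", fraction, horizon_cycles, ramp)
    if key not in _ALIASES:
        raise ValueError(
            f"unknown scenario {name!r}; choose from "
            f"{sorted(set(_ALIASES))} or 'custom'"
        )
    base = _ALIASES[key]
    return ScenarioSpec(base.name, base.replacement_fraction, horizon_cycles, ramp)


@dataclass
class IntakeTrajectory:
    """Attained brown-rice intake per stratum and cycle (grams/day, dry).

    ``brown_rice_g`` has the 8 strata as rows and cycles 1..H as columns;
    ``baseline_g`` is the per-stratum starting intake.  The substituted dose
    at a cycle is attained minus baseline.
    """

    brown_rice_g: pd.DataFrame
    baseline_g: pd.Series
    spec: ScenarioSpec

    def substituted_g(self, cycle: int) -> pd.Series:
        """Grams/day of white rice replaced during the given cycle (1-based)."""
        return self.brown_rice_g[cycle] - self.baseline_g


def build_trajectory(spec: ScenarioSpec, params: ParameterSet) -> IntakeTrajectory:
    """Per-cycle attained brown-rice intake for every stratum under a scenario.

    The linear ramp starts at the baseline in cycle 1 and reaches
    baseline + fraction x white_rice in the final cycle (a one-cycle horizon
    jumps straight to the target); the immediate ramp holds the target from
    cycle 1.  The trajectory is non-decreasing and, for fraction 0, constant
    at the baseline.
    """
    baseline = params.strata["brown_rice_baseline_g"]
    target_add = spec.replacement_fraction * params.strata["white_rice_g"]
    cycles = np.arange(1, spec.horizon_cycles + 1)
    if spec.ramp == "immediate" or spec.horizon_cycles == 1:
        weights = np.ones_like(cycles, dtype=float)
    else:
        weights = (cycles - 1) / (spec.horizon_cycles - 1)
    values = baseline.to_numpy()[:, None] + np.outer(target_add.to_numpy(), weights)
    traj = pd.DataFrame(values, index=params.strata.index, columns=cycles)
    return IntakeTrajectory(brown_rice_g=traj, baseline_g=baseline, spec=spec)


def rr_at_dose(substituted_g, effect: EffectParams):
    """Relative risk of incident T2D at a given substituted dose.

    Log-linear in grams: exp(ln(rr) * dose / unit).  0 g gives exactly 1;
    one unit (50 g/day by default) gives exactly ``rr_t2d``; doses compose
    multiplicatively.  Accepts scalars or arrays; negative doses are a
    domain error.
    """
    dose = np.asarray(substituted_g, dtype=float)
    if (dose < 0).any():
        raise ValueError("substituted dose must be >= 0 g/day")
    out = np.exp(np.log(effect.rr_t2d) * dose / effect.substitution_unit_g)
    if np.isscalar(substituted_g):
        return float(out)
    return out
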