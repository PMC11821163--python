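"""Deterministic one-way sensitivity analysis (tornado) on projected savings.

Each analysed parameter is set in turn to a low and a high value with every
other input held at its point estimate; the full pipeline (base case plus
scenario, costs, discounting) is rerun for each bound and the pair of
projected savings recorded.  Results are sorted by descending span, the
order a tornado diagram plots them in.

Stratified parameters (white-rice intake, T2D incidence and prevalence) are
perturbed by moving *all* strata to their respective confidence-interval
bounds simultaneously; scalar parameters (substitution RR, discount rate)
take explicit low/high values.  Prevalence perturbation changes the initial
state split and, through it, the per-case cost denominator — its only roles
in the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .economics import accrue_costs
from .engine import run_cohort
from .parameters import ParameterSet
from .scenario import ScenarioSpec

__all__ = ["DSAResult", "default_plan", "one_way_dsa", "scenario_savings"]

#: Parameters the DSA knows how to perturb.  "ci" bounds read the stored
#: per-stratum confidence-interval columns; scalars need explicit numbers.
_STRATIFIED = {
    "white_rice_g": ("white_rice_low", "white_rice_high"),
    "incidence_t2d": ("incidence_low", "incidence_high"),
    "prevalence_t2d": ("prevalence_low", "prevalence_high"),
    "hr_mortality_t2d": ("hr_low", "hr_high"),
}
_SCALAR = ("rr_t2d", "discount_rate")
VALID_PARAMETERS = tuple(_STRATIFIED) + _SCALAR


@dataclass(frozen=True)
class DSAResult:
    """Tornado row: the savings reached at a parameter's low and high bound."""

    parameter: str
    low_input: object
    high_input: object
    outcome_low: float
    outcome_high: float

    @property
    def span(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def scenario_savings(
    params: ParameterSet, spec: ScenarioSpec, sex: str | None = None
) -> float:
    """Total discounted savings (USD) of a scenario vs the base case."""
    base_spec = ScenarioSpec("base", 0.0, spec.horizon_cycles, spec.ramp)
    base = accrue_costs(run_cohort(params, base_spec), params)
    scen = accrue_costs(run_cohort(params, spec), params)
    diff = base.discounted_cost_usd - scen.discounted_cost_usd
    if sex is not None:
        diff = diff.xs(sex, level="sex")
    return float(diff.sum())


def _perturbed(params: ParameterSet, name: str, bound) -> ParameterSet:
    """A copy of ``params`` with one parameter moved to a bound.

    ``bound`` is "ci_low"/"ci_high" for stratified parameters (or "point" for
    the degenerate no-op) and a number for scalar ones.
    """
    if name in _STRATIFIED:
        out = params.copy()
        if bound == "point":
            return out
        low_col, high_col = _STRATIFIED[name]
        col = {"ci_low": low_col, "ci_high": high_col}.get(bound)
        if col is None:
            raise ValueError(
                f"stratified parameter {name!r} takes bounds 'ci_low', "
                f"'ci_high' or 'point', got {bound!r}"
            )
        out.strata[name] = out.strata[col]
        return out
    if name == "rr_t2d":
        rr = float(bound)
        return params.with_effects(
            rr_t2d=rr, rr_low=min(rr, params.effects.rr_low),
            rr_high=max(rr, params.effects.rr_high),
        )
    if name == "discount_rate":
        return params.with_econ(discount_rate=float(bound))
    raise ValueError(
        f"unknown DSA parameter {name!r}; valid names: {sorted(VALID_PARAMETERS)}"
    )


def default_plan(params: ParameterSet) -> list[tuple[str, object, object]]:
    """The canonical analysis plan: discount rate swept 0-4%, substitution RR
    over its 95% CI, and intake/incidence/prevalence over their per-stratum
    CI bounds."""
    return [
        ("rr_t2d", params.effects.rr_low, params.effects.rr_high),
        ("incidence_t2d", "ci_low", "ci_high"),
        ("prevalence_t2d", "ci_low", "ci_high"),
        ("white_rice_g", "ci_low", "ci_high"),
        ("discount_rate", 0.0, 0.04),
    ]


def one_way_dsa(
    params: ParameterSet,
    spec: ScenarioSpec,
    plan: list[tuple[str, object, object]] | None = None,
    sex: str | None = None,
) -> list[DSAResult]:
    """Run a one-way DSA over ``plan`` and return tornado-ordered results.

    For each (parameter, low, high) entry the pipeline is rerun twice with
    that parameter alone at its bound.  ``sex`` restricts the savings outcome
    to one sex's strata (the whole model still runs).  Results come back
    sorted by descending span.
    """
    if plan is None:
        plan = default_plan(params)
    results = []
    for name, low, high in plan:
        lo_sav = scenario_savings(_perturbed(params, name, low), spec, sex=sex)
        hi_sav = scenario_savings(_perturbed(params, name, high), spec, sex=sex)
        results.append(DSAResult(name, low, high, lo_sav, hi_sav))
    return sorted(results, key=lambda r: r.span, reverse=True)


def dsa_frame(results: list[DSAResult]) -> pd.DataFrame:
    """Tabular DSA export (one tornado row per parameter)."""
    return pd.DataFrame([
        {
            "parameter": r.parameter,
            "low_input": r.low_input,
            "high_input": r.high_input,
            "savings_at_low_usd": r.outcome_low,
            "savings_at_high_usd": r.outcome_high,
            "span_usd": r.span,
        }
        for r in results
    ])
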