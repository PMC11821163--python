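"""Healthcare costs: discounting, currency conversion and cost accrual.

Annual national T2D expenditures are assigned to the T2D state as a per
prevalent-case rate (see ``ParameterSet.annual_cost_per_case_jpy``).  A run's
cost is the half-cycle-corrected T2D person-time in each cycle times that
rate, discounted back to the start of the simulation, converted to USD at
the fixed 2019 average exchange rate (JPY 109.01 per USD by default).
Savings of a substitution scenario are the base-case cost minus the scenario
cost, per stratum and overall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CohortTrace
from .parameters import ParameterSet

__all__ = ["CostResult", "discount_factor", "jpy_to_usd", "accrue_costs", "savings"]


def discount_factor(rate: float, cycle: float) -> float:
    """Present-value factor (1 + rate)^(-cycle); 1 at cycle 0."""
    if cycle < 0:
        raise ValueError(f"cycle must be >= 0, got {cycle}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return float((1.0 + rate) ** (-cycle))


def jpy_to_usd(amount_jpy: float, exchange_rate_jpy_per_usd: float = 109.01) -> float:
    """Convert JPY to USD at a fixed annual-average exchange rate."""
    if exchange_rate_jpy_per_usd <= 0:
        raise ValueError("exchange rate must be > 0")
    return amount_jpy / exchange_rate_jpy_per_usd


@dataclass
class CostResult:
    """Discounted cumulative T2D healthcare cost of one run, in USD.

    ``discounted_cost_usd`` is indexed by stratum; ``total_usd`` sums it.
    """

    discounted_cost_usd: pd.Series
    scenario_name: str
    discount_rate: float
    discount_timing: str

    @property
    def total_usd(self) -> float:
        return float(self.discounted_cost_usd.sum())


def accrue_costs(trace: CohortTrace, params: ParameterSet) -> CostResult:
    """Discounted cumulative cost per stratum for one cohort trace.

    Cost in cycle c is person_time_t2d_hcc(c) x annual per-case cost,
    discounted by (1 + r)^(-c) under the default end-of-cycle timing (or
    (1 + r)^(-(c - 1/2)) under midpoint timing), then converted to USD.
    """
    if not trace.strata.equals(params.strata.index):
        raise ValueError("trace and parameter strata do not match")
    per_case = params.annual_cost_per_case_jpy().to_numpy()
    cycles = np.arange(1, trace.horizon + 1, dtype=float)
    if params.econ.discount_timing == "midpoint":
        cycles = cycles - 0.5
    dfac = (1.0 + params.econ.discount_rate) ** (-cycles)
    cost_jpy = (trace.person_time_t2d_hcc * per_case[:, None] * dfac[None, :]).sum(axis=1)
    cost_usd = cost_jpy / params.econ.exchange_rate_jpy_per_usd
    return CostResult(
        discounted_cost_usd=pd.Series(cost_usd, index=trace.strata),
        scenario_name=trace.spec.name,
        discount_rate=params.econ.discount_rate,
        discount_timing=params.econ.discount_timing,
    )


def savings(base: CostResult, scenario: CostResult) -> pd.DataFrame:
    """Per-stratum savings of a scenario vs the base case (USD and %)."""
    diff = base.discounted_cost_usd - scenario.discounted_cost_usd
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * diff / base.discounted_cost_usd
    return pd.DataFrame({
        "base_cost_usd": base.discounted_cost_usd,
        "scenario_cost_usd": scenario.discounted_cost_usd,
        "savings_usd": diff,
        "savings_pct": pct.fillna(0.0),
    })
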