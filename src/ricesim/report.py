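"""Orchestration and table-shaped reporting.

``run_analysis`` runs the base case and each requested substitution scenario
through the full pipeline and assembles three tables mirroring the published
layout: base-case outcomes (population, cumulative T2D incidence and deaths,
discounted expenditures), outcomes averted per scenario, and discounted
savings per scenario.  Each table carries the 8 age-band rows plus 40-79
sex-subtotal rows and a cohort-total row, aggregated from unrounded values;
percentages are rounded to one decimal only at format time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .economics import accrue_costs, savings
from .engine import cumulative_outcomes, run_cohort
from .parameters import ParameterSet, load_parameters
from .scenario import ScenarioSpec, resolve_scenario
from .sensitivity import dsa_frame, one_way_dsa

__all__ = ["RunReport", "run_analysis"]

logger = logging.getLogger(__name__)


def _with_totals(df: pd.DataFrame, count_cols: list[str], pct_of: dict[str, str]) -> pd.DataFrame:
    """Append 40-79 sex subtotals and a cohort-total row; recompute percentages.

    ``pct_of`` maps a percentage column to the count column it is derived
    from; percentages are recomputed from unrounded sums against the
    population column.
    """
    df = df.reset_index()
    rows = [df.assign(row_kind="age")]
    for sex in ("male", "female"):
        sub = df[df["sex"] == sex][count_cols].sum()
        rows.append(pd.DataFrame([{
            "sex": sex, "age_band": "40-79", "row_kind": "sex_total", **sub,
        }]))
    total = df[count_cols].sum()
    rows.append(pd.DataFrame([{
        "sex": "all", "age_band": "40-79", "row_kind": "cohort_total", **total,
    }]))
    out = pd.concat(rows, ignore_index=True)
    for pct_col, num_col in pct_of.items():
        out[pct_col] = 100.0 * out[num_col] / out["population"]
    order = {"male": 0, "female": 1, "all": 2}
    out = out.sort_values(
        ["sex", "row_kind", "age_band"],
        key=lambda s: s.map(order) if s.name == "sex" else s,
    ).reset_index(drop=True)
    return out


@dataclass
class RunReport:
    """Everything one analysis run produced, plus audit metadata."""

    base_case: pd.DataFrame
    averted: dict[str, pd.DataFrame]
    savings: dict[str, pd.DataFrame]
    dsa: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def to_dir(self, outdir: str | Path) -> None:
        """Write CSV tables plus a JSON metadata report to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.base_case.to_csv(outdir / "base_case.csv", index=False)
        for name, df in self.averted.items():
            df.to_csv(outdir / f"averted_{name}.csv", index=False)
        for name, df in self.savings.items():
            df.to_csv(outdir / f"savings_{name}.csv", index=False)
        for name, df in self.dsa.items():
            df.to_csv(outdir / f"dsa_{name}.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(self.summary(), indent=2))

    def summary(self) -> dict:
        """Cohort-level headline numbers (unrounded counts, 1-dp percentages)."""
        tot = self.base_case[self.base_case["row_kind"] == "cohort_total"].iloc[0]
        out = {
            "metadata": self.metadata,
            "base_case": {
                "population": float(tot["population"]),
                "cum_incidence": float(tot["cum_incidence"]),
                "cum_incidence_pct": round(float(tot["pct_incidence"]), 1),
                "cum_deaths": float(tot["cum_deaths"]),
                "cum_deaths_pct": round(float(tot["pct_deaths"]), 1),
                "discounted_cost_usd": float(tot["discounted_cost_usd"]),
            },
            "scenarios": {},
        }
        for name, av in self.averted.items():
            row = av[av["row_kind"] == "cohort_total"].iloc[0]
            sv = self.savings[name]
            svrow = sv[sv["row_kind"] == "cohort_total"].iloc[0]
            out["scenarios"][name] = {
                "averted_cases": float(row["averted_cases"]),
                "averted_cases_pct": round(float(row["averted_cases_pct"]), 1),
                "averted_deaths": float(row["averted_deaths"]),
                "averted_deaths_pct": round(float(row["averted_deaths_pct"]), 2),
                "savings_usd": float(svrow["savings_usd"]),
                "savings_pct": round(float(svrow["savings_pct"]), 1),
            }
        return out


def run_analysis(
    config: str | Path | ParameterSet,
    scenarios: list[str | ScenarioSpec] = ("base", "s1", "s2"),
    horizon_cycles: int = 10,
    ramp: str = "linear",
    dsa: bool = False,
    seed: int | None = None,
) -> RunReport:
    """Run base case plus scenarios and assemble published-layout tables.

    ``config`` is a YAML path or an in-memory parameter set.  The report is
    deterministic given the config (no randomness in the pipeline itself;
    ``seed`` is recorded in metadata for provenance of generated configs).
    """
    params = (
        config if isinstance(config, ParameterSet) else load_parameters(config)
    )
    specs = [resolve_scenario(s, horizon_cycles, ramp) for s in scenarios]
    base_spec = resolve_scenario("base", horizon_cycles, ramp)

    logger.info(
        "run_analysis: horizon=%d ramp=%s discount=%s timing=%s hr_scale=rate",
        horizon_cycles, ramp, params.econ.discount_rate, params.econ.discount_timing,
    )

    base_trace = run_cohort(params, base_spec)
    base_out = cumulative_outcomes(base_trace)
    base_cost = accrue_costs(base_trace, params)

    base_table = base_out.copy()
    base_table["discounted_cost_usd"] = base_cost.discounted_cost_usd
    base_table = _with_totals(
        base_table,
        ["population", "cum_incidence", "cum_deaths", "discounted_cost_usd"],
        {"pct_incidence": "cum_incidence", "pct_deaths": "cum_deaths"},
    )

    averted_tables: dict[str, pd.DataFrame] = {}
    savings_tables: dict[str, pd.DataFrame] = {}
    dsa_tables: dict[str, pd.DataFrame] = {}
    for spec in specs:
        if spec.replacement_fraction == 0.0:
            continue
        trace = run_cohort(params, spec)
        out = cumulative_outcomes(trace)
        cost = accrue_costs(trace, params)

        av = pd.DataFrame({
            "population": base_out["population"],
            "averted_cases": base_out["cum_incidence"] - out["cum_incidence"],
            "averted_deaths": base_out["cum_deaths"] - out["cum_deaths"],
            "base_cases": base_out["cum_incidence"],
            "base_deaths": base_out["cum_deaths"],
        })
        av = _with_totals(
            av,
            ["population", "averted_cases", "averted_deaths", "base_cases", "base_deaths"],
            {},
        )
        # percentages are relative to base-case outcome counts, not population
        av["averted_cases_pct"] = 100.0 * av["averted_cases"] / av["base_cases"]
        av["averted_deaths_pct"] = 100.0 * av["averted_deaths"] / av["base_deaths"]
        averted_tables[spec.name] = av

        sv = savings(base_cost, cost)
        sv["population"] = base_out["population"]
        sv = _with_totals(
            sv,
            ["population", "base_cost_usd", "scenario_cost_usd", "savings_usd"],
            {},
        )
        sv["savings_pct"] = 100.0 * sv["savings_usd"] / sv["base_cost_usd"]
        savings_tables[spec.name] = sv

        if dsa:
            rows = {"all": dsa_frame(one_way_dsa(params, spec))}
            for sex in ("male", "female"):
                rows[sex] = dsa_frame(one_way_dsa(params, spec, sex=sex))
            dsa_tables[spec.name] = pd.concat(
                [df.assign(group=g) for g, df in rows.items()], ignore_index=True
            )

    metadata = {
        "config_hash": params.config_hash(),
        "seed": seed,
        "horizon_cycles": horizon_cycles,
        "conventions": {
            "ramp": ramp,
            "discount_timing": params.econ.discount_timing,
            "hr_scale": "rate",
            "rate_to_prob": "1-exp(-r)",
        },
        "discount_rate": params.econ.discount_rate,
        "exchange_rate_jpy_per_usd": params.econ.exchange_rate_jpy_per_usd,
    }
    return RunReport(
        base_case=base_table,
        averted=averted_tables,
        savings=savings_tables,
        dsa=dsa_tables,
        metadata=metadata,
    )
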