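"""Synthetic parameter sets and packaged reference tables.

The original model inputs (GBD-style rates, survey-based rice intake,
national expenditure accounts) are not redistributable, so this module
generates complete, validated :class:`~ricesim.parameters.ParameterSet`
objects that emulate their statistical structure:

* ``japan_like`` — stratum populations are the published 2019 census counts
  verbatim; rates, intake and costs are drawn around realistic Japanese
  midpoints (incidence and mortality rising with age, male mortality above
  female, dry-equivalent rice intake in the 100-350 g/day range) with
  seeded lognormal noise.  The calibration targets a 10-year cumulative T2D
  incidence of 3-9% per stratum.
* ``random_valid`` — everything drawn uniformly from the schema's valid
  ranges; useful for property tests and engine-vs-oracle sweeps.

The module also ships transcriptions of the published projection tables
(base-case outcomes, averted outcomes, savings) with checksums, used by the
aggregation tests and the acceptance script.  They are model *outputs* kept
as reference points, never inputs to the simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .parameters import AGE_BANDS, SEXES, ParameterSet, parameters_from_dict

__all__ = ["GeneratorConfig", "FixtureTables", "generate", "load_fixtures"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded generator settings; the same config always yields the same set."""

    seed: int
    mode: str = "japan_like"
    noise_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("japan_like", "random_valid"):
            raise ValueError(
                f"mode must be 'japan_like' or 'random_valid', got {self.mode!r}"
            )
        if not (0.0 <= self.noise_scale < 1.0):
            raise ValueError(f"noise_scale must be in [0, 1), got {self.noise_scale}")


# 2019 census population counts for the eight strata (published verbatim).
_POPULATION = {
    ("male", "40-49"): 9_373_569,
    ("male", "50-59"): 8_160_860,
    ("male", "60-69"): 7_929_684,
    ("male", "70-79"): 7_333_357,
    ("female", "40-49"): 9_146_186,
    ("female", "50-59"): 8_116_993,
    ("female", "60-69"): 8_301_898,
    ("female", "70-79"): 8_593_569,
}

# japan_like midpoints by (sex, age band).  Annual rates per person-year;
# intake in dry-equivalent g/day; per-case cost in JPY/person-year.  Chosen
# so the base-case 10-year cumulative T2D incidence lands in 3-9% per
# stratum and cost totals sit at the scale implied by the published
# expenditure projections.
_MID_INCIDENCE = {
    "male": {"40-49": 0.0050, "50-59": 0.0095, "60-69": 0.0110, "70-79": 0.0055},
    "female": {"40-49": 0.0032, "50-59": 0.0072, "60-69": 0.0090, "70-79": 0.0048},
}
_MID_PREVALENCE = {
    "male": {"40-49": 0.06, "50-59": 0.10, "60-69": 0.15, "70-79": 0.18},
    "female": {"40-49": 0.03, "50-59": 0.06, "60-69": 0.09, "70-79": 0.12},
}
_MID_MORTALITY = {
    "male": {"40-49": 0.0016, "50-59": 0.0045, "60-69": 0.0129, "70-79": 0.0297},
    "female": {"40-49": 0.0009, "50-59": 0.0022, "60-69": 0.0052, "70-79": 0.0128},
}
_MID_WHITE_RICE = {
    "male": {"40-49": 210.0, "50-59": 220.0, "60-69": 215.0, "70-79": 195.0},
    "female": {"40-49": 150.0, "50-59": 160.0, "60-69": 165.0, "70-79": 155.0},
}
_MID_COST_PER_CASE = {
    "male": {"40-49": 10_000.0, "50-59": 18_000.0, "60-69": 30_000.0, "70-79": 45_000.0},
    "female": {"40-49": 7_000.0, "50-59": 12_000.0, "60-69": 22_000.0, "70-79": 33_000.0},
}

# Relative 95% CI half-widths used in japan_like mode: incidence and
# prevalence mirror typical burden-of-disease uncertainty intervals, intake
# the sampling precision of a national dietary survey.
_CI_HALF_WIDTH = {"incidence": 0.20, "prevalence": 0.10, "white_rice": 0.07}

_HR_MORTALITY = (1.7, 1.5, 1.9)  # point, low, high


def _japan_like(rng: np.random.Generator, noise_scale: float) -> dict:
    def jitter() -> float:
        return float(np.exp(rng.normal(0.0, noise_scale))) if noise_scale else 1.0

    cfg: dict = {
        "population": {},
        "epidemiology": {},
        "diet": {},
        "effects": {"rr_t2d": 0.84, "rr_ci": [0.79, 0.91], "substitution_unit_g": 50.0},
        "costs": {
            "exchange_rate_jpy_per_usd": 109.01,
            "discount_rate": 0.02,
            "national_t2d_expenditure_jpy": {},
        },
    }
    for sex in SEXES:
        for band in AGE_BANDS:
            key = f"{sex} {band}"
            pop = _POPULATION[(sex, band)]
            inc = _MID_INCIDENCE[sex][band] * jitter()
            prev = min(_MID_PREVALENCE[sex][band] * jitter(), 0.9)
            mort = _MID_MORTALITY[sex][band] * jitter()
            wr = _MID_WHITE_RICE[sex][band] * jitter()
            w_inc = _CI_HALF_WIDTH["incidence"]
            w_prev = _CI_HALF_WIDTH["prevalence"]
            w_wr = _CI_HALF_WIDTH["white_rice"]
            cfg["population"][key] = pop
            cfg["epidemiology"][key] = {
                "prevalence_t2d": prev,
                "prevalence_ci": [prev * (1 - w_prev), min(prev * (1 + w_prev), 1.0)],
                "incidence_t2d": inc,
                "incidence_ci": [inc * (1 - w_inc), inc * (1 + w_inc)],
                "mortality_all_cause": mort,
                "hr_mortality_t2d": _HR_MORTALITY[0],
                "hr_ci": [_HR_MORTALITY[1], _HR_MORTALITY[2]],
            }
            cfg["diet"][key] = {
                "white_rice_g": wr,
                "white_rice_ci": [wr * (1 - w_wr), wr * (1 + w_wr)],
                "brown_rice_baseline_g": 1.0,
            }
            cfg["costs"]["national_t2d_expenditure_jpy"][key] = (
                prev * pop * _MID_COST_PER_CASE[sex][band] * jitter()
            )
    return cfg


def _random_valid(rng: np.random.Generator) -> dict:
    cfg: dict = {
        "population": {},
        "epidemiology": {},
        "diet": {},
        "effects": {},
        "costs": {
            "exchange_rate_jpy_per_usd": 109.01,
            "discount_rate": float(rng.uniform(0.0, 0.04)),
            "national_t2d_expenditure_jpy": {},
        },
    }
    rr = float(rng.uniform(0.5, 0.99))
    cfg["effects"] = {
        "rr_t2d": rr,
        "rr_ci": [rr * float(rng.uniform(0.85, 1.0)), rr * float(rng.uniform(1.0, 1.1))],
        "substitution_unit_g": 50.0,
    }
    for sex in SEXES:
        for band in AGE_BANDS:
            key = f"{sex} {band}"
            prev = float(rng.uniform(0.01, 0.30))
            inc = float(rng.uniform(0.001, 0.03))
            mort = float(rng.uniform(0.0005, 0.05))
            hr = float(rng.uniform(1.0, 3.0))
            wr = float(rng.uniform(100.0, 350.0))
            cfg["population"][key] = float(rng.uniform(1e5, 1e7))
            cfg["epidemiology"][key] = {
                "prevalence_t2d": prev,
                "prevalence_ci": [prev * 0.9, min(prev * 1.1, 1.0)],
                "incidence_t2d": inc,
                "incidence_ci": [inc * 0.8, inc * 1.2],
                "mortality_all_cause": mort,
                "hr_mortality_t2d": hr,
                "hr_ci": [hr * 0.9, hr * 1.1],
            }
            cfg["diet"][key] = {
                "white_rice_g": wr,
                "white_rice_ci": [wr * 0.93, wr * 1.07],
                "brown_rice_baseline_g": 1.0,
            }
            cfg["costs"]["national_t2d_expenditure_jpy"][key] = float(
                rng.uniform(1e9, 5e11)
            )
    return cfg


def generate(config: GeneratorConfig) -> ParameterSet:
    """Generate a validated parameter set; deterministic under a fixed config."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "japan_like":
        cfg = _japan_like(rng, config.noise_scale)
    else:
        cfg = _random_valid(rng)
    return parameters_from_dict(cfg)


# ---------------------------------------------------------------------------
# Packaged reference tables


@dataclass
class FixtureTables:
    """Published projection tables plus their provenance manifest.

    ``base_case`` — 10-year base-case population, T2D incidence, deaths and
    discounted expenditures per stratum; ``averted`` — cases and deaths
    prevented under the two substitution scenarios; ``savings`` — discounted
    expenditure savings.  Each table carries age-band rows and the printed
    40-79 sex-subtotal rows (``row_kind`` column); the manifest records the
    known +-1 rounding discordances between them.
    """

    base_case: pd.DataFrame
    averted: pd.DataFrame
    savings: pd.DataFrame
    manifest: dict


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


def _read_packaged(name: str, expected_sha: str) -> pd.DataFrame:
    raw = resources.files("ricesim.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha:
        raise FixtureIntegrityError(
            f"checksum mismatch for packaged fixture {name}: "
            f"expected {expected_sha}, got {digest}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_fixtures() -> FixtureTables:
    """Load the packaged reference tables, verifying checksums."""
    manifest = json.loads(
        resources.files("ricesim.data").joinpath("manifest.json").read_text()
    )
    sums = manifest["checksums"]
    return FixtureTables(
        base_case=_read_packaged("table2_base_case.csv", sums["table2_base_case.csv"]),
        averted=_read_packaged("table3_averted.csv", sums["table3_averted.csv"]),
        savings=_read_packaged("table4_savings.csv", sums["table4_savings.csv"]),
        manifest=manifest,
    )
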