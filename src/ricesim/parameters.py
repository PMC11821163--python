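"""Model inputs: strata, epidemiological rates, diet, effects and costs.

The cohort is the Japanese population aged 40-79 in 2019, stratified by sex
and 10-year age band (8 strata).  A :class:`ParameterSet` bundles everything
the simulation needs: per-stratum population counts, type 2 diabetes (T2D)
prevalence and incidence, all-cause mortality, the mortality hazard ratio for
T2D, mean white-rice intake (dry-grain equivalent), the substitution relative
risk, and annual national T2D healthcare expenditures.

Parameters are loaded from a single YAML config with sections ``population``,
``epidemiology``, ``diet``, ``effects``, ``costs`` and (optionally)
``scenario``.  Unknown keys and missing strata are hard errors: the loader
fails loud rather than filling silent defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SEXES",
    "AGE_BANDS",
    "STRATA",
    "Stratum",
    "EffectParams",
    "EconSettings",
    "ParameterSet",
    "SchemaError",
    "ValidationError",
    "load_parameters",
    "write_parameters",
    "per_case_cost",
]

SEXES = ("male", "female")
AGE_BANDS = ("40-49", "50-59", "60-69", "70-79")


class Stratum(NamedTuple):
    """One sex x 10-year-age-band cell of the cohort; the unit of simulation."""

    sex: str
    age_band: str

    def __str__(self) -> str:  # "male 40-49" -- the config-file key format
        return f"{self.sex} {self.age_band}"


#: The eight strata, in canonical order (men first, ages ascending).
STRATA: tuple[Stratum, ...] = tuple(
    Stratum(sex, band) for sex in SEXES for band in AGE_BANDS
)

#: Columns of the per-stratum table, with (inclusive) validity bounds.
_STRATUM_COLUMNS: dict[str, tuple[float, float]] = {
    "population": (np.nextafter(0.0, 1.0), np.inf),
    "prevalence_t2d": (0.0, 1.0),
    "prevalence_low": (0.0, 1.0),
    "prevalence_high": (0.0, 1.0),
    "incidence_t2d": (0.0, np.inf),
    "incidence_low": (0.0, np.inf),
    "incidence_high": (0.0, np.inf),
    "mortality_all_cause": (0.0, np.inf),
    "hr_mortality_t2d": (np.nextafter(0.0, 1.0), np.inf),
    "hr_low": (np.nextafter(0.0, 1.0), np.inf),
    "hr_high": (np.nextafter(0.0, 1.0), np.inf),
    "white_rice_g": (0.0, np.inf),
    "white_rice_low": (0.0, np.inf),
    "white_rice_high": (0.0, np.inf),
    "brown_rice_baseline_g": (0.0, np.inf),
    "national_t2d_expenditure_jpy": (0.0, np.inf),
}

#: (point, low, high) column triples whose CI ordering is enforced.
_CI_TRIPLES = (
    ("prevalence_t2d", "prevalence_low", "prevalence_high"),
    ("incidence_t2d", "incidence_low", "incidence_high"),
    ("hr_mortality_t2d", "hr_low", "hr_high"),
    ("white_rice_g", "white_rice_low", "white_rice_high"),
)


class SchemaError(ValueError):
    """Config structure is wrong: missing strata/sections or unknown keys."""


class ValidationError(ValueError):
    """A parameter value violates its stated bound or CI ordering."""


@dataclass(frozen=True)
class EffectParams:
    """Dose-response of T2D risk to white->brown rice substitution.

    ``rr_t2d`` is the relative risk of incident T2D per ``substitution_unit_g``
    grams/day of white rice replaced by brown rice (0.84 per 50 g/day in the
    default calibration, 95% CI 0.79-0.91).
    """

    rr_t2d: float = 0.84
    rr_low: float = 0.79
    rr_high: float = 0.91
    substitution_unit_g: float = 50.0

    def validate(self) -> None:
        if not (0.0 < self.rr_t2d <= 1.0):
            raise ValidationError(
                f"effects.rr_t2d must be in (0, 1], got {self.rr_t2d}"
            )
        if not (0.0 < self.rr_low <= self.rr_t2d <= self.rr_high):
            raise ValidationError(
                "effects rr CI must satisfy 0 < low <= point <= high, got "
                f"({self.rr_low}, {self.rr_t2d}, {self.rr_high})"
            )
        if not self.substitution_unit_g > 0:
            raise ValidationError(
                f"effects.substitution_unit_g must be > 0, got "
                f"{self.substitution_unit_g}"
            )


@dataclass(frozen=True)
class EconSettings:
    """Economic conventions: currency conversion and discounting."""

    exchange_rate_jpy_per_usd: float = 109.01
    discount_rate: float = 0.02
    #: When within a cycle costs are discounted: "end" (cycle c discounted
    #: c periods) or "midpoint" (c - 1/2 periods).
    discount_timing: str = "end"

    def validate(self) -> None:
        if not self.exchange_rate_jpy_per_usd > 0:
            raise ValidationError(
                "costs.exchange_rate_jpy_per_usd must be > 0, got "
                f"{self.exchange_rate_jpy_per_usd}"
            )
        if not (0.0 <= self.discount_rate <= 0.04):
            raise ValidationError(
                "costs.discount_rate must be in [0, 0.04] (the sensitivity "
                f"range), got {self.discount_rate}"
            )
        if self.discount_timing not in ("end", "midpoint"):
            raise ValidationError(
                f"costs.discount_timing must be 'end' or 'midpoint', got "
                f"{self.discount_timing!r}"
            )


@dataclass
class ParameterSet:
    """All validated inputs for every stratum.

    ``strata`` is a DataFrame indexed by (sex, age_band) in canonical order
    with one column per field in ``_STRATUM_COLUMNS``.
    """

    strata: pd.DataFrame
    effects: EffectParams = field(default_factory=EffectParams)
    econ: EconSettings = field(default_factory=EconSettings)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ParameterSet":
        """Enforce every structural and range invariant; return self."""
        expected = pd.MultiIndex.from_tuples(STRATA, names=["sex", "age_band"])
        missing = set(expected) - set(map(tuple, self.strata.index))
        if missing:
            names = ", ".join(f"{s} {b}" for s, b in sorted(missing))
            raise SchemaError(f"missing stratum block(s): {names}")
        extra = set(map(tuple, self.strata.index)) - set(expected)
        if extra:
            names = ", ".join(f"{s} {b}" for s, b in sorted(extra))
            raise SchemaError(f"unknown stratum key(s): {names}")
        if self.strata.index.duplicated().any():
            raise SchemaError("duplicated stratum rows")
        unknown_cols = set(self.strata.columns) - set(_STRATUM_COLUMNS)
        if unknown_cols:
            raise SchemaError(f"unknown parameter column(s): {sorted(unknown_cols)}")
        missing_cols = set(_STRATUM_COLUMNS) - set(self.strata.columns)
        if missing_cols:
            raise SchemaError(f"missing parameter column(s): {sorted(missing_cols)}")

        # canonical row order and column order
        self.strata = self.strata.reindex(expected)[list(_STRATUM_COLUMNS)]

        values = self.strata.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite parameter value present")
        for col, (lo, hi) in _STRATUM_COLUMNS.items():
            s = self.strata[col]
            bad = s[(s < lo) | (s > hi)]
            if len(bad):
                stratum = " ".join(bad.index[0])
                raise ValidationError(
                    f"{col} out of range [{lo}, {hi}] for stratum "
                    f"'{stratum}': {bad.iloc[0]}"
                )
        for point, low, high in _CI_TRIPLES:
            ok = (self.strata[low] <= self.strata[point]) & (
                self.strata[point] <= self.strata[high]
            )
            if not ok.all():
                stratum = " ".join(self.strata.index[~ok][0])
                raise ValidationError(
                    f"CI ordering low <= point <= high violated for {point} "
                    f"in stratum '{stratum}'"
                )
        # baseline brown rice cannot exceed white rice available to replace
        ok = self.strata["brown_rice_baseline_g"] <= self.strata["white_rice_g"]
        if not ok.all():
            stratum = " ".join(self.strata.index[~ok][0])
            raise ValidationError(
                f"brown_rice_baseline_g exceeds white_rice_g in stratum "
                f"'{stratum}'"
            )
        self.effects.validate()
        self.econ.validate()
        return self

    # -- derived quantities -------------------------------------------------

    def prevalent_cases(self) -> pd.Series:
        """Baseline prevalent T2D count per stratum (prevalence x population)."""
        return self.strata["prevalence_t2d"] * self.strata["population"]

    def annual_cost_per_case_jpy(self) -> pd.Series:
        """Annual healthcare cost per prevalent T2D case, JPY/person-year.

        National annual T2D expenditure for a stratum divided by the modeled
        baseline prevalent count, so that multiplying back by the prevalent
        count recovers the aggregate exactly.
        """
        return self.strata.apply(
            lambda row: per_case_cost(
                row["national_t2d_expenditure_jpy"],
                row["prevalence_t2d"] * row["population"],
            ),
            axis=1,
        )

    def config_hash(self) -> str:
        """Stable sha256 of the serialized parameter set (for run metadata)."""
        return hashlib.sha256(_to_yaml_text(self).encode()).hexdigest()

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            strata=self.strata.copy(), effects=self.effects, econ=self.econ
        )

    def with_econ(self, **kwargs) -> "ParameterSet":
        return ParameterSet(
            strata=self.strata.copy(),
            effects=self.effects,
            econ=replace(self.econ, **kwargs),
        )

    def with_effects(self, **kwargs) -> "ParameterSet":
        return ParameterSet(
            strata=self.strata.copy(),
            effects=replace(self.effects, **kwargs),
            econ=self.econ,
        )


def per_case_cost(national_expenditure: float, prevalent_cases: float) -> float:
    """Annual per-case cost (currency/person-year) from an aggregate total.

    Raises ZeroDivisionError with a remediation hint when there is expenditure
    but no prevalent case to carry it.
    """
    if prevalent_cases <= 0:
        if national_expenditure == 0:
            return 0.0
        raise ZeroDivisionError(
            "prevalent_cases is 0 but national expenditure is positive; "
            "check the prevalence and population inputs for this stratum"
        )
    return national_expenditure / prevalent_cases


# ---------------------------------------------------------------------------
# YAML config I/O


_TOP_SECTIONS = ("population", "epidemiology", "diet", "effects", "costs", "scenario")

_EPI_KEYS = {
    "prevalence_t2d", "prevalence_ci", "incidence_t2d", "incidence_ci",
    "mortality_all_cause", "hr_mortality_t2d", "hr_ci",
}
_DIET_KEYS = {"white_rice_g", "white_rice_ci", "brown_rice_baseline_g"}
_EFFECT_KEYS = {"rr_t2d", "rr_ci", "substitution_unit_g"}
_COST_KEYS = {
    "exchange_rate_jpy_per_usd", "discount_rate", "discount_timing",
    "national_t2d_expenditure_jpy",
}


def _parse_stratum_key(key: str) -> Stratum:
    parts = str(key).split()
    if len(parts) != 2 or parts[0] not in SEXES or parts[1] not in AGE_BANDS:
        raise SchemaError(
            f"bad stratum key {key!r}; expected '<sex> <age-band>' like "
            f"'male 40-49'"
        )
    return Stratum(parts[0], parts[1])


def _stratified_section(raw: dict, section: str, allowed: set[str] | None) -> dict:
    """Parse one stratified section into {Stratum: {field: value}}."""
    if not isinstance(raw, dict):
        raise SchemaError(f"section '{section}' must be a mapping of strata")
    out: dict[Stratum, dict] = {}
    for key, block in raw.items():
        stratum = _parse_stratum_key(key)
        if allowed is None:  # scalar-valued section (population, expenditures)
            out[stratum] = block
            continue
        if not isinstance(block, dict):
            raise SchemaError(
                f"section '{section}', stratum '{stratum}': expected a mapping"
            )
        unknown = set(block) - allowed
        if unknown:
            raise SchemaError(
                f"section '{section}', stratum '{stratum}': unknown key(s) "
                f"{sorted(unknown)}"
            )
        out[stratum] = block
    return out


def _ci(block: dict, key: str, point: float) -> tuple[float, float]:
    ci = block.get(f"{key}_ci")
    if ci is None:
        return (point, point)
    if not (isinstance(ci, (list, tuple)) and len(ci) == 2):
        raise SchemaError(f"{key}_ci must be a [low, high] pair, got {ci!r}")
    return float(ci[0]), float(ci[1])


def parameters_from_dict(cfg: dict) -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from a parsed config dict."""
    if not isinstance(cfg, dict):
        raise SchemaError("config root must be a mapping")
    unknown = set(cfg) - set(_TOP_SECTIONS)
    if unknown:
        raise SchemaError(f"unknown top-level section(s): {sorted(unknown)}")
    for section in ("population", "epidemiology", "diet", "effects", "costs"):
        if section not in cfg:
            raise SchemaError(f"missing required section '{section}'")

    pop = _stratified_section(cfg["population"], "population", None)
    epi = _stratified_section(cfg["epidemiology"], "epidemiology", _EPI_KEYS)
    diet = _stratified_section(cfg["diet"], "diet", _DIET_KEYS)

    costs_raw = cfg["costs"]
    unknown = set(costs_raw) - _COST_KEYS
    if unknown:
        raise SchemaError(f"section 'costs': unknown key(s) {sorted(unknown)}")
    if "national_t2d_expenditure_jpy" not in costs_raw:
        raise SchemaError("section 'costs' must include national_t2d_expenditure_jpy")
    exp = _stratified_section(
        costs_raw["national_t2d_expenditure_jpy"],
        "costs.national_t2d_expenditure_jpy",
        None,
    )

    rows = []
    for stratum in STRATA:
        for name, table in (
            ("population", pop), ("epidemiology", epi), ("diet", diet),
            ("costs.national_t2d_expenditure_jpy", exp),
        ):
            if stratum not in table:
                raise SchemaError(
                    f"section '{name}': missing stratum '{stratum}'"
                )
        e, d = epi[stratum], diet[stratum]
        prev = float(e["prevalence_t2d"])
        inc = float(e["incidence_t2d"])
        hr = float(e["hr_mortality_t2d"])
        wr = float(d["white_rice_g"])
        prev_lo, prev_hi = _ci(e, "prevalence", prev)
        inc_lo, inc_hi = _ci(e, "incidence", inc)
        hr_lo, hr_hi = _ci(e, "hr", hr)
        wr_lo, wr_hi = _ci(d, "white_rice", wr)
        rows.append({
            "sex": stratum.sex,
            "age_band": stratum.age_band,
            "population": float(pop[stratum]),
            "prevalence_t2d": prev,
            "prevalence_low": prev_lo,
            "prevalence_high": prev_hi,
            "incidence_t2d": inc,
            "incidence_low": inc_lo,
            "incidence_high": inc_hi,
            "mortality_all_cause": float(e["mortality_all_cause"]),
            "hr_mortality_t2d": hr,
            "hr_low": hr_lo,
            "hr_high": hr_hi,
            "white_rice_g": wr,
            "white_rice_low": wr_lo,
            "white_rice_high": wr_hi,
            "brown_rice_baseline_g": float(d.get("brown_rice_baseline_g", 1.0)),
            "national_t2d_expenditure_jpy": float(exp[stratum]),
        })
    strata = pd.DataFrame(rows).set_index(["sex", "age_band"])

    eff_raw = cfg["effects"]
    unknown = set(eff_raw) - _EFFECT_KEYS
    if unknown:
        raise SchemaError(f"section 'effects': unknown key(s) {sorted(unknown)}")
    rr = float(eff_raw["rr_t2d"])
    rr_lo, rr_hi = _ci(eff_raw, "rr", rr)
    effects = EffectParams(
        rr_t2d=rr, rr_low=rr_lo, rr_high=rr_hi,
        substitution_unit_g=float(eff_raw.get("substitution_unit_g", 50.0)),
    )
    econ = EconSettings(
        exchange_rate_jpy_per_usd=float(
            costs_raw.get("exchange_rate_jpy_per_usd", 109.01)
        ),
        discount_rate=float(costs_raw.get("discount_rate", 0.02)),
        discount_timing=str(costs_raw.get("discount_timing", "end")),
    )
    return ParameterSet(strata=strata, effects=effects, econ=econ).validate()


def parameters_to_dict(params: ParameterSet) -> dict:
    """Inverse of :func:`parameters_from_dict` (lossless round-trip)."""
    s = params.strata
    cfg: dict = {
        "population": {}, "epidemiology": {}, "diet": {},
        "effects": {
            "rr_t2d": params.effects.rr_t2d,
            "rr_ci": [params.effects.rr_low, params.effects.rr_high],
            "substitution_unit_g": params.effects.substitution_unit_g,
        },
        "costs": {
            "exchange_rate_jpy_per_usd": params.econ.exchange_rate_jpy_per_usd,
            "discount_rate": params.econ.discount_rate,
            "discount_timing": params.econ.discount_timing,
            "national_t2d_expenditure_jpy": {},
        },
    }
    for stratum in STRATA:
        key = str(stratum)
        row = s.loc[stratum]
        cfg["population"][key] = float(row["population"])
        cfg["epidemiology"][key] = {
            "prevalence_t2d": float(row["prevalence_t2d"]),
            "prevalence_ci": [float(row["prevalence_low"]), float(row["prevalence_high"])],
            "incidence_t2d": float(row["incidence_t2d"]),
            "incidence_ci": [float(row["incidence_low"]), float(row["incidence_high"])],
            "mortality_all_cause": float(row["mortality_all_cause"]),
            "hr_mortality_t2d": float(row["hr_mortality_t2d"]),
            "hr_ci": [float(row["hr_low"]), float(row["hr_high"])],
        }
        cfg["diet"][key] = {
            "white_rice_g": float(row["white_rice_g"]),
            "white_rice_ci": [float(row["white_rice_low"]), float(row["white_rice_high"])],
            "brown_rice_baseline_g": float(row["brown_rice_baseline_g"]),
        }
        cfg["costs"]["national_t2d_expenditure_jpy"][key] = float(
            row["national_t2d_expenditure_jpy"]
        )
    return cfg


def _to_yaml_text(params: ParameterSet) -> str:
    return yaml.safe_dump(parameters_to_dict(params), sort_keys=True)


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load and validate a parameter config from a YAML (or JSON) file."""
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return parameters_from_dict(cfg)


def write_parameters(params: ParameterSet, config_path: str | Path) -> None:
    """Serialize a parameter set back to YAML (round-trips losslessly)."""
    Path(config_path).write_text(_to_yaml_text(params))
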