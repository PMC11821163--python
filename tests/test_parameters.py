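"""Parameter loading, validation and the per-case cost conversion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricesim import (
    STRATA,
    SchemaError,
    ValidationError,
    load_parameters,
    per_case_cost,
    write_parameters,
)
from ricesim.parameters import parameters_from_dict, parameters_to_dict


@pytest.fixture()
def config_dict(japan_params):
    return parameters_to_dict(japan_params)


class TestLoadAndRoundTrip:
    def test_yaml_round_trip_is_lossless(self, japan_params, tmp_path):
        path = tmp_path / "config.yaml"
        write_parameters(japan_params, path)
        reloaded = load_parameters(path)
        assert reloaded.strata.equals(japan_params.strata)
        assert reloaded.effects == japan_params.effects
        assert reloaded.econ == japan_params.econ

    def test_default_calibration_has_8_strata_and_published_rr(self, japan_params):
        assert len(japan_params.strata) == 8
        assert list(japan_params.strata.index) == [tuple(s) for s in STRATA]
        assert japan_params.effects.rr_t2d == 0.84
        assert (japan_params.effects.rr_low, japan_params.effects.rr_high) == (0.79, 0.91)

    def test_missing_config_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_parameters(tmp_path / "nope.yaml")


class TestValidation:
    def test_out_of_range_prevalence_names_field(self, config_dict):
        config_dict["epidemiology"]["male 40-49"]["prevalence_t2d"] = 1.2
        config_dict["epidemiology"]["male 40-49"]["prevalence_ci"] = [1.2, 1.2]
        with pytest.raises(ValidationError, match="prevalence_t2d"):
            parameters_from_dict(config_dict)

    def test_missing_stratum_names_stratum(self, config_dict):
        for section in ("population", "epidemiology", "diet"):
            cfg = {k: dict(v) if isinstance(v, dict) else v for k, v in config_dict.items()}
            cfg[section] = {k: v for k, v in cfg[section].items() if k != "female 70-79"}
            with pytest.raises(SchemaError, match="female 70-79"):
                parameters_from_dict(cfg)

    def test_unknown_key_is_rejected(self, config_dict):
        config_dict["epidemiology"]["male 40-49"]["smoking_rate"] = 0.2
        with pytest.raises(SchemaError, match="smoking_rate"):
            parameters_from_dict(config_dict)

    def test_unknown_top_level_section_is_rejected(self, config_dict):
        config_dict["complications"] = {}
        with pytest.raises(SchemaError, match="complications"):
            parameters_from_dict(config_dict)

    @pytest.mark.parametrize(
        "section, key, field, bad",
        [
            ("epidemiology", "male 40-49", "incidence_t2d", -0.01),
            ("epidemiology", "female 50-59", "mortality_all_cause", -1e-9),
            ("epidemiology", "male 60-69", "hr_mortality_t2d", 0.0),
            ("diet", "female 40-49", "white_rice_g", -5.0),
            ("population", "male 70-79", None, 0.0),
        ],
    )
    def test_single_field_perturbed_out_of_bound_is_rejected(
        self, config_dict, section, key, field, bad
    ):
        if field is None:
            config_dict[section][key] = bad
        else:
            config_dict[section][key][field] = bad
            # keep the CI triple from masking the bound violation
            ci_key = {
                "incidence_t2d": "incidence_ci",
                "mortality_all_cause": None,
                "hr_mortality_t2d": "hr_ci",
                "white_rice_g": "white_rice_ci",
            }[field]
            if ci_key:
                config_dict[section][key][ci_key] = [bad, bad]
        with pytest.raises((ValidationError, SchemaError)):
            parameters_from_dict(config_dict)

    def test_ci_ordering_enforced(self, config_dict):
        block = config_dict["epidemiology"]["male 40-49"]
        block["incidence_ci"] = [block["incidence_t2d"] * 2, block["incidence_t2d"] * 3]
        with pytest.raises(ValidationError, match="CI ordering"):
            parameters_from_dict(config_dict)

    def test_baseline_brown_rice_cannot_exceed_white_rice(self, config_dict):
        config_dict["diet"]["male 40-49"]["brown_rice_baseline_g"] = 1e6
        with pytest.raises(ValidationError, match="brown_rice_baseline_g"):
            parameters_from_dict(config_dict)


class TestPerCaseCost:
    def test_exact_division(self):
        assert per_case_cost(1_000_000, 1_000) == 1_000.0

    def test_zero_numerator(self):
        assert per_case_cost(0, 500) == 0.0

    def test_zero_cases_raises_with_hint(self):
        with pytest.raises(ZeroDivisionError, match="prevalence"):
            per_case_cost(100.0, 0)

    @settings(max_examples=200, deadline=None)
    @given(
        expenditure=st.floats(min_value=0, max_value=1e13, allow_nan=False),
        cases=st.floats(min_value=1e-3, max_value=1e8, allow_nan=False),
    )
    def test_multiplying_back_recovers_aggregate(self, expenditure, cases):
        assert per_case_cost(expenditure, cases) * cases == pytest.approx(
            expenditure, rel=1e-12, abs=1e-9
        )
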