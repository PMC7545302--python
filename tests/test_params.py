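"""Model-input loading, validation, cost aggregates and PSA distributions."""

import numpy as np
import pytest

from dupcea import (
    ParameterError,
    Scenario,
    direct_cost,
    expected_complication_cost,
    fit_distribution,
    load_parameters,
)
from dupcea.params import ParameterValue, treatment_event_cost


class TestDefaults:
    @pytest.mark.parametrize(
        "param_id, expected",
        [
            ("direct_cost.CCH.medication", 5400.00),
            ("direct_cost.LF.facility_fee", 2623.34),
            ("recurrence.LF.PIP.low", 0.24),
            ("success.CCH.MCP.low", 0.61),
            ("success.PNA.PIP.high", 0.21),
            ("utility.PIP.high", 0.942),
            ("days_off.LF", 37.0),
            ("complication_rate.CCH.skin_tear", 0.0397),
            ("complication_cost.nerve_injury", 5435.18),
            ("age", 60.0),
        ],
    )
    def test_base_values(self, params, param_id, expected):
        assert params.get(param_id).base == pytest.approx(expected)

    def test_structure(self, params):
        assert len(params.success) == 12
        assert len(params.recurrence) == 12
        assert len(params.utilities) == 4
        # component lists per treatment
        assert set(params.direct_components("CCH")) == {
            "clinic_visit", "medication", "manipulation_visit", "hand_therapy",
        }
        assert set(params.direct_components("PNA")) == {"procedure", "hand_therapy"}
        assert set(params.direct_components("LF")) == {
            "procedure", "anesthesia", "facility_fee", "hand_therapy",
        }
        assert len(params.complications("CCH")) == 4
        assert len(params.complications("PNA")) == 5
        assert len(params.complications("LF")) == 6

    def test_economics_defaults(self, params):
        assert params.econ.discount_rate == 0.03
        assert params.econ.willingness_to_pay == 100_000.0
        assert params.econ.perspective == "societal"
        assert params.indirect.annual_income == 63_179.0
        assert params.age.low == 45.0 and params.age.high == 75.0


class TestCostAggregates:
    @pytest.mark.parametrize(
        "treatment, expected",
        [
            ("LF", 1149.29 + 245.00 + 2623.34 + 1394.35),   # 5411.98
            ("PNA", 322.91 + 673.57),                        # 996.48
            ("CCH", 172.26 + 5400.00 + 209.02 + 314.62),     # 6095.90
        ],
    )
    def test_direct_cost(self, params, treatment, expected):
        assert direct_cost(treatment, params) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "treatment, expected",
        [
            # hand-summed rate x cost over each treatment's complication list
            ("CCH", 0.0038 * 3479.56 + 0.0156 * 7987.00 + 0.0026 * 176.23 + 0.0397 * 75.32),
            ("PNA", 0.0038 * 3479.56 + 0.0155 * 2746.26 + 0.0052 * 2000.33
                    + 0.0038 * 5435.18 + 0.0091 * 3581.64),
            ("LF", 0.0017 * 3479.56 + 0.0113 * 7987.00 + 0.0128 * 2746.26
                   + 0.0216 * 5435.18 + 0.0095 * 3581.64 + 0.0128 * 1658.78),
        ],
    )
    def test_expected_complication_cost(self, params, treatment, expected):
        assert expected_complication_cost(treatment, params) == pytest.approx(expected)

    def test_expected_complication_cost_zero_rates(self):
        overrides = {
            "complication_rates": {
                "CCH": {k: {"base": 0.0, "low": 0.0, "high": 0.0, "distribution": "fixed"}
                        for k in ("tendon_injury", "admission", "medication_allergy", "skin_tear")}
            }
        }
        p = load_parameters(overrides=overrides)
        assert expected_complication_cost("CCH", p) == 0.0

    def test_wage_loss_only_below_retirement(self, params):
        below = treatment_event_cost("LF", params, age=60.0)
        above = treatment_event_cost("LF", params, age=70.0)
        assert below - above == pytest.approx(37 * params.indirect.daily_wage)


class TestOverrides:
    def test_file_override(self, tmp_path):
        cfg = tmp_path / "override.yaml"
        cfg.write_text(
            "transitions:\n  success:\n    CCH:\n      MCP:\n        low: {base: 0.5, low: 0.4, high: 0.6}\n"
        )
        p = load_parameters(str(cfg))
        assert p.success[("CCH", "MCP", "low")].base == 0.5
        # untouched values keep their defaults
        assert p.success[("PNA", "MCP", "low")].base == 0.58

    def test_out_of_range_probability_rejected(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text(
            "transitions:\n  success:\n    CCH:\n      MCP:\n        low: {base: 1.7, low: 1.7, high: 1.7}\n"
        )
        with pytest.raises(ParameterError, match="CCH.MCP.low"):
            load_parameters(str(cfg))

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError, match="not_a_key"):
            load_parameters(overrides={"not_a_key": 1})

    def test_low_above_high_rejected(self):
        with pytest.raises(ParameterError, match="low <= base <= high"):
            load_parameters(
                overrides={"demographics": {"age": {"base": 60, "low": 70, "high": 50}}}
            )

    def test_non_numeric_rejected(self):
        with pytest.raises(ParameterError):
            load_parameters(overrides={"demographics": {"age": {"base": "abc"}}})

    def test_with_value_roundtrip(self, params):
        p2 = params.with_value("success.PNA.MCP.low", 0.49)
        assert p2.success[("PNA", "MCP", "low")].base == 0.49
        assert params.success[("PNA", "MCP", "low")].base == 0.58  # original untouched
        with pytest.raises(ParameterError, match="unknown parameter"):
            params.with_value("success.XXX", 0.5)

    def test_scenario_validation(self):
        with pytest.raises(ParameterError):
            Scenario("DIP", "low")
        with pytest.raises(ParameterError):
            Scenario("MCP", "medium")


class TestDistributions:
    def test_beta_fit_061_row(self, params):
        d = fit_distribution(params.success[("CCH", "MCP", "low")])
        assert d.kind == "beta"
        assert d.args == (62.0, 40.0)
        assert d.mean() == pytest.approx(62 / 102, abs=1e-12)
        lo, hi = d.interval(0.95)
        # central 95% interval reproduces this row's printed bounds
        assert lo == pytest.approx(0.52, abs=0.015)
        assert hi == pytest.approx(0.71, abs=0.015)

    def test_truncated_normal_fit(self, params):
        pv = params.direct_costs[("CCH", "medication")]
        d = fit_distribution(pv)
        assert d.kind == "truncated_normal"
        mean, sd = d.args
        assert mean == 5400.0
        assert sd == pytest.approx((6210 - 4590) / (2 * 1.959964), rel=1e-6)
        assert sd == pytest.approx(413.3, abs=0.1)

    def test_uniform_degenerate_is_point_mass(self):
        d = fit_distribution(ParameterValue(3.0, 3.0, 3.0, "uniform"))
        assert d.kind == "point"
        rng = np.random.default_rng(0)
        assert np.all(d.sample(rng, 10) == 3.0)
        assert d.std() == 0.0

    def test_beta_requires_open_unit_interval(self):
        with pytest.raises(ParameterError):
            fit_distribution(ParameterValue(1.2, 1.0, 1.4, "beta"))

    def test_unit_interval_truncation(self):
        d = fit_distribution(
            ParameterValue(0.95, 0.80, 1.10, "normal"), unit_interval=True
        )
        x = d.sample(np.random.default_rng(1), 20_000)
        assert np.all(x <= 1.0) and np.all(x >= 0.0)

    @pytest.mark.parametrize(
        "param_id",
        ["success.CCH.MCP.low", "direct_cost.LF.hand_therapy", "days_off.PNA", "age",
         "complication_rate.LF.nerve_injury", "utility.MCP.high"],
    )
    def test_sampling_mean_and_support(self, params, param_id):
        fp = {f.id: f for f in params.flatten()}[param_id]
        d = fit_distribution(fp.value, unit_interval=fp.unit_interval)
        n = 100_000
        x = np.asarray(d.sample(np.random.default_rng(7), n))
        lo, hi = d.support
        assert x.min() >= lo and x.max() <= hi
        se = d.std() / np.sqrt(n)
        assert abs(x.mean() - d.mean()) < 3 * se + 1e-12
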