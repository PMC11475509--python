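import json
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxyrelax import (
    ConditionPoint,
    LinearR1Relation,
    ModelParameters,
    delta_t1,
    dispersion_curve,
    infer_pO2,
    r1_with_oxygen,
    relaxivity,
    relaxivity_from_si,
    relaxivity_to_si,
)
from oxyrelax.core import CalibrationRangeWarning, NegativePO2Warning, kelvin_to_celsius

PUBLISHED = ModelParameters(4.87, 1.99, 0.844, 0.0323)


class TestRelaxivityModel:
    @pytest.mark.parametrize(
        "b0, temp, expected",
        [
            # hand-substitution oracles at the published constants
            (1.5, 37, 2.9281917389319947),
            (3.0, 37, 2.2966356953992597),
            (0.011, 25, 6.5203276349937695),
        ],
    )
    def test_hand_substitution(self, b0, temp, expected):
        assert relaxivity(PUBLISHED, ConditionPoint(b0, temp)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_field_and_high_field_limits(self):
        # B0=0: full Lorentzian plateau; B0->inf: offset + temperature term
        t = 37.0
        plateau = relaxivity(PUBLISHED, ConditionPoint(0.0, t))
        assert plateau == pytest.approx(4.87 + 0.844 + 0.0323 * t, rel=1e-15)
        tail = relaxivity(PUBLISHED, ConditionPoint(1e6, t))
        assert tail == pytest.approx(0.844 + 0.0323 * t, rel=1e-6)

    def test_masked_parameters_contribute_zero(self):
        masked = PUBLISHED.with_mask((True, True, True, False))
        assert relaxivity(masked, ConditionPoint(0.0, 99.0)) == pytest.approx(
            4.87 + 0.844, rel=1e-15
        )
        flat = PUBLISHED.with_mask((True, False, False, False))
        assert relaxivity(flat, ConditionPoint(8.0, 30.0)) == pytest.approx(4.87)

    def test_strictly_decreasing_in_field(self):
        grid = np.linspace(0, 9, 200)
        values = relaxivity(PUBLISHED, b0=grid, temperature=25.0)
        assert np.all(np.diff(values) < 0)

    def test_linear_in_temperature(self):
        temps = np.arange(10, 50, 2.0)
        values = relaxivity(PUBLISHED, b0=3.0, temperature=temps)
        assert np.allclose(np.diff(values, n=2), 0.0, atol=1e-12)

    def test_dispersion_curve_matches_pointwise(self):
        grid = np.array([0.011, 0.5, 1.5, 3.0, 8.45])
        curve = dispersion_curve(PUBLISHED, grid, 25.0)
        assert curve.shape == (5, 2)
        np.testing.assert_allclose(
            curve[:, 1], relaxivity(PUBLISHED, b0=grid, temperature=25.0)
        )
        single = dispersion_curve(PUBLISHED, [1.5], 25.0)
        assert single.shape == (1, 2)
        with pytest.raises(ValueError):
            dispersion_curve(PUBLISHED, [], 25.0)

    def test_out_of_calibrated_range_warns_but_returns(self):
        with pytest.warns(CalibrationRangeWarning):
            value = relaxivity(
                PUBLISHED, ConditionPoint(0.005, 25.0), warn_out_of_range=True
            )
        assert value > 0
        with pytest.warns(CalibrationRangeWarning):
            relaxivity(PUBLISHED, ConditionPoint(3.0, 50.0), warn_out_of_range=True)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            relaxivity(PUBLISHED, ConditionPoint(3.0, 37.0), warn_out_of_range=True)

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            ModelParameters(-1.0, 1.99, 0.844, 0.0323)
        with pytest.raises(ValueError):
            ModelParameters(4.87, -0.5, 0.844, 0.0323)
        with pytest.raises(ValueError):
            ModelParameters(4.87, 1.99, 0.844, 0.0323,
                            active_mask=(False, True, True, True))

    def test_json_roundtrip_preserves_mask_and_units(self):
        params = PUBLISHED.with_mask((True, True, False, True))
        back = ModelParameters.from_json(params.to_json())
        assert back == params
        payload = json.loads(params.to_json())
        assert payload["parameters"]["c2"]["units"] == "T^-2"


class TestLinearR1Relation:
    REL = LinearR1Relation(r1_0=1 / 3, r1ox=3.6e-4)

    def test_r1_at_200_mmhg(self):
        assert r1_with_oxygen(self.REL, 200) == pytest.approx(
            0.4053333333333333, rel=1e-12
        )
        assert r1_with_oxygen(self.REL, 0) == self.REL.r1_0

    def test_linearity_in_pO2(self):
        d1 = r1_with_oxygen(self.REL, 100) - self.REL.r1_0
        d2 = r1_with_oxygen(self.REL, 200) - self.REL.r1_0
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_inversion_of_known_rate(self):
        assert infer_pO2(self.REL, 0.4053333333333333) == pytest.approx(200, rel=1e-10)
        assert infer_pO2(self.REL, self.REL.r1_0) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(pO2=st.floats(0, 800))
    def test_roundtrip_identity(self, pO2):
        back = infer_pO2(self.REL, r1_with_oxygen(self.REL, pO2))
        assert back == pytest.approx(pO2, rel=1e-10, abs=1e-10)

    def test_below_baseline_warns_and_stays_negative(self):
        with pytest.warns(NegativePO2Warning):
            value = infer_pO2(self.REL, self.REL.r1_0 - 1e-5)
        assert value < 0

    def test_negative_pO2_rejected(self):
        with pytest.raises(ValueError):
            r1_with_oxygen(self.REL, -1.0)


class TestDeltaT1:
    def test_published_scenario(self):
        # 3000 ms starting T1, r1ox 3.6e-4 s^-1/mmHg, +200 mmHg oxygen
        assert delta_t1(3000, 3.6e-4, 200) == pytest.approx(532.894736842105)

    def test_no_oxygen_change_no_t1_change(self):
        assert delta_t1(3000, 3.6e-4, 0) == 0.0

    def test_monotone_in_initial_t1_and_bounded(self):
        t1s = np.array([500, 1000, 2000, 3000, 4000])
        deltas = np.array([delta_t1(t, 3.6e-4, 200) for t in t1s])
        assert np.all(np.diff(deltas) > 0)
        assert np.all(deltas < t1s)

    def test_rejects_nonpositive_t1(self):
        with pytest.raises(ValueError):
            delta_t1(0, 3.6e-4, 200)


def test_scale_conversions_are_inverse():
    assert relaxivity_to_si(3.6) == pytest.approx(3.6e-4)
    assert relaxivity_from_si(relaxivity_to_si(2.93)) == pytest.approx(2.93, rel=1e-15)


def test_kelvin_boundary_conversion():
    assert kelvin_to_celsius(310.15) == pytest.approx(37.0)
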