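"""Unit and property tests for the calibrated-BOLD physiology core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laminarbold.physio import (
    CalibParams,
    DegenerateOxygenStateError,
    ModelSaturationError,
    arterial_o2_content,
    bold_change,
    forward_bold_hypercapnia,
    forward_bold_hyperoxia,
    grubb_cbv_ratio,
    hyperoxia_dhb_ratio,
    invert_cbv,
    m_value,
    oxygen_state,
    severinghaus_saturation,
)


class TestCalibParams:
    def test_defaults_are_the_reference_constants(self, params):
        assert params.alpha == 0.2
        assert params.beta == 1.0
        assert params.oef0 == 0.30
        assert params.cmro2_ratio_by_condition == {
            "+3": 0.97, "+5": 0.95, "+8": 0.92, "+10": 0.90,
        }

    @pytest.mark.parametrize("bad", [
        {"alpha": 0.0}, {"alpha": 1.0}, {"beta": 0.0}, {"oef0": 1.0},
        {"cmro2_ratio_by_condition": {"+5": 1.5}},
    ])
    def test_invariants_rejected(self, bad):
        with pytest.raises(ValueError):
            CalibParams(**bad)

    def test_flat_dict_round_trip(self, params):
        restored = CalibParams.from_dict(params.to_dict())
        assert restored == params
        assert all(np.isscalar(v) for v in params.to_dict().values())

    def test_unknown_level_raises(self, params):
        with pytest.raises(KeyError, match="unknown hypercapnia level"):
            params.cmro2_ratio("+42")


class TestOxygenTransport:
    # expected values evaluated by hand from the closed forms
    @pytest.mark.parametrize("po2, expected", [(100.0, 0.97747), (450.0, 0.99974)])
    def test_saturation_reference_points(self, po2, expected):
        assert severinghaus_saturation(po2) == pytest.approx(expected, abs=1e-5)

    def test_saturation_asymptote_and_domain(self):
        assert severinghaus_saturation(1e9) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            severinghaus_saturation(0.0)

    @given(st.floats(1.0, 2000.0), st.floats(1.0, 2000.0))
    @settings(max_examples=50, derandomize=True)
    def test_saturation_monotone(self, a, b):
        lo, hi = sorted((a, b))
        if hi > lo:
            assert severinghaus_saturation(hi) > severinghaus_saturation(lo)

    def test_o2_content_reference_point(self, params):
        # 1.34 * 15 * 0.97747 + 0.0031 * 100
        assert arterial_o2_content(100.0, params) == pytest.approx(19.957, abs=2e-3)

    def test_o2_content_dissolved_only_without_hb(self):
        p = CalibParams(hb=0.0)
        assert arterial_o2_content(250.0, p) == pytest.approx(p.eps * 250.0)

    def test_oxygen_state_consistency(self, params):
        state = oxygen_state(100.0, params)
        assert state.dhb_fraction == pytest.approx(1.0 - state.svo2)
        assert 0.0 <= state.svo2 <= state.sao2 <= 1.0


class TestDhbRatio:
    def test_identical_states_give_unity(self, params):
        assert hyperoxia_dhb_ratio(100.0, 100.0, params) == pytest.approx(1.0)

    def test_reference_hyperoxia_ratio(self, params):
        # content chain by hand: CaO2(100)=19.957, CaO2(450)=21.490,
        # extraction 5.987 -> SvO2 0.6950 / 0.7713 -> ratio 0.7499
        assert hyperoxia_dhb_ratio(100.0, 450.0, params) == pytest.approx(0.750, abs=1e-3)

    def test_ratio_decreases_with_po2_until_cap(self, params):
        po2 = np.array([150.0, 250.0, 450.0, 800.0])
        ratios = hyperoxia_dhb_ratio(100.0, po2, params)
        assert np.all(np.diff(ratios) < 0)
        assert np.all(ratios < 1.0)

    def test_degenerate_baseline_raises(self):
        p = CalibParams(oef0=0.001)
        with pytest.raises(DegenerateOxygenStateError):
            hyperoxia_dhb_ratio(5000.0, 6000.0, p)

    def test_unit_consistency_under_rescaling(self, params):
        """Rescaling phi*hb (O2-carrying capacity) leaves the ratio invariant.

        The ratio depends only on saturations; doubling phi and halving hb
        keeps phi*hb and (to the dissolved-term accuracy) the whole chain.
        """
        a = hyperoxia_dhb_ratio(100.0, 450.0, params)
        swapped = CalibParams(phi=params.phi * 2, hb=params.hb / 2)
        b = hyperoxia_dhb_ratio(100.0, 450.0, swapped)
        assert a == pytest.approx(b, rel=1e-12)


class TestMValue:
    def test_zero_change_gives_zero(self, params):
        assert m_value(0.0, 0.8, params) == 0.0

    def test_direct_arithmetic(self):
        assert m_value(0.02, 0.8, CalibParams(beta=1.0)) == pytest.approx(0.10)

    def test_degenerate_ratio_raises(self, params):
        with pytest.raises(DegenerateOxygenStateError):
            m_value(0.02, 1.0, params)

    @given(st.floats(0.01, 0.3), st.floats(0.1, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_scale_linearity(self, m, k):
        base = m_value(m, 0.75)
        assert m_value(k * m, 0.75) == pytest.approx(k * base, rel=1e-12)

    def test_round_trip_through_hyperoxia_forward_model(self, params):
        m_true, ratio = 0.14, 0.7499
        dbold = forward_bold_hyperoxia(ratio, m_true, params)
        assert m_value(dbold, ratio, params) == pytest.approx(m_true, abs=1e-14)

    def test_generic_model_reduces_to_hyperoxia_form_without_cbv_change(self, params):
        """With no CBV change the full calibrated model is the hyperoxia one."""
        for ratio in (0.6, 0.75, 0.9):
            assert bold_change(0.14, 1.0, ratio, params) == pytest.approx(
                forward_bold_hyperoxia(ratio, 0.14, params), abs=1e-15
            )


class TestDavisGrubb:
    def test_grubb_reference_points(self, params):
        assert grubb_cbv_ratio(1.0, params) == 1.0
        assert grubb_cbv_ratio(1.9, params) == pytest.approx(1.9**0.2, rel=1e-12)
        assert grubb_cbv_ratio(1.9, params) == pytest.approx(1.137, abs=1e-3)
        with pytest.raises(ValueError):
            grubb_cbv_ratio(0.0, params)

    def test_forward_null_state_is_zero(self, params):
        assert forward_bold_hypercapnia(1.0, 1.0, 0.14, params) == pytest.approx(0.0)

    def test_forward_reference_point(self, params):
        # 0.14 * (1 - 1.1**-4 * 0.95)
        assert forward_bold_hypercapnia(1.1, 0.95, 0.14, params) == pytest.approx(
            0.0492, abs=1e-4
        )

    def test_forward_increasing_in_cbv(self, params):
        cbv = np.linspace(1.0, 1.3, 7)
        vals = forward_bold_hypercapnia(cbv, 0.95, 0.14, params)
        assert np.all(np.diff(vals) > 0)

    def test_invert_reference_points(self, params):
        assert invert_cbv(0.0, 0.14, 1.0, params) == pytest.approx(1.0)
        assert invert_cbv(0.0492, 0.14, 0.95, params) == pytest.approx(1.100, abs=2e-4)

    def test_invert_error_conditions(self, params):
        with pytest.raises(ModelSaturationError):
            invert_cbv(0.15, 0.14, 0.95, params)
        with pytest.raises(ValueError):
            invert_cbv(0.01, -0.1, 0.95, params)

    def test_round_trip_identity_on_grid(self, params):
        """invert(forward(x)) = x to < 1e-9 over the physiological grid."""
        cbv = np.linspace(0.8, 1.5, 15)
        for m in np.linspace(0.05, 0.25, 5):
            for level in ("+3", "+5", "+8", "+10"):
                r = params.cmro2_ratio(level)
                back = invert_cbv(forward_bold_hypercapnia(cbv, r, m, params), m, r, params)
                assert np.abs(back - cbv).max() < 1e-9

    @given(st.floats(0.85, 1.45), st.floats(0.06, 0.24), st.floats(0.9, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_property(self, cbv, m, cmro2):
        p = CalibParams()
        assert invert_cbv(
            forward_bold_hypercapnia(cbv, cmro2, m, p), m, cmro2, p
        ) == pytest.approx(cbv, abs=1e-9)
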