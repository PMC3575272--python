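"""Tactor display logic and the first-order biofeedback torque."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from posturefb.biofeedback import (BiofeedbackParams, DisplayConfig,
                                   TactorActivation, TiltSignal,
                                   advance_feedback_torque,
                                   select_activation, sense_tilt,
                                   target_torque)


def tilt(azimuth, magnitude, inclination=None):
    inc = magnitude if inclination is None else inclination
    return TiltSignal(inclination=inc, rate=0.0, azimuth=azimuth,
                      magnitude=magnitude)


class TestSenseTilt:
    def test_upright_reports_zero_and_azimuth_convention(self):
        sig = sense_tilt(np.zeros(8))
        assert sig.inclination == 0.0
        assert sig.magnitude == 0.0
        assert sig.azimuth == 0.0

    def test_forward_tilt_with_growth_combines_rate(self):
        # 2 deg forward inclination growing at 1 deg/s -> m = 2.5 deg
        state = np.zeros(8)
        state[0] = np.deg2rad(1.2)
        state[1] = np.deg2rad(0.8)
        state[4] = np.deg2rad(1.0)
        sig = sense_tilt(state)
        assert sig.azimuth == pytest.approx(0.0)
        assert sig.inclination == pytest.approx(2.0)
        assert sig.magnitude == pytest.approx(2.5)

    def test_pure_rightward_tilt_maps_to_90deg(self):
        state = np.zeros(8)
        state[2] = np.deg2rad(1.5)
        sig = sense_tilt(state)
        assert sig.azimuth == pytest.approx(90.0)

    def test_backward_tilt_maps_to_180deg(self):
        state = np.zeros(8)
        state[0] = -np.deg2rad(1.0)
        assert sense_tilt(state).azimuth == pytest.approx(180.0)


class TestSelectActivation:
    def test_dead_zone_keeps_display_off(self):
        cfg = DisplayConfig.preset("3x4")
        act = select_activation(tilt(azimuth=37.0, magnitude=0.5), cfg)
        assert act.row == 0 and act.column is None

    def test_nearest_neighbor_column(self):
        cfg = DisplayConfig.preset("3x4")
        act = select_activation(tilt(azimuth=10.0, magnitude=1.5), cfg)
        assert act.column == 0.0 and act.row == 1

    def test_1x2_wraps_circularly(self):
        cfg = DisplayConfig.preset("1x2")
        act = select_activation(tilt(azimuth=100.0, magnitude=2.0), cfg)
        assert act.column == 180.0    # circular distance 80 < 100

    def test_midway_tie_prefers_lower_azimuth(self):
        cfg = DisplayConfig.preset("3x4")
        act = select_activation(tilt(azimuth=45.0, magnitude=1.5), cfg)
        assert act.column == 0.0

    def test_rows_step_with_magnitude_and_cap(self):
        cfg = DisplayConfig.preset("3x4")
        for m, row in ((1.0, 1), (1.9, 1), (2.0, 2), (3.5, 3), (50.0, 3)):
            assert select_activation(tilt(0.0, m), cfg).row == row

    def test_empty_display_forces_off(self):
        cfg = DisplayConfig.preset("off")
        act = select_activation(tilt(0.0, 10.0), cfg)
        assert act.row == 0 and act.column is None


class TestTargetTorque:
    def test_display_off_targets_zero(self):
        k_s, k_c = target_torque(TactorActivation(None, 0),
                                 BiofeedbackParams())
        assert np.all(k_s == 0.0) and np.all(k_c == 0.0)

    def test_navel_column_row1_is_pure_sagittal(self):
        p = BiofeedbackParams()
        k_s, k_c = target_torque(TactorActivation(0.0, 1), p)
        assert np.allclose(k_s, p.k_s[0])
        assert np.all(k_c == 0.0)

    def test_left_column_row2_is_pure_negative_coronal(self):
        p = BiofeedbackParams(k_c=np.array([[1.0, 0.5], [2.0, 1.0],
                                            [3.0, 1.5]]))
        k_s, k_c = target_torque(TactorActivation(270.0, 2), p)
        assert np.all(k_s == 0.0)          # cos 270 exactly zero
        assert np.allclose(k_c, -p.k_c[1])

    @given(row=st.integers(1, 3),
           col=st.sampled_from([22.5 * i for i in range(16)]))
    def test_magnitude_monotone_in_row_and_decomposition(self, row, col):
        p = BiofeedbackParams(
            k_s=np.array([[4.0, 1.0], [6.0, 2.0], [8.0, 3.0]]),
            k_c=np.array([[2.0, 0.5], [3.0, 1.0], [4.0, 2.0]]))
        mags = []
        for r in range(1, 4):
            k_s, k_c = target_torque(TactorActivation(col, r), p)
            mags.append(np.hypot(np.linalg.norm(k_s), np.linalg.norm(k_c)))
        assert mags[0] <= mags[1] + 1e-12 <= mags[2] + 2e-12
        # unit decomposition identity at this row
        k_s, k_c = target_torque(TactorActivation(col, row), p)
        lhs = (k_s[0] / p.k_s[row - 1, 0]) ** 2 \
            + (k_c[0] / p.k_c[row - 1, 0]) ** 2
        assert lhs == pytest.approx(1.0)


class TestFeedbackLag:
    def test_step_response_closed_form(self):
        tau, dt = 0.25, 0.001
        target = np.array([6.0, 1.5])
        t_f = np.zeros(2)
        for i in range(round(5 * tau / dt)):
            t_f = advance_feedback_torque(t_f, target, tau, dt)
            t = (i + 1) * dt
            expected = target * (1 - np.exp(-t / tau))
            assert np.allclose(t_f, expected, rtol=1e-9, atol=1e-12)

    def test_fixed_point(self):
        target = np.array([3.0, -1.0])
        out = advance_feedback_torque(target.copy(), target, 0.2, 0.01)
        assert np.allclose(out, target)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            advance_feedback_torque(np.zeros(2), np.zeros(2), 0.0, 0.01)


class TestResolutionDegeneracy:
    def test_shared_column_motions_activate_identically(self):
        # any azimuth within +-11.25 deg of a 3x4 column selects the same
        # column and row in the 3x4 and 3x16 displays
        c4 = DisplayConfig.preset("3x4")
        c16 = DisplayConfig.preset("3x16")
        for base in (0.0, 90.0, 180.0, 270.0):
            for d_az in (-11.0, -5.0, 0.0, 5.0, 11.0):
                for m in (0.4, 1.2, 2.4, 4.0):
                    sig = tilt((base + d_az) % 360.0, m)
                    a4 = select_activation(sig, c4)
                    a16 = select_activation(sig, c16)
                    assert a4 == a16

    def test_off_preset_matches_tactors_off_model(self):
        p = BiofeedbackParams()
        act = select_activation(tilt(12.0, 5.0), DisplayConfig.preset("off"))
        k_s, k_c = target_torque(act, p)
        assert np.all(k_s == 0.0) and np.all(k_c == 0.0)


class TestParamValidation:
    def test_row_ordering_enforced(self):
        with pytest.raises(ValueError):
            BiofeedbackParams(k_s=np.array([[5.0, 0.0], [4.0, 1.0],
                                            [8.0, 2.0]]))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            BiofeedbackParams(tau_f=0.0)
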