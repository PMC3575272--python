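"""Closed-loop simulation orchestration."""

import numpy as np
import pytest

import posturefb as pf
from posturefb.simulation import resample_to_experiment, simulate


class TestEquilibriumAndBookkeeping:
    def test_all_zero_scenario_stays_at_rest(self, body):
        ctrl = pf.ControllerParams(K_s=np.zeros((2, 4)),
                                   K_c=np.zeros((2, 4)), t_d=0.05)
        sc = pf.Scenario(body=body, controller=ctrl,
                         biofeedback=pf.BiofeedbackParams(
                             k_s=np.zeros((3, 2))),
                         display=pf.DisplayConfig.preset("off"),
                         perturbation=pf.PerturbationSpec(displacement=0.0),
                         dt=0.002, horizon=4.0)
        traj = simulate(sc)
        for col in ("ap_sway_deg", "ml_sway_deg", "cop_x_cm", "cop_y_cm",
                    "tj_ankle_s_nm", "tf_ankle_s_nm"):
            assert not np.any(traj.channel(col))

    def test_torque_superposition_identity_exact(self, sim_cache):
        traj = sim_cache(225.0, "3x4")
        for plane in ("s", "c"):
            for joint in ("ankle", "hip"):
                tj = traj.channel(f"tj_{joint}_{plane}_nm")
                tpc = traj.channel(f"tpc_{joint}_{plane}_nm")
                tf = traj.channel(f"tf_{joint}_{plane}_nm")
                assert np.max(np.abs(tj - (tpc + tf))) == 0.0

    def test_determinism_bit_identical(self, body, demo_ctrl):
        sc = pf.Scenario(body=body, controller=demo_ctrl,
                         display=pf.DisplayConfig.preset("3x4"),
                         perturbation=pf.PerturbationSpec(direction=225.0),
                         dt=0.005)
        t1 = simulate(sc)
        t2 = simulate(sc)
        assert t1.data.equals(t2.data)


class TestUnidirectionalResponse:
    def test_backward_perturbation_is_sagittal_only(self, sim_cache):
        traj = sim_cache(180.0, "3x4")
        assert np.max(np.abs(traj.channel("ml_sway_deg"))) <= 1e-12
        assert np.max(np.abs(traj.channel("cop_y_cm"))) <= 1e-12
        assert np.abs(traj.channel("ap_sway_deg")).max() > 0.5

    def test_rightward_perturbation_is_coronal_only(self, sim_cache):
        traj = sim_cache(90.0, "3x4")
        assert np.max(np.abs(traj.channel("ap_sway_deg"))) <= 1e-12
        assert np.max(np.abs(traj.channel("cop_x_cm"))) <= 1e-12
        assert np.abs(traj.channel("ml_sway_deg")).max() > 0.2


class TestBiofeedbackEffect:
    def test_corrective_3x4_does_not_increase_peak_ap_sway(self, sim_cache):
        off = sim_cache(180.0, "off")
        on = sim_cache(180.0, "3x4")
        peak_off = np.abs(off.channel("ap_sway_deg")).max()
        peak_on = np.abs(on.channel("ap_sway_deg")).max()
        assert peak_on <= peak_off

    def test_display_off_and_on_agree_until_first_activation(self, sim_cache):
        off = sim_cache(180.0, "off")
        on = sim_cache(180.0, "3x4")
        rows = on.channel("tactor_row")
        first = int(np.argmax(rows > 0))
        assert rows[first] > 0
        a_off = off.channel("ap_sway_deg")
        a_on = on.channel("ap_sway_deg")
        assert np.array_equal(a_off[:first + 1], a_on[:first + 1])
        assert np.any(a_off[first + 1:] != a_on[first + 1:])


class TestFallDetection:
    def test_toppling_run_raises(self, body):
        ctrl = pf.ControllerParams(K_s=np.zeros((2, 4)),
                                   K_c=np.zeros((2, 4)), t_d=0.0)
        sc = pf.Scenario(body=body, controller=ctrl,
                         display=pf.DisplayConfig.preset("off"),
                         perturbation=pf.PerturbationSpec(displacement=0.0),
                         dt=0.002, horizon=5.0,
                         initial_state=(0.3, 0.2, 0, 0, 0, 0, 0, 0))
        with pytest.raises(pf.SimulationFallError):
            simulate(sc)


class TestResampling:
    def test_integer_decimation_keeps_samples(self, sim_cache):
        traj = sim_cache(180.0, "off")            # dt = 2 ms
        dec = resample_to_experiment(traj, 100.0)  # keep every 5th
        assert dec.dt == pytest.approx(0.01)
        assert np.array_equal(dec.channel("ap_sway_deg"),
                              traj.channel("ap_sway_deg")[::5])

    def test_constant_channel_preserved_exactly(self, sim_cache):
        traj = sim_cache(180.0, "off")
        dec = resample_to_experiment(traj, 100.0)
        assert np.all(dec.channel("ml_sway_deg") == 0.0)

    def test_band_limited_sine_is_exact_at_kept_samples(self, sim_cache):
        traj = sim_cache(180.0, "off")
        df = traj.data.copy()
        df["ap_sway_deg"] = np.sin(2 * np.pi * 2.0 * df["t_s"])
        synthetic = pf.Trajectory(df, traj.dt)
        dec = resample_to_experiment(synthetic, 100.0)
        expected = np.sin(2 * np.pi * 2.0 * dec.t)
        assert np.allclose(dec.channel("ap_sway_deg"), expected, atol=1e-9)

    def test_upsampling_rejected(self, sim_cache):
        with pytest.raises(ValueError):
            resample_to_experiment(sim_cache(180.0, "off"), 1000.0)


class TestScenarioValidation:
    def test_short_horizon_rejected(self, body, demo_ctrl):
        with pytest.raises(ValueError):
            pf.Scenario(body=body, controller=demo_ctrl, horizon=2.0)

    def test_dt_refinement_convergence(self, body, demo_ctrl):
        # halving dt from the 1-ms default changes the sway by a tiny RMS
        kw = dict(body=body, controller=demo_ctrl,
                  display=pf.DisplayConfig.preset("off"),
                  perturbation=pf.PerturbationSpec(direction=180.0))
        t1 = simulate(pf.Scenario(dt=0.001, **kw))
        t2 = simulate(pf.Scenario(dt=0.0005, **kw))
        a1 = resample_to_experiment(t1, 100.0).channel("ap_sway_deg")
        a2 = resample_to_experiment(t2, 100.0).channel("ap_sway_deg")
        rms = np.sqrt(np.mean((a1 - a2) ** 2))
        assert rms < 1e-4
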