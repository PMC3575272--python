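"""Fitting objective, sweep, perpendicular search and sensitivity."""

import numpy as np
import pytest
from dataclasses import replace

import posturefb as pf
from posturefb.fitting import (FitProblem, parameter_sweep,
                               perpendicular_search, rotating_search,
                               sensitivity_screen, set_params, get_param)
from posturefb.fixtures import demo_controller
from posturefb.simulation import Trajectory, resample_to_experiment, simulate


class _AnalyticProblem:
    """Duck-typed stand-in exposing the optimizer-facing surface."""

    def __init__(self, fn, n):
        self.fn = fn
        self.free = [f"p{i}" for i in range(n)]
        self.bounds = {}
        self.n_evals = 0
        self.diagnostics = []

    def objective(self, x):
        self.n_evals += 1
        return float(self.fn(np.asarray(x, float)))

    def project(self, x):
        return np.array(x, float)

    def x0(self):
        return np.zeros(len(self.free))


@pytest.fixture(scope="module")
def gain_problem(body):
    """A small real fit problem: 180-deg reference from known gains."""
    truth = demo_controller(body, sagittal_scale=1.1)
    sc_truth = pf.Scenario(body=body, controller=truth,
                           display=pf.DisplayConfig.preset("off"),
                           perturbation=pf.PerturbationSpec(direction=180.0),
                           dt=0.01)
    ref = resample_to_experiment(simulate(sc_truth), 100.0)
    template = replace(sc_truth, controller=demo_controller(body))
    free = [f"controller.K_s[{i},{j}]" for i in range(2) for j in range(4)]
    return FitProblem(scenarios={180.0: template},
                      references={180.0: ref}, free=free), ref, truth


class TestParameterPaths:
    def test_get_set_roundtrip(self, body):
        sc = pf.Scenario(body=body, controller=demo_controller(body))
        sc2 = set_params(sc, {"controller.K_s[0,1]": 123.0,
                              "biofeedback.tau_f": 0.4})
        assert get_param(sc2, "controller.K_s[0,1]") == 123.0
        assert get_param(sc2, "biofeedback.tau_f") == 0.4
        # the original scenario is untouched
        assert get_param(sc, "biofeedback.tau_f") == 0.25

    def test_malformed_path_rejected(self, body):
        sc = pf.Scenario(body=body, controller=demo_controller(body))
        with pytest.raises(ValueError):
            set_params(sc, {"controller.K_s[0]": 1.0})


class TestObjective:
    def test_generating_parameters_give_zero(self, gain_problem):
        prob, _, _ = gain_problem
        assert prob.objective(prob.x0() * 1.1) == 0.0

    def test_start_parameters_give_positive(self, gain_problem):
        prob, _, _ = gain_problem
        assert prob.objective(prob.x0()) > 1e-4

    def test_excluded_ap_channel_ignored_for_90deg(self, body):
        ctrl = demo_controller(body)
        sc = pf.Scenario(body=body, controller=ctrl,
                         display=pf.DisplayConfig.preset("off"),
                         perturbation=pf.PerturbationSpec(direction=90.0),
                         dt=0.01)
        ref = resample_to_experiment(simulate(sc), 100.0)
        free = ["controller.K_c[0,0]"]
        p1 = FitProblem(scenarios={90.0: sc}, references={90.0: ref},
                        free=free)
        x = p1.x0() * 1.05
        j1 = p1.objective(x)
        # corrupt the AP sway channel of the reference: excluded, so J
        # must not change
        df = ref.data.copy()
        df["ap_sway_deg"] = 99.0
        ref2 = Trajectory(df, ref.dt)
        p2 = FitProblem(scenarios={90.0: sc}, references={90.0: ref2},
                        free=free)
        assert p2.objective(x) == j1

    def test_single_channel_closed_form(self, gain_problem, monkeypatch):
        # sim identically zero, triangular reference on one channel:
        # J = integral (exp/max)^2 dt
        prob, ref, _ = gain_problem
        zero = Trajectory(ref.data.assign(
            **{c: 0.0 for c in ("ap_sway_deg", "ml_sway_deg",
                                "cop_x_cm", "cop_y_cm")}), ref.dt)
        tri = ref.data.copy()
        onset = 0.5
        tt = tri["t_s"].to_numpy()
        tri["ap_sway_deg"] = np.maximum(0.0, 1.0 - np.abs(tt - onset - 1.5))
        tri["cop_x_cm"] = 0.0
        ref_tri = Trajectory(tri, ref.dt)
        p = FitProblem(scenarios=prob.scenarios,
                       references={180.0: ref_tri}, free=prob.free)
        monkeypatch.setattr(FitProblem, "simulate_candidate",
                            lambda self, x, d: zero)
        got = p.objective(p.x0())
        # integral of the unit triangle squared over [0.5, 3.5]:
        # 2 * int_0^1 u^2 du = 2/3 (max value is 1)
        assert got == pytest.approx(2.0 / 3.0, rel=2e-2)

    def test_residuals_square_to_objective(self, gain_problem):
        prob, _, _ = gain_problem
        x = prob.x0() * 1.03
        r = prob.residual_vector(x)
        assert float(r @ r) == pytest.approx(prob.objective(x), rel=1e-12)


class TestParameterSweep:
    def test_singleton_grid(self):
        p = _AnalyticProblem(lambda x: (x[0] - 3) ** 2, 1)
        x, j, table = parameter_sweep(p, {"p0": [5.0]})
        assert x[0] == 5.0 and j == 4.0 and len(table) == 1

    def test_grid_containing_truth_wins(self):
        p = _AnalyticProblem(lambda x: (x[0] - 1) ** 2 + (x[1] + 2) ** 2, 2)
        x, j, _ = parameter_sweep(p, {"p0": [0.0, 1.0, 2.0],
                                      "p1": [-2.0, 0.0]})
        assert np.allclose(x, [1.0, -2.0]) and j == 0.0

    def test_convex_slice_brackets_minimum(self):
        p = _AnalyticProblem(lambda x: (x[0] - 0.7) ** 2, 1)
        levels = [-1.0, 0.0, 1.0, 2.0]
        x, _, table = parameter_sweep(p, {"p0": levels})
        assert x[0] == 1.0          # closest grid point to 0.7
        assert len(table) == 4

    def test_empty_grid_rejected(self):
        p = _AnalyticProblem(lambda x: 0.0, 1)
        with pytest.raises(ValueError):
            parameter_sweep(p, {})


class TestPerpendicularSearch:
    def test_optimal_start_terminates_without_moves(self):
        p = _AnalyticProblem(lambda x: x @ x, 3)
        res = perpendicular_search(p, np.zeros(3), initial_step=0.5,
                                   step_tol=1e-3, max_cycles=50)
        assert res.objective == 0.0
        assert len(res.trace) == 1          # no accepted moves

    def test_separable_quadratic_recovered(self):
        target = np.array([1.5, -2.0, 0.25])
        p = _AnalyticProblem(lambda x: np.sum((x - target) ** 2), 3)
        res = perpendicular_search(p, np.zeros(3), initial_step=1.0,
                                   step_tol=1e-6, max_cycles=200)
        assert np.allclose(res.x, target, atol=1e-4)

    def test_monotone_descent_trace(self):
        p = _AnalyticProblem(
            lambda x: (x[0] - 1) ** 2 + 10 * (x[1] - x[0]) ** 2, 2)
        res = perpendicular_search(p, np.array([3.0, -3.0]),
                                   initial_step=0.7, step_tol=1e-6,
                                   max_cycles=300)
        js = res.trace["J"].to_numpy()
        assert np.all(np.diff(js) <= 0)
        assert res.objective < 1e-6

    def test_rotating_variant_handles_valleys(self):
        # Rosenbrock banana: coordinate schemes crawl, rotation succeeds
        p = _AnalyticProblem(
            lambda x: (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2, 2)
        res = rotating_search(p, np.array([-1.2, 1.0]), initial_step=0.2,
                              step_tol=1e-10, max_evals=4000)
        assert res.objective < 1e-4


class TestSensitivity:
    def test_decoupled_parameter_has_zero_sensitivity(self, body):
        # a coronal gain cannot influence a pure sagittal perturbation
        ctrl = demo_controller(body)
        sc = pf.Scenario(body=body, controller=ctrl,
                         display=pf.DisplayConfig.preset("off"),
                         perturbation=pf.PerturbationSpec(direction=180.0),
                         dt=0.01)
        ref = resample_to_experiment(simulate(sc), 100.0)
        prob = FitProblem(scenarios={180.0: sc}, references={180.0: ref},
                          free=["controller.K_c[0,0]",
                                "controller.K_s[0,0]"])
        scr = sensitivity_screen(prob, prob.x0() * 1.02)
        by_name = dict(zip(scr["parameter"], scr["abs_delta_J"]))
        assert by_name["controller.K_c[0,0]"] == 0.0
        assert by_name["controller.K_s[0,0]"] > 0.0
        assert scr["parameter"].iloc[0] == "controller.K_s[0,0]"

    def test_linear_slice_sensitivity_proportional_to_delta(self):
        p = _AnalyticProblem(lambda x: 2.0 * x[0] + 7.0, 1)
        s1 = sensitivity_screen(p, np.array([0.0]), deltas=np.array([0.1]))
        s2 = sensitivity_screen(p, np.array([0.0]), deltas=np.array([0.2]))
        assert s2["delta_J"].iloc[0] == pytest.approx(
            2 * s1["delta_J"].iloc[0])

    def test_ranking_invariant_to_uniform_delta_scaling(self):
        p = _AnalyticProblem(lambda x: 4 * x[0] ** 2 + x[1] ** 2
                             + 0.1 * x[2] ** 2, 3)
        base = np.array([1.0, 1.0, 1.0])
        r1 = sensitivity_screen(p, base, deltas=0.1)["parameter"].tolist()
        r2 = sensitivity_screen(p, base, deltas=0.05)["parameter"].tolist()
        assert r1 == r2
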