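"""Closed-loop simulation: plant + delayed controllers + biofeedback.

A single fixed-step grid (RK4, default dt = 1 ms) is shared by the
plant, the controller delay buffer and the biofeedback lag.  Per step:

    read delayed state -> controller torque -> sense tilt -> tactor
    activation -> target torque -> advance feedback lag -> sum torques
    -> plant RK4 step.

The device logic (tilt sensing, activation, target selection) runs once
per grid sample and is held over the step; the continuous parts of the
loop are evaluated at the Runge-Kutta stage times — the delayed state by
linear interpolation in the history buffer, the biofeedback lag by its
exact exponential solution within the step — so the closed-loop
integration converges under dt refinement instead of being limited by a
zero-order hold on the torques.

Outputs are collected into a :class:`Trajectory`: sway (torso
inclination components, deg), COP (cm), torque channels split into
controller and biofeedback parts, platform motion and tactor activation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import BodyParams, SubjectSpec, derive_body_params
from .biofeedback import (BiofeedbackParams, DisplayConfig,
                          FeedbackTorqueState, advance_feedback_torque,
                          select_activation, sense_tilt, target_torque)
from .controller import ControllerParams, StateHistory, control_torque
from .dynamics import DynamicsEngine, ModelValidityError
from .perturbation import PerturbationSpec, TrapezoidProfile

__all__ = ["Scenario", "Trajectory", "SimulationFallError", "simulate",
           "resample_to_experiment", "TRAJECTORY_COLUMNS"]

STATE_COLUMNS = ["ankle_s_rad", "hip_s_rad", "ankle_c_rad", "hip_c_rad",
                 "dankle_s_rads", "dhip_s_rads", "dankle_c_rads",
                 "dhip_c_rads"]

TRAJECTORY_COLUMNS = (
    ["t_s", "ap_sway_deg", "ml_sway_deg", "cop_x_cm", "cop_y_cm"]
    + STATE_COLUMNS
    + ["tpc_ankle_s_nm", "tpc_hip_s_nm", "tpc_ankle_c_nm", "tpc_hip_c_nm",
       "tf_ankle_s_nm", "tf_hip_s_nm", "tf_ankle_c_nm", "tf_hip_c_nm",
       "tj_ankle_s_nm", "tj_hip_s_nm", "tj_ankle_c_nm", "tj_hip_c_nm",
       "plat_x_m", "plat_y_m", "plat_vx_ms", "plat_vy_ms",
       "plat_ax_ms2", "plat_ay_ms2", "tactor_col_deg", "tactor_row"])


class SimulationFallError(RuntimeError):
    """A joint angle exceeded the fall threshold during simulation."""


@dataclass(frozen=True)
class Scenario:
    """Everything needed for one closed-loop run."""
    body: BodyParams
    controller: ControllerParams
    biofeedback: BiofeedbackParams = field(default_factory=BiofeedbackParams)
    display: DisplayConfig = field(
        default_factory=lambda: DisplayConfig.preset("off"))
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    dt: float = 0.001
    horizon: float | None = None
    initial_state: tuple[float, ...] = (0.0,) * 8
    seed: int | None = None      # used only by the fixture noise model
    subject: SubjectSpec | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon is None:
            object.__setattr__(self, "horizon",
                               self.perturbation.end + 3.0)
        if self.horizon < self.perturbation.end + 3.0 - 1e-12:
            raise ValueError("horizon must cover perturbation end + 3 s")
        if len(self.initial_state) != 8:
            raise ValueError("initial state must have 8 entries")

    @classmethod
    def from_subject(cls, subject: SubjectSpec, controller: ControllerParams,
                     fractions: dict | None = None, **kw) -> "Scenario":
        body = derive_body_params(subject, fractions)
        return cls(body=body, controller=controller, subject=subject, **kw)


@dataclass
class Trajectory:
    """Uniform time series of every simulation channel (see
    ``TRAJECTORY_COLUMNS``); thin wrapper over a DataFrame."""
    data: pd.DataFrame
    dt: float

    def __post_init__(self):
        missing = set(TRAJECTORY_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory missing columns: {sorted(missing)}")

    @property
    def t(self) -> np.ndarray:
        return self.data["t_s"].to_numpy()

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def window(self, start: float, duration: float) -> "Trajectory":
        """Sub-trajectory covering [start, start + duration], inclusive."""
        t = self.t
        m = (t >= start - 1e-9) & (t <= start + duration + 1e-9)
        return Trajectory(self.data.loc[m].reset_index(drop=True), self.dt)


FALL_LIMIT = math.pi / 2


def simulate(scenario: Scenario) -> Trajectory:
    """Run one closed-loop simulation and record every channel.

    Raises :class:`SimulationFallError` if any joint angle leaves
    (-pi/2, pi/2), and propagates :class:`ModelValidityError` if the
    vertical ground reaction becomes non-positive.
    """
    sc = scenario
    engine = DynamicsEngine(sc.body)
    profile = TrapezoidProfile(sc.perturbation, sc.dt)
    dt = sc.dt
    n = round(sc.horizon / dt) + 1

    state = np.array(sc.initial_state, float)
    depth = max(1, round(sc.controller.t_d / dt)) + 3
    history = StateHistory(dt, depth, state)
    fb = FeedbackTorqueState()

    rows = np.empty((n, len(TRAJECTORY_COLUMNS)))
    col_index = {c: i for i, c in enumerate(TRAJECTORY_COLUMNS)}

    K_s, K_c = sc.controller.K_s, sc.controller.K_c
    t_d = sc.controller.t_d
    tau = sc.biofeedback.tau_f
    delayed_by_steps = round(t_d / dt) >= 1

    for i in range(n):
        t = i * dt
        if np.max(np.abs(state[:4])) > FALL_LIMIT:
            raise SimulationFallError(
                f"fall detected at t = {t:.3f} s "
                f"(joint angle beyond ±{FALL_LIMIT:.2f} rad)")

        t_pc_s, t_pc_c = control_torque(history, t, sc.controller)
        tilt = sense_tilt(state)
        act = select_activation(tilt, sc.display)
        k_f_s, k_f_c = target_torque(act, sc.biofeedback)
        # the device's corrective demand is applied with a restoring
        # sign in the generalized-torque convention
        tgt_s, tgt_c = -k_f_s, -k_f_c
        tf_s0, tf_c0 = fb.t_f_s, fb.t_f_c
        fb.t_f_s = advance_feedback_torque(tf_s0, tgt_s, tau, dt)
        fb.t_f_c = advance_feedback_torque(tf_c0, tgt_c, tau, dt)
        fb.k_f_s, fb.k_f_c = tgt_s, tgt_c

        def loop_torques(ts: float, x_stage: np.ndarray) -> np.ndarray:
            """Generalized torques at a stage time within [t, t+dt]."""
            if delayed_by_steps:
                xd = history.interp(ts - t_d)
            else:
                xd = x_stage
            pc_s = -K_s @ xd[[0, 1, 4, 5]]
            pc_c = -K_c @ xd[[2, 3, 6, 7]]
            decay = np.exp(-(ts - t) / tau)
            f_s = tgt_s + (tf_s0 - tgt_s) * decay
            f_c = tgt_c + (tf_c0 - tgt_c) * decay
            return np.array([pc_s[0] + f_s[0], pc_s[1] + f_s[1],
                             pc_c[0] + f_c[0], pc_c[1] + f_c[1]])

        torques = np.array([t_pc_s[0] + tf_s0[0], t_pc_s[1] + tf_s0[1],
                            t_pc_c[0] + tf_c0[0], t_pc_c[1] + tf_c0[1]])

        a_now = profile.accel(t)
        deriv = engine.rhs(state, torques, a_now)
        cop = engine.center_of_pressure(state, deriv[4:], a_now)

        r = rows[i]
        r[col_index["t_s"]] = t
        r[col_index["ap_sway_deg"]] = np.rad2deg(state[0] + state[1])
        r[col_index["ml_sway_deg"]] = np.rad2deg(state[2] + state[3])
        r[col_index["cop_x_cm"]] = cop[0] * 100.0
        r[col_index["cop_y_cm"]] = cop[1] * 100.0
        for j, c in enumerate(STATE_COLUMNS):
            r[col_index[c]] = state[j]
        r[col_index["tpc_ankle_s_nm"]] = t_pc_s[0]
        r[col_index["tpc_hip_s_nm"]] = t_pc_s[1]
        r[col_index["tpc_ankle_c_nm"]] = t_pc_c[0]
        r[col_index["tpc_hip_c_nm"]] = t_pc_c[1]
        r[col_index["tf_ankle_s_nm"]] = tf_s0[0]
        r[col_index["tf_hip_s_nm"]] = tf_s0[1]
        r[col_index["tf_ankle_c_nm"]] = tf_c0[0]
        r[col_index["tf_hip_c_nm"]] = tf_c0[1]
        r[col_index["tj_ankle_s_nm"]] = t_pc_s[0] + tf_s0[0]
        r[col_index["tj_hip_s_nm"]] = t_pc_s[1] + tf_s0[1]
        r[col_index["tj_ankle_c_nm"]] = t_pc_c[0] + tf_c0[0]
        r[col_index["tj_hip_c_nm"]] = t_pc_c[1] + tf_c0[1]
        pos, vel = profile.pos(t), profile.vel(t)
        r[col_index["plat_x_m"]] = pos[0]
        r[col_index["plat_y_m"]] = pos[1]
        r[col_index["plat_vx_ms"]] = vel[0]
        r[col_index["plat_vy_ms"]] = vel[1]
        r[col_index["plat_ax_ms2"]] = a_now[0]
        r[col_index["plat_ay_ms2"]] = a_now[1]
        r[col_index["tactor_col_deg"]] = (np.nan if act.column is None
                                          else act.column)
        r[col_index["tactor_row"]] = act.row

        if i == n - 1:
            break

        # RK4 with delayed feedback, feedback lag and platform
        # acceleration all evaluated at the stage times
        a_mid = profile.accel(t + dt / 2)
        a_end = profile.accel(t + dt, left=True)
        k1 = deriv
        x2 = state + dt / 2 * k1
        k2 = engine.rhs(x2, loop_torques(t + dt / 2, x2), a_mid)
        x3 = state + dt / 2 * k2
        k3 = engine.rhs(x3, loop_torques(t + dt / 2, x3), a_mid)
        x4 = state + dt * k3
        k4 = engine.rhs(x4, loop_torques(t + dt, x4), a_end)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        # k4 approximates the derivative at t+dt to the step's accuracy;
        # it seeds the Hermite dense output of the delay buffer
        history.push(t + dt, state, k4)

    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return Trajectory(df, dt)


def resample_to_experiment(traj: Trajectory, rate: float = 100.0) -> Trajectory:
    """Decimate a simulation trajectory to the experimental sample rate.

    The target rate must divide the simulation rate evenly (samples are
    kept, never interpolated, so channel values are unchanged).
    """
    if rate > traj.rate + 1e-9:
        raise ValueError("target rate exceeds the simulation rate")
    step = (1.0 / rate) / traj.dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError("target rate must divide the simulation rate evenly")
    step = round(step)
    df = traj.data.iloc[::step].reset_index(drop=True)
    return Trajectory(df, traj.dt * step)
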