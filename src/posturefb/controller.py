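"""Delayed full-state-feedback postural controllers.

Two independent linear controllers, one per plane, each computing

    T_PC(t) = -K x(t - t_d)

with K a 2x4 gain matrix (rows: ankle, hip torque; columns: ankle angle,
hip angle, ankle rate, hip rate) and t_d a sensorimotor delay.  Feedback
is noise-free; there is no estimator, predictor or sensory-integration
stage.  The delay is realised with a ring buffer on the fixed
integration grid and rounded to a whole number of steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["ControllerParams", "StateHistory", "control_torque", "lqr_gains"]


@dataclass(frozen=True)
class ControllerParams:
    """Per-plane 2x4 gain matrices and the shared feedback delay (s).

    The default delay is 0.05 s.  Static delayed-state feedback (no
    predictor) can stabilize this two-link plant only up to a delay of
    about 0.07 s: the minimum stabilizing ankle stiffness is set by
    gravity (~mgh) and the fast unstable coupled mode sits near
    9.4 rad/s, so longer physiological latencies would require the
    predictive elements this model deliberately omits.
    """
    K_s: np.ndarray
    K_c: np.ndarray
    t_d: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "K_s", np.asarray(self.K_s, float))
        object.__setattr__(self, "K_c", np.asarray(self.K_c, float))
        if self.K_s.shape != (2, 4) or self.K_c.shape != (2, 4):
            raise ValueError("gain matrices must be 2x4")
        if not (np.isfinite(self.K_s).all() and np.isfinite(self.K_c).all()):
            raise ValueError("gains must be finite")
        if self.t_d < 0:
            raise ValueError("feedback delay must be >= 0")


class StateHistory:
    """Ring buffer of full 8-states on the integration grid.

    The buffer is pre-filled with the initial state, so lookups earlier
    than the first sample return that state (upright start => zero torque
    until real history accumulates).
    """

    def __init__(self, dt: float, depth: int, initial_state: np.ndarray):
        if dt <= 0 or depth < 1:
            raise ValueError("need dt > 0 and depth >= 1")
        self.dt = dt
        self.depth = depth
        self._buf = np.tile(np.asarray(initial_state, float), (depth, 1))
        # pre-fill derivative as zero: the history before t = 0 is the
        # initial state held constant
        self._dbuf = np.zeros_like(self._buf)
        self._head = 0          # index of the most recent sample
        self._t_head = 0.0      # time of the most recent sample

    def push(self, t: float, state: np.ndarray,
             deriv: np.ndarray | None = None) -> None:
        self._head = (self._head + 1) % self.depth
        self._buf[self._head] = state
        self._dbuf[self._head] = 0.0 if deriv is None else deriv
        self._t_head = t

    def lookup(self, t: float) -> np.ndarray:
        """State at time ``t``, rounded to the nearest grid sample."""
        steps_back = round((self._t_head - t) / self.dt)
        if steps_back < 0:
            raise ValueError("lookup ahead of the newest sample")
        if steps_back >= self.depth:
            raise ValueError("lookup beyond the buffer depth; increase depth")
        return self._buf[(self._head - steps_back) % self.depth].copy()

    def interp(self, t: float) -> np.ndarray:
        """State at time ``t``, cubic-Hermite interpolated between samples.

        Used by the integrator to evaluate the delayed feedback at
        Runge-Kutta stage times that fall between grid samples (dense
        output of the method of steps); lookups before the oldest stored
        sample clamp to it.
        """
        back = (self._t_head - t) / self.dt
        if back < -1e-9:
            raise ValueError("interp ahead of the newest sample")
        back = min(max(back, 0.0), self.depth - 1.0)
        lo = int(np.floor(back))
        frac = back - lo
        ia = (self._head - lo) % self.depth          # later sample
        if frac < 1e-12:
            return self._buf[ia].copy()
        ib = (self._head - lo - 1) % self.depth      # earlier sample
        s = 1.0 - frac                               # fraction from b to a
        s2, s3 = s * s, s * s * s
        h = self.dt
        return ((2 * s3 - 3 * s2 + 1) * self._buf[ib]
                + (s3 - 2 * s2 + s) * h * self._dbuf[ib]
                + (-2 * s3 + 3 * s2) * self._buf[ia]
                + (s3 - s2) * h * self._dbuf[ia])


def control_torque(history: StateHistory, t: float,
                   params: ControllerParams) -> tuple[np.ndarray, np.ndarray]:
    """(T_PC^S, T_PC^C) ankle/hip torque pairs at time ``t``.

    Each plane is computed independently from the delayed per-plane state
    [angle_a, angle_h, rate_a, rate_h].
    """
    x = history.lookup(t - params.t_d)
    x_s = x[[0, 1, 4, 5]]
    x_c = x[[2, 3, 6, 7]]
    return -params.K_s @ x_s, -params.K_c @ x_c


def lqr_gains(A: np.ndarray, B: np.ndarray, Q: np.ndarray,
              R: np.ndarray) -> np.ndarray:
    """Continuous-time LQR gain K (T = -K x) for one plane.

    Plumbing for demo/fixture defaults; fitted gains replace these.
    """
    P = scipy.linalg.solve_continuous_are(A, B, Q, R)
    return np.linalg.solve(R, B.T @ P)
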