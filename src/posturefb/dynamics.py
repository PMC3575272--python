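"""Nonlinear two-link stance dynamics on a translating platform.

State ordering used throughout the package (8 states):

    [alpha_a^S, alpha_h^S, alpha_a^C, alpha_h^C,
     dalpha_a^S, dalpha_h^S, dalpha_a^C, dalpha_h^C]

with S = sagittal (pitch, positive forward) and C = coronal (roll,
positive rightward); a = ankle, h = hip.  Applied generalized torques are
ordered [T_a^S, T_h^S, T_a^C, T_h^C] and are conjugate to the joint
angles: a positive sagittal torque accelerates the joint angle forward.

Joints are ideal (no passive stiffness or damping); the only horizontal
coupling to the world is the prescribed platform acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._symbolics import derive
from .anthropometry import BodyParams

__all__ = ["TorqueSet", "DynamicsEngine", "ModelValidityError",
           "SAGITTAL", "CORONAL"]

G = 9.81

#: index slices of the per-plane 4-state [angle_a, angle_h, rate_a, rate_h]
SAGITTAL = np.array([0, 1, 4, 5])
CORONAL = np.array([2, 3, 6, 7])


class ModelValidityError(RuntimeError):
    """The simulated state left the model's domain of validity."""


@dataclass
class TorqueSet:
    """Per-plane ankle/hip torques, split into postural-controller and
    biofeedback contributions; the applied torque is their sum."""
    t_pc_s: np.ndarray
    t_pc_c: np.ndarray
    t_f_s: np.ndarray
    t_f_c: np.ndarray

    @classmethod
    def zero(cls) -> "TorqueSet":
        return cls(*(np.zeros(2) for _ in range(4)))

    @property
    def t_j_s(self) -> np.ndarray:
        return self.t_pc_s + self.t_f_s

    @property
    def t_j_c(self) -> np.ndarray:
        return self.t_pc_c + self.t_f_c

    def generalized(self) -> np.ndarray:
        """[T_a^S, T_h^S, T_a^C, T_h^C] applied to the plant."""
        tjs, tjc = self.t_j_s, self.t_j_c
        return np.array([tjs[0], tjs[1], tjc[0], tjc[1]])


class DynamicsEngine:
    """Numeric plant bound to one set of :class:`BodyParams`.

    Wraps the lambdified symbolic derivation; all public methods take and
    return plain numpy arrays in the package state ordering.
    """

    def __init__(self, params: BodyParams, g: float = G):
        params.validate()
        self.params = params
        self.g = g
        self._p = params.as_tuple(g)
        self._f = derive()

    # -- core dynamics -------------------------------------------------

    def rhs(self, state: np.ndarray, torques: np.ndarray,
            platform_accel: np.ndarray) -> np.ndarray:
        """State derivative of the full nonlinear 4-DOF plant.

        ``torques`` is the generalized 4-vector, ``platform_accel`` the
        horizontal (ax, ay) base acceleration in m/s^2.
        """
        q = state[:4]
        u = state[4:]
        mf = self._f["dyn_terms"](*q, *u, platform_accel[0],
                                  platform_accel[1], *self._p)
        M = np.array(mf[:16]).reshape(4, 4)
        f = np.array(mf[16:]) + torques
        qdd = np.linalg.solve(M, f)
        return np.concatenate([u, qdd])

    def accelerations(self, state, torques, platform_accel) -> np.ndarray:
        return self.rhs(state, torques, platform_accel)[4:]

    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        return np.array(self._f["mass_matrix"](*q, *self._p))

    def energy(self, state: np.ndarray) -> float:
        """Total mechanical energy (kinetic + potential) for a stationary
        platform; conserved for the passive unforced pendulum."""
        return float(self._f["energy"](*state[:4], *state[4:], *self._p))

    # -- linearization -------------------------------------------------

    def linearize(self) -> tuple[np.ndarray, np.ndarray]:
        """Linear state-space (A, B) about the upright equilibrium.

        x = 8 states as ordered above, u = 4 generalized torques;
        dx/dt = A x + B u.  The Jacobians of the forcing are evaluated
        symbolically, not by finite differences.
        """
        z = np.zeros(4)
        M0 = self.mass_matrix(z)
        Minv = np.linalg.inv(M0)
        fq = np.array(self._f["forcing_jac_q"](*z, *z, 0.0, 0.0, *self._p))
        fu = np.array(self._f["forcing_jac_u"](*z, *z, 0.0, 0.0, *self._p))
        A = np.zeros((8, 8))
        A[:4, 4:] = np.eye(4)
        A[4:, :4] = Minv @ fq
        A[4:, 4:] = Minv @ fu
        B = np.zeros((8, 4))
        B[4:, :] = Minv
        return A, B

    def plane_linearization(self, plane: str) -> tuple[np.ndarray, np.ndarray]:
        """4-state/2-input (A, B) of one decoupled plane ('S' or 'C')."""
        A, B = self.linearize()
        idx = SAGITTAL if plane == "S" else CORONAL
        cols = [0, 1] if plane == "S" else [2, 3]
        return A[np.ix_(idx, idx)], B[np.ix_(idx, cols)]

    # -- ground reaction / center of pressure --------------------------

    def reaction_wrench(self, state, qdd, platform_accel):
        """(F, M): force and moment the platform exerts on the body about
        the ankle point, platform frame."""
        w = self._f["reaction"](*state[:4], *state[4:], *qdd,
                                platform_accel[0], platform_accel[1],
                                *self._p)
        return np.array(w[:3]), np.array(w[3:])

    def center_of_pressure(self, state, qdd, platform_accel) -> np.ndarray:
        """(COP_x, COP_y) in m, platform frame, ankle at the origin.

        The COP is the point on the support surface where the
        ground-reaction wrench has no horizontal moment components:
        x = -M_y / F_z, y = M_x / F_z, with F_z the instantaneous
        vertical reaction (weight plus link inertial loads).
        """
        F, M = self.reaction_wrench(state, qdd, platform_accel)
        if F[2] <= 0:
            raise ModelValidityError(
                f"vertical ground reaction {F[2]:.1f} N <= 0 (airborne)")
        off = self.params.ankle_offset
        # transfer the ankle moment down to the platform surface if the
        # ankle sits above it: M_surface = M + (off z) x F
        mx = M[0] + off * (-F[1])
        my = M[1] + off * F[0]
        return np.array([-my / F[2], mx / F[2]])
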