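"""Symbolic derivation of the two-link 3D inverted-pendulum dynamics.

The body is modelled as two rigid links — legs (ankle to hip) and
torso+head (hip up) — attached to a horizontally translating platform
through an ideal 2-DOF ankle joint; the hip is likewise a 2-DOF joint
(pitch + roll, axial yaw locked).  Generalized coordinates, in order:

    q0 = ankle pitch  (sagittal, positive forward)
    q1 = hip   pitch  (sagittal, relative to legs, positive forward)
    q2 = ankle roll   (coronal,  positive rightward)
    q3 = hip   roll   (coronal,  relative to legs, positive rightward)

Axes: x forward, y rightward, z up (right-handed).  A positive pitch is a
rotation about +y; a positive (rightward) roll is a rotation about -x.

The equations of motion are derived once, symbolically, from the
Lagrangian written in a frame translating with the platform; the base
excitation then enters as the generalized force of the horizontal
pseudo-force -m*a_base acting at each link's center of mass.  The
resulting mass matrix, forcing vector, energy, linearization Jacobians
and the ground-reaction terms used for the center of pressure are
lambdified into plain-math callables and cached for the session.
"""

from __future__ import annotations

import inspect
import math
from functools import lru_cache

import sympy as sp


def _jit_scalar_function(func):
    """Compile a lambdified scalar-math callable with numba.

    The generated source is rewritten to return a tuple (numba-friendly)
    and jitted in nopython mode; on any failure the original callable is
    returned unchanged.  The compiled function is bit-identical to the
    interpreted one but ~50x faster, which matters in the innermost
    integration loop.
    """
    try:
        import numba
        src = inspect.getsource(func).replace(
            "def _lambdifygenerated", "def _jitted")
        i = src.rindex("return [")
        j = src.rindex("]")
        src = src[:i] + "return (" + src[i + len("return ["):j] + ")" \
            + src[j + 1:]
        ns = {"sin": math.sin, "cos": math.cos, "tan": math.tan,
              "sqrt": math.sqrt, "atan2": math.atan2, "math": math}
        exec(src, ns)
        jitted = numba.njit(ns["_jitted"])
        jitted(*([0.1] * _n_args(func)))   # force compilation now
        return jitted
    except Exception:      # pragma: no cover - jit is an optimization only
        return func


def _n_args(func) -> int:
    return len(inspect.signature(func).parameters)

#: argument order of every lambdified callable produced here (after the
#: kinematic arguments specific to each function).
PARAM_NAMES = ("m1", "m2", "L1", "c1", "c2",
               "I1x", "I1y", "I1z", "I2x", "I2y", "I2z", "g")


def _rot_y(a):
    c, s = sp.cos(a), sp.sin(a)
    return sp.Matrix([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_x(a):
    c, s = sp.cos(a), sp.sin(a)
    return sp.Matrix([[1, 0, 0], [0, c, -s], [0, s, c]])


@lru_cache(maxsize=1)
def derive():
    """Derive and lambdify the plant functions.  Returns a dict of callables.

    Keys
    ----
    mass_matrix(q0..q3, *params) -> 4x4 nested list
    forcing(q0..q3, u0..u3, ax, ay, *params) -> length-4 list
        M(q) qdd = forcing(q, u, a_base) + Q_applied, with Q_applied the
        generalized joint torques [T_a^S, T_h^S, T_a^C, T_h^C].
    energy(q0..q3, u0..u3, *params) -> float
        Kinetic + gravitational potential energy for a stationary platform.
    forcing_jac_q / forcing_jac_u -> 4x4 nested lists (for linearization)
    reaction(q0..q3, u0..u3, qdd0..qdd3, ax, ay, *params) -> length-6 list
        [Fx, Fy, Fz, Mx, My, Mz]: force and moment (about the ankle point,
        platform frame) that the platform exerts on the body — the
        ground-reaction wrench from which the center of pressure follows.
    """
    t = sp.Symbol("t")
    m1, m2, L1, c1, c2, I1x, I1y, I1z, I2x, I2y, I2z, g = sp.symbols(
        " ".join(PARAM_NAMES), positive=True)
    params = (m1, m2, L1, c1, c2, I1x, I1y, I1z, I2x, I2y, I2z, g)
    ax, ay = sp.symbols("ax ay", real=True)

    qf = [sp.Function(f"q{i}")(t) for i in range(4)]
    q = sp.Matrix(qf)
    qd = q.diff(t)
    qdd = qd.diff(t)

    # Link orientations: pitch about +y, then rightward roll (about -x).
    R1 = _rot_y(qf[0]) * _rot_x(-qf[2])
    R2 = R1 * _rot_y(qf[1]) * _rot_x(-qf[3])

    up = sp.Matrix([0, 0, 1])
    com1 = R1 * (c1 * up)
    hip = R1 * (L1 * up)
    com2 = hip + R2 * (c2 * up)
    v1 = com1.diff(t)
    v2 = com2.diff(t)

    def body_omega(R):
        S = sp.trigsimp(R.T * R.diff(t))
        return sp.Matrix([S[2, 1], S[0, 2], S[1, 0]])

    w1 = body_omega(R1)
    w2 = body_omega(R2)

    T = (m1 * v1.dot(v1) + m2 * v2.dot(v2)) / 2 \
        + (I1x * w1[0] ** 2 + I1y * w1[1] ** 2 + I1z * w1[2] ** 2) / 2 \
        + (I2x * w2[0] ** 2 + I2y * w2[1] ** 2 + I2z * w2[2] ** 2) / 2
    V = g * (m1 * com1[2] + m2 * com2[2])
    L = sp.expand(T - V)

    # Euler-Lagrange:  M(q) qdd + h(q, qd) = Q
    eom = sp.Matrix([sp.diff(L, qd[i]).diff(t) - sp.diff(L, qf[i])
                     for i in range(4)])
    eom = sp.expand(eom)
    M = eom.jacobian(qdd)
    h = eom.subs({qdd[i]: 0 for i in range(4)})

    # Horizontal base acceleration as a pseudo-force at each mass center.
    a_base = sp.Matrix([ax, ay, 0])
    Jv1 = com1.jacobian(q)
    Jv2 = com2.jacobian(q)
    Q_base = -(m1 * Jv1.T + m2 * Jv2.T) * a_base

    forcing = sp.expand(-h + Q_base)

    # Ground-reaction wrench at the ankle (platform frame, ankle at origin):
    # force F = sum(m a_abs) - W,  moment M = sum(Iw wd + w x Iw w
    # + r x m a_abs) - sum(r x m g_vec), with a_abs the absolute mass-center
    # acceleration (relative + base) and g_vec = -g z.
    g_vec = sp.Matrix([0, 0, -g])
    F = sp.zeros(3, 1)
    Mom = sp.zeros(3, 1)
    for (m_i, com_i, R_i, Ib) in (
            (m1, com1, R1, sp.diag(I1x, I1y, I1z)),
            (m2, com2, R2, sp.diag(I2x, I2y, I2z))):
        a_abs = com_i.diff(t, 2) + a_base
        w_world = sp.Matrix([
            (R_i.diff(t) * R_i.T)[2, 1],
            (R_i.diff(t) * R_i.T)[0, 2],
            (R_i.diff(t) * R_i.T)[1, 0]])
        H = R_i * Ib * R_i.T * w_world
        tau = H.diff(t)
        F += m_i * a_abs - m_i * g_vec
        Mom += tau + com_i.cross(m_i * a_abs) - com_i.cross(m_i * g_vec)

    # Replace time-functions by plain symbols for lambdification.
    qs = sp.symbols("q0:4")
    us = sp.symbols("u0:4")
    as_ = sp.symbols("A0:4")
    rep = {}
    for i in range(4):
        rep[qdd[i]] = as_[i]
        rep[qd[i]] = us[i]
        rep[qf[i]] = qs[i]

    def flat(expr):
        return expr.xreplace(rep)

    M_s = flat(M)
    forcing_s = flat(forcing)
    energy_s = flat(T + V)
    fjq = forcing_s.jacobian(qs)
    fju = forcing_s.jacobian(us)
    wrench_s = flat(sp.Matrix.vstack(F, Mom))

    mods = ["math"]
    funcs = {
        # combined M (row-major, 16) and forcing (4) with shared
        # subexpressions: the per-integration-step workhorse
        "dyn_terms": _jit_scalar_function(sp.lambdify(
            qs + us + (ax, ay) + params,
            list(M_s) + list(forcing_s), modules=mods, cse=True)),
        "mass_matrix": sp.lambdify(qs + params, M_s.tolist(), modules=mods,
                                   cse=True),
        "forcing": sp.lambdify(qs + us + (ax, ay) + params,
                               list(forcing_s), modules=mods, cse=True),
        "energy": sp.lambdify(qs + us + params, energy_s, modules=mods,
                              cse=True),
        "forcing_jac_q": sp.lambdify(qs + us + (ax, ay) + params,
                                     fjq.tolist(), modules=mods, cse=True),
        "forcing_jac_u": sp.lambdify(qs + us + (ax, ay) + params,
                                     fju.tolist(), modules=mods, cse=True),
        "reaction": _jit_scalar_function(
            sp.lambdify(qs + us + as_ + (ax, ay) + params,
                        list(wrench_s), modules=mods, cse=True)),
    }
    return funcs
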