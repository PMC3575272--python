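"""Independent equations-of-motion oracle via Kane's method.

Re-derives the two-link 3D pendulum dynamics with
``sympy.physics.mechanics.KanesMethod`` — a different algorithm and code
path from the package's own Lagrangian derivation — for cross-checking
generalized accelerations on random states.  Base excitation is handled
the same way as in the package (translating frame, horizontal
pseudo-forces at the mass centers), and applied joint torques enter as
generalized forces conjugate to the joint angles.
"""

from functools import lru_cache

import numpy as np
import sympy as sp
import sympy.physics.mechanics as me


@lru_cache(maxsize=1)
def _derive():
    q = me.dynamicsymbols("q0:4")
    u = me.dynamicsymbols("u0:4")
    m1, m2, L1, c1, c2 = sp.symbols("m1 m2 L1 c1 c2", positive=True)
    I1x, I1y, I1z, I2x, I2y, I2z = sp.symbols("I1x I1y I1z I2x I2y I2z",
                                              positive=True)
    g, ax, ay = sp.symbols("g ax ay", real=True)

    N = me.ReferenceFrame("N")
    O = me.Point("O")
    O.set_vel(N, 0)

    # pitch about +y then rightward roll about -x, matching the package
    A1 = N.orientnew("A1", "Body", (q[0], -q[2], 0), "YXZ")
    A1.set_ang_vel(N, A1.ang_vel_in(N).subs(
        {qi.diff(): ui for qi, ui in zip(q, u)}))
    A2 = A1.orientnew("A2", "Body", (q[1], -q[3], 0), "YXZ")
    A2.set_ang_vel(A1, A2.ang_vel_in(A1).subs(
        {qi.diff(): ui for qi, ui in zip(q, u)}))

    com1 = O.locatenew("com1", c1 * A1.z)
    hip = O.locatenew("hip", L1 * A1.z)
    com2 = hip.locatenew("com2", c2 * A2.z)
    com1.v2pt_theory(O, N, A1)
    hip.v2pt_theory(O, N, A1)
    com2.v2pt_theory(hip, N, A2)

    legs = me.RigidBody("legs", com1, A1, m1,
                        (me.inertia(A1, I1x, I1y, I1z), com1))
    torso = me.RigidBody("torso", com2, A2, m2,
                         (me.inertia(A2, I2x, I2y, I2z), com2))

    loads = [
        (com1, -m1 * g * N.z - m1 * (ax * N.x + ay * N.y)),
        (com2, -m2 * g * N.z - m2 * (ax * N.x + ay * N.y)),
    ]

    kde = [qi.diff() - ui for qi, ui in zip(q, u)]
    kane = me.KanesMethod(N, q_ind=list(q), u_ind=list(u), kd_eqs=kde)
    kane.kanes_equations([legs, torso], loads)

    MM = kane.mass_matrix
    forcing = kane.forcing

    qs = sp.symbols("Q0:4")
    us = sp.symbols("U0:4")
    rep = {}
    for i in range(4):
        rep[q[i]] = qs[i]
        rep[u[i]] = us[i]
    params = (m1, m2, L1, c1, c2, I1x, I1y, I1z, I2x, I2y, I2z, g)
    f_mm = sp.lambdify(qs + us + (ax, ay) + params,
                       MM.xreplace(rep).tolist(), modules="math", cse=True)
    f_fo = sp.lambdify(qs + us + (ax, ay) + params,
                       list(forcing.xreplace(rep)), modules="math", cse=True)
    return f_mm, f_fo


def kane_rhs(state, torques, platform_accel, body_params, g=9.81):
    """State derivative from the Kane derivation (oracle)."""
    f_mm, f_fo = _derive()
    p = body_params.as_tuple(g)
    args = (*state[:4], *state[4:], platform_accel[0], platform_accel[1], *p)
    MM = np.array(f_mm(*args))
    fo = np.array(f_fo(*args)) + np.asarray(torques, float)
    qdd = np.linalg.solve(MM, fo)
    return np.concatenate([np.asarray(state[4:], float), qdd])
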