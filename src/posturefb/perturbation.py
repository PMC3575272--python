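"""Discrete support-surface translation profiles.

A perturbation is a straight-line platform translation with a trapezoidal
velocity profile: constant acceleration, constant velocity, constant
deceleration (defaults 100/200/100 ms), total travel 50-70 mm.  Azimuth
convention used package-wide: 0 deg = forward (navel direction), angles
increase clockwise viewed from above, so 90 deg = rightward, 180 deg =
backward.  The direction is the direction of platform motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PerturbationSpec", "PlatformMotion", "TrapezoidProfile",
           "trapezoid_profile", "cosd", "sind"]


def cosd(deg: float) -> float:
    """Cosine of an angle in degrees, exact at multiples of 90 deg."""
    r = deg % 360.0
    if r == 0.0:
        return 1.0
    if r == 90.0 or r == 270.0:
        return 0.0
    if r == 180.0:
        return -1.0
    return float(np.cos(np.deg2rad(deg)))


def sind(deg: float) -> float:
    """Sine of an angle in degrees, exact at multiples of 90 deg."""
    r = deg % 360.0
    if r == 0.0 or r == 180.0:
        return 0.0
    if r == 90.0:
        return 1.0
    if r == 270.0:
        return -1.0
    return float(np.sin(np.deg2rad(deg)))


@dataclass(frozen=True)
class PerturbationSpec:
    """Platform translation: azimuth (deg, clockwise from forward),
    total displacement (m), phase durations (s) and onset time (s)."""
    direction: float = 180.0
    displacement: float = 0.060
    t_accel: float = 0.100
    t_const: float = 0.200
    t_decel: float = 0.100
    onset: float = 0.5

    def __post_init__(self):
        if self.displacement < 0:
            raise ValueError("displacement must be >= 0")
        if min(self.t_accel, self.t_const, self.t_decel) <= 0:
            raise ValueError("phase durations must be positive")
        if not (0.0 <= self.direction < 360.0):
            raise ValueError("direction must lie in [0, 360) deg")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")

    @property
    def duration(self) -> float:
        return self.t_accel + self.t_const + self.t_decel

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class PlatformMotion:
    """Uniformly sampled platform motion (x forward, y rightward)."""
    t: np.ndarray
    pos: np.ndarray    # (n, 2) m
    vel: np.ndarray    # (n, 2) m/s
    acc: np.ndarray    # (n, 2) m/s^2
    dt: float


class TrapezoidProfile:
    """Closed-form trapezoidal-velocity translation along a fixed azimuth.

    Phase durations are rounded to the nearest integration sample so the
    profile lies exactly on the grid; the peak speed is then rescaled so
    the net displacement still equals ``spec.displacement`` exactly.
    """

    def __init__(self, spec: PerturbationSpec, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.spec = spec
        self.dt = dt
        rnd = lambda x: max(1, round(x / dt)) * dt
        self.ta = rnd(spec.t_accel)
        self.tc = rnd(spec.t_const)
        self.td = rnd(spec.t_decel)
        self.onset = round(spec.onset / dt) * dt
        # displacement = v_pk * (ta/2 + tc + td/2)
        self.v_pk = spec.displacement / (self.ta / 2 + self.tc + self.td / 2)
        self.u = np.array([cosd(spec.direction), sind(spec.direction)])

    @property
    def duration(self) -> float:
        return self.ta + self.tc + self.td

    def _scalar(self, t: float,
                left: bool = False) -> tuple[float, float, float]:
        """(s, v, a) along the motion axis at absolute time t.

        The acceleration is piecewise constant with jumps at the phase
        boundaries; ``left`` selects the left-sided limit there (used by
        the integrator for stages that end exactly on a boundary).
        """
        tau = t - self.onset
        ta, tc, td, v = self.ta, self.tc, self.td, self.v_pk
        eps = 1e-9     # snap grid times that land a few ulp off a boundary
        before = (tau <= eps) if left else (tau < -eps)
        if before or v == 0.0:
            return (0.0, 0.0, 0.0)

        def lt(x, y):
            return x <= y + eps if left else x < y - eps

        a1 = v / ta
        if lt(tau, ta):
            return (a1 * tau ** 2 / 2, a1 * tau, a1)
        if lt(tau, ta + tc):
            return (v * ta / 2 + v * (tau - ta), v, 0.0)
        if lt(tau, ta + tc + td):
            x = tau - ta - tc
            a3 = v / td
            return (v * ta / 2 + v * tc + v * x - a3 * x ** 2 / 2,
                    v - a3 * x, -a3)
        return (v * (ta / 2 + tc + td / 2), 0.0, 0.0)

    def accel(self, t: float, left: bool = False) -> np.ndarray:
        return self._scalar(t, left)[2] * self.u

    def vel(self, t: float) -> np.ndarray:
        return self._scalar(t)[1] * self.u

    def pos(self, t: float) -> np.ndarray:
        return self._scalar(t)[0] * self.u

    def motion(self, horizon: float) -> PlatformMotion:
        """Sample the profile on the uniform grid [0, horizon]."""
        if horizon < self.onset + self.duration:
            raise ValueError("horizon shorter than the perturbation")
        n = round(horizon / self.dt) + 1
        t = np.arange(n) * self.dt
        sva = np.array([self._scalar(ti) for ti in t])
        return PlatformMotion(t=t,
                              pos=np.outer(sva[:, 0], self.u),
                              vel=np.outer(sva[:, 1], self.u),
                              acc=np.outer(sva[:, 2], self.u),
                              dt=self.dt)


def trapezoid_profile(spec: PerturbationSpec, dt: float,
                      horizon: float) -> PlatformMotion:
    """Sampled trapezoidal platform motion (see :class:`TrapezoidProfile`)."""
    return TrapezoidProfile(spec, dt).motion(horizon)
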