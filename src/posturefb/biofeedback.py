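"""Vibrotactile biofeedback device model and the additive feedback torque.

The device senses torso tilt, displays its direction on one of up to 16
tactor columns spaced 22.5 deg around the torso (nearest-neighbor
selection) and its magnitude on up to 3 tactor rows (stepwise
thresholds, 1 deg dead zone).  The displayed signal elicits an
additional joint torque that relaxes with a first-order lag (time
constant tau_F) toward a steady-state target set by the active row and
the *displayed* column azimuth theta:

    K_F^S = k_r^S cos(theta),   K_F^C = k_r^C sin(theta)

with constant 2-vectors (ankle, hip) k_1 <= k_2 <= k_3 componentwise so
the torque magnitude grows with the row.  The feedback magnitude the
device displays is the combined signal m = inclination + 0.5 *
inclination rate (deg, deg/s); m, not the raw inclination, is compared
against the dead zone and row thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .perturbation import cosd, sind

__all__ = ["DisplayConfig", "TiltSignal", "TactorActivation",
           "BiofeedbackParams", "FeedbackTorqueState", "sense_tilt",
           "select_activation", "target_torque", "advance_feedback_torque",
           "DISPLAY_PRESETS"]

_ALL_COLUMNS = tuple(22.5 * i for i in range(16))

#: Named display presets: rows x active columns.
DISPLAY_PRESETS: dict[str, dict] = {
    "off": {"columns": (), "rows": 0},
    "1x2": {"columns": (0.0, 180.0), "rows": 1},
    "3x4": {"columns": (0.0, 90.0, 180.0, 270.0), "rows": 3},
    "3x8": {"columns": tuple(45.0 * i for i in range(8)), "rows": 3},
    "3x16": {"columns": _ALL_COLUMNS, "rows": 3},
}


@dataclass(frozen=True)
class DisplayConfig:
    """Active tactor columns (azimuths, deg clockwise from the navel),
    row count and the ascending row thresholds (deg of feedback
    magnitude); the first threshold is the dead zone."""
    columns: tuple[float, ...] = DISPLAY_PRESETS["3x4"]["columns"]
    rows: int = 3
    thresholds: tuple[float, ...] = (1.0, 2.0, 3.0)

    def __post_init__(self):
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column azimuths must be distinct")
        if any(not (0.0 <= c < 360.0) for c in self.columns):
            raise ValueError("column azimuths must lie in [0, 360) deg")
        if not 0 <= self.rows <= 3:
            raise ValueError("row count must be 0..3")
        th = self.thresholds[:self.rows] if self.rows else ()
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("row thresholds must be strictly ascending")

    @property
    def dead_zone(self) -> float:
        return self.thresholds[0] if self.rows else np.inf

    @classmethod
    def preset(cls, name: str, thresholds: tuple[float, ...] = (1.0, 2.0, 3.0),
               **overrides) -> "DisplayConfig":
        try:
            geom = DISPLAY_PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown display preset {name!r}") from None
        kw = {"columns": geom["columns"], "rows": geom["rows"],
              "thresholds": thresholds}
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class TiltSignal:
    """Torso inclination (deg), inclination rate (deg/s), azimuth (deg,
    clockwise from the navel) and the displayed feedback magnitude
    m = inclination + 0.5 * rate (deg)."""
    inclination: float
    rate: float
    azimuth: float
    magnitude: float


@dataclass(frozen=True)
class TactorActivation:
    """Displayed column azimuth (deg; None when off) and active row
    r in {0..3} (0 = display off)."""
    column: float | None
    row: int

    def __post_init__(self):
        if not 0 <= self.row <= 3:
            raise ValueError("row must be in 0..3")
        if (self.row == 0) != (self.column is None):
            raise ValueError("row 0 iff no column active")


@dataclass(frozen=True)
class BiofeedbackParams:
    """Reaction time constant tau_F (s) and per-row steady-state torque
    magnitudes: k_s, k_c are (3, 2) arrays [row, (ankle, hip)] in N m for
    the sagittal and coronal planes."""
    tau_f: float = 0.25
    k_s: np.ndarray = field(
        default_factory=lambda: np.array([[4.0, 0.0], [6.0, 1.5], [8.0, 3.0]]))
    k_c: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 2)))

    def __post_init__(self):
        object.__setattr__(self, "k_s", np.asarray(self.k_s, float))
        object.__setattr__(self, "k_c", np.asarray(self.k_c, float))
        if self.tau_f <= 0:
            raise ValueError("tau_F must be positive")
        for name, k in (("k_s", self.k_s), ("k_c", self.k_c)):
            if k.shape != (3, 2):
                raise ValueError(f"{name} must be (3, 2) [row, joint]")
            if np.any(np.diff(k, axis=0) < -1e-12):
                raise ValueError(
                    f"{name} violates the row ordering k_1 <= k_2 <= k_3")


@dataclass
class FeedbackTorqueState:
    """Current first-order-lag torque state and its steady-state targets,
    per plane (ankle, hip components, N m)."""
    t_f_s: np.ndarray = field(default_factory=lambda: np.zeros(2))
    t_f_c: np.ndarray = field(default_factory=lambda: np.zeros(2))
    k_f_s: np.ndarray = field(default_factory=lambda: np.zeros(2))
    k_f_c: np.ndarray = field(default_factory=lambda: np.zeros(2))


def sense_tilt(state: np.ndarray) -> TiltSignal:
    """Device-sensed torso tilt from the plant state.

    Small-angle torso inclination components: AP = alpha_a^S + alpha_h^S,
    ML = alpha_a^C + alpha_h^C (converted to degrees).  Azimuth is the
    two-argument arctangent of (ML, AP) mapped clockwise from the navel;
    upright (zero inclination) reports azimuth 0 by convention and the
    rate falls back to the norm of the component rates.
    """
    ap = np.rad2deg(state[0] + state[1])
    ml = np.rad2deg(state[2] + state[3])
    dap = np.rad2deg(state[4] + state[5])
    dml = np.rad2deg(state[6] + state[7])
    phi = float(np.hypot(ap, ml))
    if phi > 1e-12:
        rate = (ap * dap + ml * dml) / phi
        azimuth = float(np.rad2deg(np.arctan2(ml, ap))) % 360.0
    else:
        rate = float(np.hypot(dap, dml))
        azimuth = 0.0
    return TiltSignal(inclination=phi, rate=rate, azimuth=azimuth,
                      magnitude=phi + 0.5 * rate)


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def select_activation(tilt: TiltSignal,
                      config: DisplayConfig) -> TactorActivation:
    """Nearest-neighbor column and stepwise row for the sensed tilt.

    Off (row 0) when the feedback magnitude is below the dead zone or no
    columns are configured; otherwise the row is the highest threshold
    not exceeding the magnitude, and the column the configured azimuth
    with minimal circular distance to the tilt azimuth (ties: the lower
    azimuth wins).
    """
    if not config.columns or config.rows == 0:
        return TactorActivation(column=None, row=0)
    m = tilt.magnitude
    if m < config.dead_zone:
        return TactorActivation(column=None, row=0)
    row = 0
    for thr in config.thresholds[:config.rows]:
        if m >= thr:
            row += 1
    cols = sorted(config.columns)
    best = min(cols, key=lambda c: (_circ_dist(c, tilt.azimuth), c))
    return TactorActivation(column=best, row=row)


def target_torque(activation: TactorActivation, params: BiofeedbackParams
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state feedback torque targets (K_F^S, K_F^C).

    Decomposition by the displayed column azimuth: K_F^S = k_r cos(theta),
    K_F^C = k_r sin(theta); row 0 targets zero.  The returned magnitudes
    are in the device's corrective sense — the simulation applies them
    with a restoring sign, so positive k with cos(theta) > 0 yields an
    applied torque opposing forward tilt.
    """
    if activation.row == 0:
        return np.zeros(2), np.zeros(2)
    r = activation.row
    if not 1 <= r <= 3:
        raise ValueError("active row must be 1..3")
    th = activation.column
    return params.k_s[r - 1] * cosd(th), params.k_c[r - 1] * sind(th)


def advance_feedback_torque(t_f: np.ndarray, target: np.ndarray,
                            tau_f: float, dt: float) -> np.ndarray:
    """One exact step of the first-order lag tau_F dT/dt + T = K.

    The target is held constant over the step, so
    T(t+dt) = K + (T(t) - K) exp(-dt/tau_F) — exact, not an Euler step.
    """
    if tau_f <= 0 or dt <= 0:
        raise ValueError("tau_F and dt must be positive")
    decay = np.exp(-dt / tau_f)
    return target + (np.asarray(t_f, float) - target) * decay
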