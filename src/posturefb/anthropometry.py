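"""Anthropometric derivation of the two-link body parameters.

The plant has exactly two links: *legs* (both legs lumped, ankle to hip,
knees locked) and *torso* (head-arms-trunk lumped, hip to vertex).  Link
masses and lengths are fixed fractions of total body mass and height,
taken from standard segment-parameter tables; moments of inertia come
from closed-form solids (a cylinder for the legs, an ellipsoid for the
torso).  The shipped fraction table is a documented stand-in from the
biomechanics literature, fully overridable via configuration — the feet
are excluded from the leg mass because the model has no feet.

Link frames: x forward, y rightward, z along the link's long axis.
Inertias are principal tensors about the center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SubjectSpec", "LinkParams", "BodyParams",
           "DEFAULT_FRACTIONS", "solid_inertia", "derive_body_params"]

#: Default segment fractions (of total mass / total height).
#:
#: legs  = 2 x (thigh + shank); feet excluded (not modelled), so link
#:         masses deliberately sum to ~97% of body mass.
#: torso = head + arms + trunk (HAT), hip to vertex.
#: com_fraction is measured from the proximal joint (ankle for the legs,
#: hip for the torso) as a fraction of the link length.
#: shape_dims are fractions of the link length.
DEFAULT_FRACTIONS: dict = {
    "legs": {
        "mass_fraction": 0.293,
        "length_fraction": 0.491,   # ankle to greater trochanter
        "com_fraction": 0.55,
        "shape": "cylinder",
        "shape_dims": {"radius_fraction": 0.12},
    },
    "torso": {
        "mass_fraction": 0.678,
        "length_fraction": 0.470,   # greater trochanter to vertex
        "com_fraction": 0.42,
        "shape": "ellipsoid",
        "shape_dims": {"a_fraction": 0.14, "b_fraction": 0.20},
    },
}


@dataclass(frozen=True)
class SubjectSpec:
    """Total body height (m) and mass (kg)."""
    height: float
    mass: float

    def __post_init__(self):
        if not (self.height > 0 and self.mass > 0):
            raise ValueError("subject height and mass must be positive")


@dataclass(frozen=True)
class LinkParams:
    """One rigid link: mass (kg), length (m), proximal-joint-to-COM
    distance (m) and principal inertia about the COM (kg m^2, diag)."""
    mass: float
    length: float
    com: float
    inertia: tuple[float, float, float]

    def validate(self) -> None:
        if min(self.mass, self.length, self.com) < 0:
            raise ValueError("link mass/length/com must be non-negative")
        if any(i < 0 for i in self.inertia):
            raise ValueError("principal inertias must be non-negative")


@dataclass(frozen=True)
class BodyParams:
    legs: LinkParams
    torso: LinkParams
    ankle_offset: float = 0.0   # ankle height above the platform surface

    def validate(self, total_mass: float | None = None) -> None:
        self.legs.validate()
        self.torso.validate()
        m = self.legs.mass + self.torso.mass
        if m <= 0:
            raise ValueError("link masses must be positive")
        if total_mass is not None and m > total_mass * (1 + 1e-12):
            raise ValueError("link masses exceed total body mass")

    @property
    def total_mass(self) -> float:
        return self.legs.mass + self.torso.mass

    def as_tuple(self, g: float = 9.81) -> tuple:
        """Parameter vector in the order the symbolic plant expects."""
        return (self.legs.mass, self.torso.mass, self.legs.length,
                self.legs.com, self.torso.com,
                *self.legs.inertia, *self.torso.inertia, g)


def solid_inertia(shape: str, mass: float, dimensions) -> np.ndarray:
    """Principal COM inertia of a homogeneous solid.

    Parameters
    ----------
    shape : {"cylinder", "ellipsoid"}
        ``cylinder``: dimensions = (radius, length); long axis = z.
        ``ellipsoid``: dimensions = (a, b, c) semi-axes along x, y, z.
    mass : kg
    dimensions : lengths in m, all positive

    Returns
    -------
    (3,) array (Ix, Iy, Iz) about the center of mass.
    """
    if mass < 0 or any(d < 0 for d in dimensions):
        raise ValueError("mass and dimensions must be non-negative")
    if shape == "cylinder":
        r, L = dimensions
        it = mass * (3 * r ** 2 + L ** 2) / 12.0
        return np.array([it, it, mass * r ** 2 / 2.0])
    if shape == "ellipsoid":
        a, b, c = dimensions
        return (mass / 5.0) * np.array(
            [b ** 2 + c ** 2, a ** 2 + c ** 2, a ** 2 + b ** 2])
    raise ValueError(f"unknown shape {shape!r}")


def _link_from_fractions(subject: SubjectSpec, frac: dict) -> LinkParams:
    m = subject.mass * frac["mass_fraction"]
    length = subject.height * frac["length_fraction"]
    com = length * frac["com_fraction"]
    dims = frac["shape_dims"]
    if frac["shape"] == "cylinder":
        geometry = (dims["radius_fraction"] * length, length)
    elif frac["shape"] == "ellipsoid":
        geometry = (dims["a_fraction"] * length, dims["b_fraction"] * length,
                    length / 2.0)
    else:
        raise ValueError(f"unknown shape {frac['shape']!r}")
    inertia = solid_inertia(frac["shape"], m, geometry)
    return LinkParams(mass=m, length=length, com=com,
                      inertia=tuple(float(i) for i in inertia))


def derive_body_params(subject: SubjectSpec,
                       fractions: dict | None = None) -> BodyParams:
    """Populate :class:`BodyParams` from subject height/mass and a
    fraction table (defaults to :data:`DEFAULT_FRACTIONS`)."""
    table = fractions if fractions is not None else DEFAULT_FRACTIONS
    missing = {"legs", "torso"} - set(table)
    if missing:
        raise ValueError(f"fraction table missing segments: {sorted(missing)}")
    params = BodyParams(legs=_link_from_fractions(subject, table["legs"]),
                        torso=_link_from_fractions(subject, table["torso"]))
    params.validate(total_mass=subject.mass)
    return params
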