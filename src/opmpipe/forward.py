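"""Forward model: current dipole in a spherically symmetric volume conductor.

The magnetic field outside a spherically symmetric conductor due to a current
dipole has a closed form (Sarvas): with the conductor centred at the origin,
a dipole of moment ``Q`` (A·m) at ``r0``, and a field point ``r``,

    a = r - r0,  a = |a|,  r = |r|
    F = a (r a + r^2 - r0 · r)
    ∇F = (a^2/r + a·r/a + 2a + 2r) r - (a + 2r + a·r/a) r0
    B(r) = mu0 / (4 pi F^2) [ F (Q x r0) - ((Q x r0) · r) ∇F ]

Two consequences used throughout: a radial dipole (Q parallel to r0) is
externally silent, and the field does not depend on the conductor radius or
conductivity profile.  Fields are returned in fT for moments in A·m and
distances in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError

_MU0_OVER_4PI = 1e-7  # T·m/A
_T_TO_FT = 1e15

#: minimum distance (m) of a source from the sphere origin before the
#: closed form is declared singular (Q x r0 -> 0, orientation undefined)
ORIGIN_TOL = 1e-6


@dataclass
class SensorArray:
    """Geometry of a triaxial magnetometer array on a spherical scalp.

    Each physical sensor contributes three measurement channels whose
    orientation axes (radial + two tangential) are orthonormal, so
    ``n_channels = 3 * n_sensors``.
    """

    sensor_positions: np.ndarray      # (n_sensors, 3), m
    sensor_orientations: np.ndarray   # (n_sensors, 3, 3): rows rad, tan1, tan2
    channel_names: list[str]
    sphere_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scalp_radius: float = 0.095

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_channels(self) -> int:
        return 3 * self.n_sensors

    @property
    def channel_positions(self) -> np.ndarray:
        """(n_channels, 3) position of every measurement axis."""
        return np.repeat(self.sensor_positions, 3, axis=0)

    @property
    def channel_orientations(self) -> np.ndarray:
        """(n_channels, 3) unit orientation of every measurement axis."""
        return self.sensor_orientations.reshape(-1, 3)

    def validate(self, atol: float = 1e-9) -> None:
        for s in range(self.n_sensors):
            O = self.sensor_orientations[s]
            if not np.allclose(O @ O.T, np.eye(3), atol=1e-10):
                raise GeometryError(f"orientation triplet of sensor {s} not orthonormal")
        radii = np.linalg.norm(self.sensor_positions - self.sphere_origin, axis=1)
        if not np.allclose(radii, self.scalp_radius, atol=atol):
            raise GeometryError("sensor positions not on the scalp sphere")


def tangential_basis(location: np.ndarray, origin: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal basis (t1, t2, radial) at a point in the conductor.

    The radial direction points away from the sphere origin; the two
    tangential directions complete a right-handed orthonormal triple with a
    deterministic convention (t1 orthogonal to the global axis least aligned
    with the radial direction).
    """
    r = np.asarray(location, float) - np.asarray(origin, float)
    nr = np.linalg.norm(r)
    if nr < ORIGIN_TOL:
        raise GeometryError("point coincides with the sphere origin")
    rhat = r / nr
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(rhat)))] = 1.0
    t1 = np.cross(rhat, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(rhat, t1)
    return t1, t2, rhat


def dipole_field_at(points: np.ndarray, location: np.ndarray, moment: np.ndarray,
                    origin: np.ndarray) -> np.ndarray:
    """Vector field (Tesla) at ``points`` (n, 3) outside the conductor."""
    origin = np.asarray(origin, float)
    r0 = np.asarray(location, float) - origin
    r = np.atleast_2d(np.asarray(points, float)) - origin
    q = np.asarray(moment, float)

    a = r - r0
    na = np.linalg.norm(a, axis=1)
    nr = np.linalg.norm(r, axis=1)
    if np.any(na < ORIGIN_TOL):
        raise GeometryError("field point coincides with the source")
    adotr = np.einsum("ij,ij->i", a, r)
    F = na * (nr * na + nr ** 2 - r @ r0)
    gradF = ((na ** 2 / nr + adotr / na + 2 * na + 2 * nr)[:, None] * r
             - (na + 2 * nr + adotr / na)[:, None] * r0)
    qxr0 = np.cross(q, r0)
    B = _MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0 - (r @ qxr0)[:, None] * gradF)
    return B


def check_inside(location: np.ndarray, array: SensorArray) -> np.ndarray:
    """Validate that a source lies strictly inside the scalp sphere, off origin."""
    loc = np.asarray(location, float)
    d = np.linalg.norm(loc - array.sphere_origin)
    if d < ORIGIN_TOL:
        raise GeometryError("source at the sphere origin: external field undefined")
    if d >= array.scalp_radius:
        raise GeometryError("source outside the conductor sphere")
    return loc


def dipole_field(location: np.ndarray, moment: np.ndarray, array: SensorArray) -> np.ndarray:
    """Per-channel field (fT) of a current dipole, projected on each axis."""
    loc = check_inside(location, array)
    B = dipole_field_at(array.sensor_positions, loc, moment, array.sphere_origin)
    # each sensor's 3 axes read the projection of the same vector field
    proj = np.einsum("sij,sj->si", array.sensor_orientations, B)
    return proj.reshape(-1) * _T_TO_FT


def leadfield(location: np.ndarray, array: SensorArray) -> np.ndarray:
    """Leadfield matrix (n_channels, 3), fT per unit dipole moment (A·m).

    Columns are the fields of unit dipoles along the local tangential
    orthobasis (t1, t2) completed by the radial direction; the radial column
    is numerically zero in a spherical conductor.
    """
    loc = check_inside(location, array)
    t1, t2, rhat = tangential_basis(loc, array.sphere_origin)
    cols = [dipole_field(loc, m, array) for m in (t1, t2, rhat)]
    return np.column_stack(cols)
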