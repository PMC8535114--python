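"""Point-dipole model of the capsule magnet and the torque/force laws acting on it.

The capsule carries an axially magnetized cylindrical NdFeB magnet.  At the
sensor-board distances used here (tens of millimetres, several magnet lengths)
the magnet is modelled as a point dipole of moment ``m = M_s * V`` along the
capsule axis.  The field constant ``BT = mu0 * |m| / (4 pi)`` (units T·m³)
collects everything the field formula needs besides geometry:

    B(r) = BT * (3 (D·P) P / |P|^5  -  D / |P|^3),    P = r - position

where ``D`` is the unit heading.  Steering and propulsion follow from the
magnetostatic torque ``tau = V M x B`` and force ``F = V (M·grad) B``.

All quantities are SI (tesla, metre, ampere-metre²) internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU0 = 4e-7 * np.pi

#: Validity floor of the point-dipole model: evaluations closer than this to
#: the magnet centre are refused (the real magnet is 10 mm across).
MIN_DIPOLE_RANGE = 1e-3


class DegenerateGeometryError(ValueError):
    """Field requested inside the dipole-model exclusion sphere."""


def _as_unit(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
        raise ValueError(f"{name} must be unit-norm, got |{name}| = {n!r}")
    return v


@dataclass(frozen=True)
class MagnetPose:
    """5-DOF pose of the capsule magnet: position (m) and unit heading."""

    position: np.ndarray
    heading: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "heading", _as_unit(self.heading, "heading"))

    @classmethod
    def from_angles(cls, position, yaw: float, pitch: float) -> "MagnetPose":
        return cls(position=np.asarray(position, float),
                   heading=heading_from_angles(yaw, pitch))

    @property
    def yaw_pitch(self) -> tuple[float, float]:
        y, p, _ = angles_from_heading(self.heading)
        return y, p


@dataclass(frozen=True)
class MagnetSpec:
    """Magnetic properties of the capsule's permanent magnet.

    Parameters
    ----------
    volume : float
        Magnet volume, m³.
    magnetization_magnitude : float
        Saturation magnetization |M|, A/m.
    dipole_strength : float
        BT = mu0 * volume * |M| / (4 pi), T·m³.  Derived automatically when
        omitted; if given it must be consistent with the other two fields.
    """

    volume: float
    magnetization_magnitude: float
    dipole_strength: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.volume <= 0 or self.magnetization_magnitude <= 0:
            raise ValueError("volume and magnetization must be strictly positive")
        bt = MU0 * self.volume * self.magnetization_magnitude / (4 * np.pi)
        if self.dipole_strength is None:
            object.__setattr__(self, "dipole_strength", bt)
        elif abs(self.dipole_strength - bt) > 1e-12 * bt:
            raise ValueError(
                f"dipole_strength {self.dipole_strength!r} inconsistent with "
                f"mu0*V*|M|/4pi = {bt!r}")

    @classmethod
    def from_cylinder(cls, diameter: float, length: float,
                      remanence: float = 1.48) -> "MagnetSpec":
        """Spec for an axially magnetized cylinder given remanence Br (T).

        Default Br = 1.48 T, typical of grade N54 NdFeB.  |M| = Br / mu0.
        """
        volume = np.pi * (diameter / 2) ** 2 * length
        return cls(volume=volume, magnetization_magnitude=remanence / MU0)

    @property
    def moment(self) -> float:
        """Dipole moment magnitude |m| = V * |M|, A·m²."""
        return self.volume * self.magnetization_magnitude


def default_magnet_spec() -> MagnetSpec:
    """The Ø10 mm x 12 mm N54 capsule magnet (BT ≈ 1.11e-7 T·m³)."""
    return MagnetSpec.from_cylinder(diameter=10e-3, length=12e-3)


# ---------------------------------------------------------------------------
# Fields


def dipole_field(pose: MagnetPose, spec: MagnetSpec, point) -> np.ndarray:
    """Dipole magnetic field (T) of the capsule magnet at ``point`` (m).

    Raises :class:`DegenerateGeometryError` within 1 mm of the magnet centre,
    where the point-dipole approximation is meaningless.
    """
    point = np.asarray(point, dtype=float)
    p = point - pose.position
    r = np.linalg.norm(p)
    if r < MIN_DIPOLE_RANGE:
        raise DegenerateGeometryError(
            f"field evaluation at {point.tolist()} is {r * 1e3:.3f} mm from the "
            f"magnet centre (< {MIN_DIPOLE_RANGE * 1e3:.0f} mm model floor)")
    d = pose.heading
    return spec.dipole_strength * (3.0 * (d @ p) * p / r**5 - d / r**3)


def dipole_field_z(pose: MagnetPose, spec: MagnetSpec, sensor) -> float:
    """z-component of the dipole field at a sensor location (T).

    This is the single quantity a board-normal mono-axis Hall sensor reads:
    ``BT * (3 (D·P) P_z / |P|^5 - D_z / |P|^3)``.
    """
    sensor = np.asarray(sensor, dtype=float)
    p = sensor - pose.position
    r = np.linalg.norm(p)
    if r < MIN_DIPOLE_RANGE:
        raise DegenerateGeometryError(
            f"field evaluation at {sensor.tolist()} is inside the "
            f"{MIN_DIPOLE_RANGE * 1e3:.0f} mm exclusion sphere")
    d = pose.heading
    return spec.dipole_strength * (3.0 * (d @ p) * p[2] / r**5 - d[2] / r**3)


def dipole_field_z_batch(positions: np.ndarray, headings: np.ndarray,
                         spec: MagnetSpec, sensors: np.ndarray) -> np.ndarray:
    """Vectorized ``dipole_field_z``: (n_pose, 3) x (n_sensor, 3) -> (n_pose, n_sensor).

    No exclusion-sphere checking — intended for grid searches and bulk
    synthesis where the caller controls the geometry.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    headings = np.atleast_2d(np.asarray(headings, float))
    sensors = np.atleast_2d(np.asarray(sensors, float))
    p = sensors[None, :, :] - positions[:, None, :]          # (np, ns, 3)
    r2 = np.einsum("ijk,ijk->ij", p, p)
    r = np.sqrt(r2)
    dp = np.einsum("ik,ijk->ij", headings, p)
    return spec.dipole_strength * (3.0 * dp * p[:, :, 2] / (r2**2 * r)
                                   - headings[:, None, 2] / (r2 * r))


# ---------------------------------------------------------------------------
# Torque and force


def magnetic_torque(spec: MagnetSpec, heading, B) -> np.ndarray:
    """Magnetostatic torque tau = V M x B (N·m) on the capsule magnet."""
    heading = _as_unit(heading, "heading")
    B = np.asarray(B, dtype=float)
    return np.cross(spec.moment * heading, B)


def magnetic_force(spec: MagnetSpec, heading, gradB) -> np.ndarray:
    """Magnetic gradient force F = V (M·grad) B (N).

    ``gradB[i, j] = dB_j / dx_i``, so component j of the force is
    ``V |M| * sum_i heading_i * dB_j/dx_i = V|M| (gradB^T heading)_j``.
    """
    heading = _as_unit(heading, "heading")
    gradB = np.asarray(gradB, dtype=float)
    if gradB.shape != (3, 3):
        raise ValueError("gradB must be a 3x3 tensor (T/m)")
    return spec.moment * (gradB.T @ heading)


# ---------------------------------------------------------------------------
# Heading <-> yaw/pitch


def heading_from_angles(yaw: float, pitch: float) -> np.ndarray:
    """Unit heading from yaw (about +z, from +x) and pitch (elevation), rad."""
    cp = np.cos(pitch)
    return np.array([cp * np.cos(yaw), cp * np.sin(yaw), np.sin(pitch)])


def angles_from_heading(d) -> tuple[float, float, bool]:
    """Inverse of :func:`heading_from_angles`.

    Returns ``(yaw, pitch, degenerate)``.  At pitch = ±90° yaw is undefined
    (gimbal degeneracy); it is returned as 0 and the flag is set.
    """
    d = _as_unit(d, "heading")
    pitch = float(np.arcsin(np.clip(d[2], -1.0, 1.0)))
    if np.hypot(d[0], d[1]) < 1e-12:
        return 0.0, pitch, True
    return float(np.arctan2(d[1], d[0])), pitch, False
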