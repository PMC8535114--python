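"""Electromagnetic actuation (EMA) model: coil field basis, superposition,
actuation matrix and minimum-norm current allocation.

The actuation system is ten air-core electromagnets — a Helmholtz pair, two
Maxwell (anti-Helmholtz) pairs and two rectangular pairs — surrounding a
100 x 100 x 40 mm region of interest (ROI) above the sensor board.  Each coil
is modelled as a filament stack: circular loops use the exact off-axis
solution in complete elliptic integrals, rectangular loops the four-segment
finite-wire formula.  Everything downstream is linear in the currents:

    B(P) = sum_k H_k(P) * i_k

where H_k is coil k's unit-current field.  The 6x10 actuation matrix X(P)
stacks the three field rows and the three heading-projected gradient rows per
unit current; commanded (field, gradient) set-points are mapped to coil
currents through the Moore–Penrose pseudoinverse, i = X(P)^+ [B; F]_desired,
which is the minimum-norm solution of the underdetermined system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe, ellipk

from .magnetics import MU0, heading_from_angles

#: Filament clearance: field evaluations closer than this to a wire are refused.
FILAMENT_CLEARANCE = 0.5e-3

#: Central-difference step for gradient tensors, m.
GRADIENT_STEP = 1e-4


class FilamentProximityError(ValueError):
    """Field requested too close to a coil filament."""


@dataclass(frozen=True)
class CoilSpec:
    """One filament coil: geometry, orientation and turn count.

    ``axis`` is the coil normal (direction of the dipole moment for positive
    current).  Circular coils use ``radius``; rectangular coils use
    ``half_width`` / ``half_height`` in the coil plane.
    """

    shape: str                      # "circular" | "rectangular"
    center: np.ndarray
    axis: np.ndarray
    turns: int
    label: str = ""
    radius: float | None = None
    half_width: float | None = None
    half_height: float | None = None

    def __post_init__(self):
        if self.shape not in ("circular", "rectangular"):
            raise ValueError(f"unknown coil shape {self.shape!r}")
        object.__setattr__(self, "center", np.asarray(self.center, float))
        ax = np.asarray(self.axis, float)
        n = np.linalg.norm(ax)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("coil axis must be unit-norm")
        object.__setattr__(self, "axis", ax)
        if self.turns <= 0:
            raise ValueError("turns must be positive")
        if self.shape == "circular":
            if self.radius is None or self.radius <= 0:
                raise ValueError("circular coil needs radius > 0")
        else:
            if (self.half_width is None or self.half_width <= 0
                    or self.half_height is None or self.half_height <= 0):
                raise ValueError("rectangular coil needs half_width/half_height > 0")

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Right-handed local frame (u, v, axis); u/v span the coil plane."""
        w = self.axis
        ref = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ w) * w
        u /= np.linalg.norm(u)
        return u, np.cross(w, u), w


# ---------------------------------------------------------------------------
# Single-loop fields (tesla per ampere)


def loop_field_circular(coil: CoilSpec, point) -> np.ndarray:
    """Unit-current field (T/A) of a circular filament loop, exact off-axis.

    Uses the standard solution in complete elliptic integrals K(m), E(m);
    reduces to the textbook on-axis closed form when the point is on the coil
    axis.
    """
    point = np.asarray(point, float)
    u, v, w = coil.frame()
    rel = point - coil.center
    z = rel @ w
    rho_vec = rel - z * w
    rho = np.linalg.norm(rho_vec)
    R = coil.radius

    alpha2 = (R - rho) ** 2 + z * z        # squared distance to the filament
    if alpha2 < FILAMENT_CLEARANCE**2:
        raise FilamentProximityError(
            f"point {point.tolist()} is {np.sqrt(alpha2)*1e3:.2f} mm from the "
            f"filament of coil {coil.label!r} (< {FILAMENT_CLEARANCE*1e3:.1f} mm)")

    if rho < 1e-12:                         # on-axis closed form
        bz = MU0 * R * R / (2.0 * (R * R + z * z) ** 1.5)
        return coil.turns * bz * w

    beta2 = (R + rho) ** 2 + z * z
    beta = np.sqrt(beta2)
    m = 4.0 * R * rho / beta2               # elliptic parameter m = k^2
    K, E = ellipk(m), ellipe(m)
    c = MU0 / np.pi
    bz = c / (2.0 * alpha2 * beta) * ((R * R - rho * rho - z * z) * E + alpha2 * K)
    brho = (c * z / (2.0 * alpha2 * beta * rho)
            * ((R * R + rho * rho + z * z) * E - alpha2 * K))
    return coil.turns * (bz * w + brho * rho_vec / rho)


def _segment_field(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Biot–Savart field (T/A) of a finite straight filament from a to b."""
    r1 = p - a
    r2 = p - b
    n1 = np.linalg.norm(r1)
    n2 = np.linalg.norm(r2)
    denom = n1 * n2 * (n1 * n2 + r1 @ r2)
    if denom < 1e-30:
        raise FilamentProximityError(
            f"point {p.tolist()} lies on a filament segment")
    return 1e-7 * (n1 + n2) / denom * np.cross(r1, r2)   # mu0/4pi = 1e-7


def loop_field_rectangular(coil: CoilSpec, point) -> np.ndarray:
    """Unit-current field (T/A) of a rectangular filament loop.

    Sum of the four analytic finite-wire segments, traversed counterclockwise
    about the coil axis so positive current gives a moment along ``axis``.
    """
    point = np.asarray(point, float)
    u, v, w = coil.frame()
    a, b = coil.half_width, coil.half_height
    corners = [coil.center + sx * a * u + sy * b * v
               for sx, sy in ((+1, +1), (-1, +1), (-1, -1), (+1, -1))]
    # filament clearance: distance to each segment
    for i in range(4):
        s, e = corners[i], corners[(i + 1) % 4]
        seg = e - s
        t = np.clip((point - s) @ seg / (seg @ seg), 0.0, 1.0)
        if np.linalg.norm(point - (s + t * seg)) < FILAMENT_CLEARANCE:
            raise FilamentProximityError(
                f"point {point.tolist()} within {FILAMENT_CLEARANCE*1e3:.1f} mm "
                f"of coil {coil.label!r} filament")
    B = np.zeros(3)
    for i in range(4):
        B += _segment_field(point, corners[i], corners[(i + 1) % 4])
    return coil.turns * B


def coil_unit_field(coil: CoilSpec, point) -> np.ndarray:
    """Unit-current field (T/A) of a coil, dispatching on its shape."""
    if coil.shape == "circular":
        return loop_field_circular(coil, point)
    return loop_field_rectangular(coil, point)


# ---------------------------------------------------------------------------
# System configuration


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned region-of-interest box (m)."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        if not np.all(hi > lo):
            raise ValueError("ROI box is empty")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    def contains(self, point, margin: float = 0.0) -> bool:
        p = np.asarray(point, float)
        return bool(np.all(p >= self.lo - margin) and np.all(p <= self.hi + margin))

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class EMAConfig:
    """The ten-coil actuation system: coil list, ROI and current limits."""

    coils: tuple[CoilSpec, ...]
    roi: ROIBox
    current_limit: float = 30.0        # A, symmetric per coil

    def __post_init__(self):
        coils = tuple(self.coils)
        if len(coils) != 10:
            raise ValueError(f"EMA system has 10 coils, got {len(coils)}")
        object.__setattr__(self, "coils", coils)

    @property
    def n_coils(self) -> int:
        return len(self.coils)


def default_ema_config() -> EMAConfig:
    """Declarative default ten-coil layout: Helmholtz pair along z, Maxwell
    pairs along x and y, and two rectangular pairs mounted on the horizontal
    diagonals (one tilted out of plane), centred on the ROI.

    The axis-aligned pairs provide uniform-field and diagonal-gradient
    authority; every coaxial pair's gradient tensor is diagonal at the
    symmetry point, so the rectangular pairs are deliberately mounted off the
    coordinate axes to supply the cross-gradient (off-diagonal) components a
    fully axis-aligned layout cannot produce there.  Coil dimensions are
    representative of a human-scale actuation barrel; the allocation layer
    achieves requested in-ROI (field, gradient) set-points by construction.
    """
    roi = ROIBox(lo=[-0.05, -0.05, 0.0], hi=[0.05, 0.05, 0.04])
    c = roi.center
    R = 0.25
    ex, ey, ez = np.eye(3)
    coils = []
    # Helmholtz pair along z: separation = radius
    for s, tag in ((+1, "+"), (-1, "-")):
        coils.append(CoilSpec("circular", c + s * (R / 2) * ez, ez,
                              turns=500, radius=R, label=f"HH_z{tag}"))
    # Maxwell pairs along x and y: separation = sqrt(3) * radius
    for axis, name in ((ex, "x"), (ey, "y")):
        for s, tag in ((+1, "+"), (-1, "-")):
            coils.append(CoilSpec("circular", c + s * (np.sqrt(3) * R / 2) * axis,
                                  axis, turns=500, radius=R,
                                  label=f"MW_{name}{tag}"))
    # Rectangular pairs (0.30 x 0.20 m) on the diagonals; pair B tilted 30°
    u1 = (ex + ey) / np.sqrt(2)
    u2 = np.cos(np.pi / 6) * (ex - ey) / np.sqrt(2) + np.sin(np.pi / 6) * ez
    for axis, name in ((u1, "d1"), (u2, "d2")):
        for s, tag in ((+1, "+"), (-1, "-")):
            coils.append(CoilSpec("rectangular", c + s * 0.30 * axis, axis,
                                  turns=300, half_width=0.15, half_height=0.10,
                                  label=f"RC_{name}{tag}"))
    return EMAConfig(coils=tuple(coils), roi=roi)


def config_to_dict(config: EMAConfig) -> dict:
    """Serializable mapping (inverse of :func:`config_from_dict`)."""
    coils = []
    for c in config.coils:
        cd = {"shape": c.shape, "center": c.center.tolist(),
              "axis": c.axis.tolist(), "turns": c.turns, "label": c.label}
        if c.shape == "circular":
            cd["radius"] = c.radius
        else:
            cd["half_width"] = c.half_width
            cd["half_height"] = c.half_height
        coils.append(cd)
    return {"coils": coils,
            "roi": {"lo": config.roi.lo.tolist(), "hi": config.roi.hi.tolist()},
            "current_limit": config.current_limit}


def config_from_dict(d: dict) -> EMAConfig:
    """Build an :class:`EMAConfig` from a structured-text (YAML/JSON) mapping."""
    coils = []
    for cd in d["coils"]:
        coils.append(CoilSpec(
            shape=cd["shape"], center=np.asarray(cd["center"], float),
            axis=np.asarray(cd["axis"], float), turns=int(cd["turns"]),
            label=cd.get("label", ""), radius=cd.get("radius"),
            half_width=cd.get("half_width"), half_height=cd.get("half_height")))
    roi = ROIBox(lo=d["roi"]["lo"], hi=d["roi"]["hi"])
    return EMAConfig(coils=tuple(coils), roi=roi,
                     current_limit=float(d.get("current_limit", 30.0)))


# ---------------------------------------------------------------------------
# Superposition, basis, gradients


def coil_basis(config: EMAConfig, points) -> np.ndarray:
    """Unit-current field table H_k at each point: array (n_coils, n_points, 3).

    This is the in-silico twin of the measured unit-current database the
    compensation step consumes; it is deterministic given the configuration.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if points.size == 0:
        raise ValueError("points must be nonempty")
    out = np.empty((config.n_coils, len(points), 3))
    for k, coil in enumerate(config.coils):
        for j, p in enumerate(points):
            out[k, j] = coil_unit_field(coil, p)
    return out


def ema_field(config: EMAConfig, currents, point) -> np.ndarray:
    """Superposed actuation field B = sum_k H_k(point) * i_k (T)."""
    currents = np.asarray(currents, float)
    if currents.shape != (config.n_coils,):
        raise ValueError(f"expected {config.n_coils} currents, got {currents.shape}")
    if np.any(np.abs(currents) > config.current_limit):
        warnings.warn(
            f"currents exceed the ±{config.current_limit:g} A limit "
            f"(max |i| = {np.max(np.abs(currents)):.2f} A)", stacklevel=2)
    B = np.zeros(3)
    for coil, i in zip(config.coils, currents):
        if i != 0.0:
            B += i * coil_unit_field(coil, point)
    return B


def field_gradient_tensor(config: EMAConfig, currents, point,
                          step: float = GRADIENT_STEP) -> np.ndarray:
    """Spatial gradient G[i, j] = dB_j/dx_i of the actuation field (T/m).

    Central finite differences; in free space the tensor is symmetric
    (curl-free) and traceless (divergence-free) up to truncation error.
    """
    point = np.asarray(point, float)
    G = np.empty((3, 3))
    for i in range(3):
        dp = np.zeros(3)
        dp[i] = step
        G[i] = (ema_field(config, currents, point + dp)
                - ema_field(config, currents, point - dp)) / (2.0 * step)
    return G


def coil_gradient_tensor(coil: CoilSpec, point,
                         step: float = GRADIENT_STEP) -> np.ndarray:
    """Unit-current gradient tensor of a single coil (T/m per A)."""
    point = np.asarray(point, float)
    G = np.empty((3, 3))
    for i in range(3):
        dp = np.zeros(3)
        dp[i] = step
        G[i] = (coil_unit_field(coil, point + dp)
                - coil_unit_field(coil, point - dp)) / (2.0 * step)
    return G


# ---------------------------------------------------------------------------
# Actuation matrix, allocation, command mapping


@dataclass(frozen=True)
class ActuationMatrix:
    """6 x n_coils map from unit coil currents to (B, heading-projected grad B)."""

    matrix: np.ndarray
    eval_point: np.ndarray
    heading_used: np.ndarray

    @property
    def condition_number(self) -> float:
        s = np.linalg.svd(self.matrix, compute_uv=False)
        return float(s[0] / s[-1]) if s[-1] > 0 else np.inf


def build_actuation_matrix(config: EMAConfig, P, heading) -> ActuationMatrix:
    """Actuation matrix X(P): rows 1–3 the per-coil unit-current field at P,
    rows 4–6 the heading-projected per-coil gradient components.

    Row ``3+j``, column ``k`` is ``heading · grad(B_j of coil k at P)``, i.e.
    the unit-current contribution of coil k to the propulsion triple
    ``(M̂·grad) B``.
    """
    P = np.asarray(P, float)
    if not config.roi.contains(P):
        raise ValueError(f"evaluation point {P.tolist()} outside the ROI box "
                         f"[{config.roi.lo.tolist()}, {config.roi.hi.tolist()}]")
    heading = np.asarray(heading, float)
    X = np.empty((6, config.n_coils))
    for k, coil in enumerate(config.coils):
        X[:3, k] = coil_unit_field(coil, P)
        X[3:, k] = heading @ coil_gradient_tensor(coil, P)
    return ActuationMatrix(matrix=X, eval_point=P, heading_used=heading)


@dataclass(frozen=True)
class DesiredWrench:
    """Desired actuation set-point: field (T) and heading-projected gradient (T/m)."""

    field: np.ndarray
    gradient_along_heading: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([np.asarray(self.field, float),
                               np.asarray(self.gradient_along_heading, float)])


def command_to_desired(yaw: float, pitch: float, F: float,
                       gamma: float = 0.1) -> DesiredWrench:
    """End-user command (yaw, pitch, push F) -> desired (field, gradient).

    The single push magnitude F (T/m) sets the gradient; the field is the
    same direction scaled by the fixed field:gradient ratio gamma (default
    0.1 m, the 1:10 tesla-to-tesla-per-metre ratio).  Both vectors point
    along the commanded heading, so the capsule aligns with, and is pushed
    along, the same direction.
    """
    if F < 0:
        raise ValueError("F must be >= 0; reverse by flipping the heading "
                         "(yaw + pi, -pitch)")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    u = heading_from_angles(yaw, pitch)
    return DesiredWrench(field=gamma * F * u, gradient_along_heading=F * u)


def allocate_currents(X: ActuationMatrix, desired: DesiredWrench,
                      rcond: float = 1e-10,
                      return_diagnostics: bool = False):
    """Minimum-norm currents i = X^+ [B; F]_desired via SVD pseudoinverse.

    Singular values below ``rcond`` times the largest are truncated; rank
    deficiency is reported in the diagnostics.
    """
    target = desired.as_vector() if isinstance(desired, DesiredWrench) \
        else np.asarray(desired, float)
    if not np.all(np.isfinite(target)):
        raise ValueError("desired 6-vector must be finite")
    M = X.matrix
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    keep = s > rcond * s[0]
    inv_s = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    currents = Vt.T @ (inv_s * (U.T @ target))
    if return_diagnostics:
        diag = {
            "rank": int(np.sum(keep)),
            "full_row_rank": bool(np.sum(keep) == M.shape[0]),
            "condition_number": float(s[0] / s[keep][-1]) if np.any(keep) else np.inf,
            "residual": float(np.linalg.norm(M @ currents - target)),
        }
        return currents, diag
    return currents
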