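"""5-DOF capsule pose estimation from a mono-axis Hall-sensor array.

Each board-mounted sensor reads the z-component of the superposed field of
the capsule magnet and the actuation coils.  Localization proceeds in two
steps:

1. **Compensation** — subtract the reconstructed actuation field, using the
   unit-current coil basis at the sensor positions and the currents active at
   read time: ``HM = HS - sum_k H_k * i_k``.  This needs no knowledge of the
   coil geometry beyond the unit-current table itself.
2. **Estimation** — fit the point-dipole z-field model to the compensated
   readings by damped nonlinear least squares (Levenberg–Marquardt), over the
   five observable parameters (x, y, z, yaw, pitch).  Roll of an axially
   magnetized capsule is unobservable and is not a parameter.

The estimator follows the fitted-model idiom: build a
:class:`DipolePoseModel` from the compensated measurements, call
:meth:`~DipolePoseModel.fit`, and read estimates, a covariance proxy and
diagnostics off the returned :class:`DipolePoseResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .magnetics import (MagnetPose, MagnetSpec, angles_from_heading,
                        dipole_field_z_batch, heading_from_angles)

#: Candidate positions closer than this to the sensor plane are rejected.
Z_FLOOR = 5e-3


@dataclass(frozen=True)
class SensorArray:
    """Layout and electrical model of the mono-axis Hall-sensor board.

    Defaults mirror a 6x6 grid of DRV5055-class ratiometric sensors on a
    20 mm pitch spanning 100 x 100 mm at z = 0, measuring the global
    z-component: 12.5 mV/mT sensitivity, ±169 mT range, 5 V supply, 16-bit
    acquisition.
    """

    positions: np.ndarray
    sensitivity: float = 12.5e-3 / 1e-3     # V/T  (12.5 mV/mT)
    range_limit: float = 169e-3             # T
    supply_voltage: float = 5.0             # V
    adc_bits: int = 16

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, float))
        if pos.shape[0] < 6:
            raise ValueError("need >= 6 sensors for 5-DOF identifiability")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def grid(cls, n: int = 6, pitch: float = 20e-3, z: float = 0.0,
             **kwargs) -> "SensorArray":
        """n x n grid centred on the origin (default 6x6, 20 mm pitch)."""
        if pitch <= 0:
            raise ValueError("pitch must be > 0")
        axis = (np.arange(n) - (n - 1) / 2) * pitch
        xx, yy = np.meshgrid(axis, axis, indexing="ij")
        pos = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, z)])
        return cls(positions=pos, **kwargs)

    @property
    def n_sensors(self) -> int:
        return len(self.positions)


def default_sensor_array() -> SensorArray:
    return SensorArray.grid()


@dataclass(frozen=True)
class SensorFrame:
    """One synchronized read of the array: per-sensor z-field (T), the coil
    currents active during the read, and a timestamp."""

    readings: np.ndarray
    currents: np.ndarray
    timestamp: float = 0.0
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        r = np.asarray(self.readings, float)
        object.__setattr__(self, "readings", r)
        object.__setattr__(self, "currents", np.asarray(self.currents, float))
        if self.saturated is None:
            object.__setattr__(self, "saturated", np.zeros(len(r), bool))
        else:
            object.__setattr__(self, "saturated",
                               np.asarray(self.saturated, bool))


# ---------------------------------------------------------------------------
# Sensor electrical model


def voltage_from_field(b, array: SensorArray):
    """Ratiometric sensor output: v = supply/2 + sensitivity * b, clipped to
    the measurement range.  Returns (voltage, saturated_mask)."""
    b = np.asarray(b, float)
    clipped = np.clip(b, -array.range_limit, array.range_limit)
    return array.supply_voltage / 2 + array.sensitivity * clipped, \
        np.abs(b) > array.range_limit


def field_from_voltage(v, array: SensorArray):
    """Inverse of :func:`voltage_from_field` inside the linear range (T)."""
    v = np.asarray(v, float)
    return (v - array.supply_voltage / 2) / array.sensitivity


def quantize_voltage(v, array: SensorArray):
    """Round to the ADC grid spanning [0, supply] with 2**adc_bits codes."""
    lsb = array.supply_voltage / (2 ** array.adc_bits)
    return np.round(np.asarray(v, float) / lsb) * lsb


# ---------------------------------------------------------------------------
# Compensation


def compensate(frame: SensorFrame, basis_at_sensors: np.ndarray) -> np.ndarray:
    """Remove the actuation field from a frame: HM = HS - sum_k H_k i_k.

    ``basis_at_sensors`` is the unit-current table from
    :func:`capsnav.coils.coil_basis` evaluated at the sensor positions,
    shape (n_coils, n_sensors, 3); only the z-column is used for the
    mono-axis board.  Exact to machine precision when the frame was
    synthesized from the same basis.
    """
    basis_z = np.asarray(basis_at_sensors)[:, :, 2]
    if basis_z.shape[0] != len(frame.currents):
        raise ValueError(
            f"basis has {basis_z.shape[0]} coils but frame carries "
            f"{len(frame.currents)} currents")
    if basis_z.shape[1] != len(frame.readings):
        raise ValueError("basis sensor count does not match the frame")
    return frame.readings - frame.currents @ basis_z


# ---------------------------------------------------------------------------
# Residuals and the fitted-model interface


def residuals(params, measurements, array: SensorArray,
              spec: MagnetSpec) -> np.ndarray:
    """Per-sensor residual (measured - modelled dipole z-field), T.

    ``params`` is (x, y, z, yaw, pitch) in metres/radians.  The summed square
    of this vector is the cost the estimator minimizes.
    """
    x, y, z, yaw, pitch = params
    if z < Z_FLOOR:
        raise ValueError(
            f"candidate height {z*1e3:.2f} mm below the {Z_FLOOR*1e3:.0f} mm "
            "sensor-plane floor")
    model = dipole_field_z_batch(np.array([[x, y, z]]),
                                 heading_from_angles(yaw, pitch)[None, :],
                                 spec, array.positions)[0]
    return np.asarray(measurements, float) - model


def _residuals_soft(params, measurements, positions, spec):
    """Residual vector with a smooth barrier below the z-floor (solver-safe)."""
    x, y, z, yaw, pitch = params
    zc = max(z, Z_FLOOR)
    model = dipole_field_z_batch(np.array([[x, y, zc]]),
                                 heading_from_angles(yaw, pitch)[None, :],
                                 spec, positions)[0]
    res = measurements - model
    if z < Z_FLOOR:                      # linear penalty pushes back above floor
        res = res + (Z_FLOOR - z)
    return res


def grid_search_pose(measurements, array: SensorArray, spec: MagnetSpec,
                     roi_lo=(-0.05, -0.05, 0.01), roi_hi=(0.05, 0.05, 0.04),
                     position_pitch: float = 0.01,
                     n_headings: int = 6) -> np.ndarray:
    """Cold-start initializer: lowest-cost cell of a coarse position grid
    crossed with a small set of headings.  Returns (x, y, z, yaw, pitch)."""
    lo = np.asarray(roi_lo, float)
    hi = np.asarray(roi_hi, float)
    axes = [np.arange(lo[i], hi[i] + 1e-12, position_pitch) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    positions = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    yaws = np.linspace(0, 2 * np.pi, n_headings, endpoint=False)
    meas = np.asarray(measurements, float)
    best = None
    for yaw in yaws:
        h = heading_from_angles(yaw, 0.0)
        model = dipole_field_z_batch(positions, np.tile(h, (len(positions), 1)),
                                     spec, array.positions)
        cost = np.sum((model - meas[None, :]) ** 2, axis=1)
        j = int(np.argmin(cost))
        if best is None or cost[j] < best[0]:
            best = (cost[j], positions[j], yaw)
    _, p, yaw = best
    return np.array([p[0], p[1], p[2], yaw, 0.0])


class DipolePoseModel:
    """Nonlinear least-squares model of compensated Hall-array readings.

    Parameters
    ----------
    measurements : array (n_sensors,)
        Compensated per-sensor z-field HM, tesla.
    array : SensorArray
    spec : MagnetSpec
    mask : bool array, optional
        Sensors to use (e.g. to drop saturated channels).  At least 6 must
        remain.
    """

    param_names = ("x", "y", "z", "yaw", "pitch")

    def __init__(self, measurements, array: SensorArray, spec: MagnetSpec,
                 mask=None):
        meas = np.asarray(measurements, float)
        if mask is None:
            mask = np.ones(len(meas), bool)
        mask = np.asarray(mask, bool)
        if mask.sum() < 6:
            raise ValueError(
                f"only {int(mask.sum())} usable sensors; >= 6 required")
        self.measurements = meas[mask]
        self.positions = array.positions[mask]
        self.array = array
        self.spec = spec
        self.mask = mask

    @classmethod
    def from_frame(cls, frame: SensorFrame, basis_at_sensors, array: SensorArray,
                   spec: MagnetSpec) -> "DipolePoseModel":
        """Compensate a raw frame and build the model, dropping saturated
        sensors."""
        hm = compensate(frame, basis_at_sensors)
        mask = ~frame.saturated
        if mask.sum() == 0:
            raise ValueError("all sensors saturated; frame unusable")
        return cls(hm, array, spec, mask=mask)

    def cost(self, params) -> float:
        """Sum of squared residuals at ``params``."""
        return float(np.sum(_residuals_soft(
            np.asarray(params, float), self.measurements, self.positions,
            self.spec) ** 2))

    def fit(self, start=None, max_iter: int = 200, xtol: float = 1e-14,
            ftol: float = 1e-14, gtol: float = 1e-14) -> "DipolePoseResults":
        """Fit by Levenberg–Marquardt from ``start`` (cold grid search when
        omitted); returns a :class:`DipolePoseResults`.

        If the unconstrained LM solution dips below the sensor-plane floor,
        the fit is refined with a bounded trust-region pass.
        """
        if start is None:
            x0 = grid_search_pose(self.measurements,
                                  SensorArray(self.positions), self.spec)
        else:
            x0 = np.asarray(start, float)
            x0 = np.array([x0[0], x0[1], max(x0[2], Z_FLOOR + 1e-4),
                           x0[3], x0[4]])
        args = (self.measurements, self.positions, self.spec)
        sol = least_squares(_residuals_soft, x0, args=args, method="lm",
                            max_nfev=max_iter * (len(x0) + 1),
                            xtol=xtol, ftol=ftol, gtol=gtol)
        if sol.x[2] < Z_FLOOR:
            lb = [-np.inf, -np.inf, Z_FLOOR, -np.inf, -np.inf]
            sol = least_squares(_residuals_soft, np.maximum(sol.x, lb),
                                args=args, method="trf",
                                bounds=(lb, [np.inf] * 5),
                                max_nfev=max_iter * (len(x0) + 1),
                                xtol=xtol, ftol=ftol, gtol=gtol)
        return DipolePoseResults(self, sol)


class DipolePoseResults:
    """Fit results: pose estimate, cost, covariance proxy and diagnostics."""

    def __init__(self, model: DipolePoseModel, sol):
        self.model = model
        self.params = np.asarray(sol.x, float)
        self.cost = float(2.0 * sol.cost)        # scipy stores 0.5 * sum r^2
        self.converged = bool(sol.status > 0)
        self.n_iterations = int(sol.nfev)
        self.residual = np.asarray(sol.fun, float)
        self._jac = np.asarray(sol.jac, float)

    @property
    def pose(self) -> MagnetPose:
        x, y, z, yaw, pitch = self.params
        return MagnetPose(position=np.array([x, y, z]),
                          heading=heading_from_angles(yaw, pitch))

    @property
    def yaw(self) -> float:
        return float(self.params[3])

    @property
    def pitch(self) -> float:
        return float(self.params[4])

    @property
    def covariance_proxy(self) -> np.ndarray:
        """sigma^2 (J^T J)^-1 from the final Jacobian — a linearized
        uncertainty proxy, not a calibrated posterior."""
        dof = max(len(self.residual) - len(self.params), 1)
        sigma2 = self.cost / dof
        JtJ = self._jac.T @ self._jac
        return sigma2 * np.linalg.pinv(JtJ)

    @property
    def stderr(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance_proxy), 0, None))

    def summary(self) -> str:
        lines = [
            "Dipole pose estimate (Levenberg-Marquardt)",
            "=" * 54,
            f"sensors used:  {len(self.residual):4d}    "
            f"cost: {self.cost:.4e} T^2",
            f"converged:     {self.converged}    fevals: {self.n_iterations}",
            "-" * 54,
            f"{'param':>6} {'estimate':>14} {'std.err':>12} {'unit':>8}",
        ]
        units = ("m", "m", "m", "rad", "rad")
        for name, val, se, unit in zip(self.model.param_names, self.params,
                                       self.stderr, units):
            lines.append(f"{name:>6} {val:14.6g} {se:12.3g} {unit:>8}")
        lines.append("=" * 54)
        return "\n".join(lines)


def estimate_pose(frame: SensorFrame, basis_at_sensors, array: SensorArray,
                  spec: MagnetSpec, init=None, **fit_kwargs) -> DipolePoseResults:
    """Convenience wrapper: compensate, build the model, fit.

    ``init`` may be a :class:`DipolePoseResults` (warm start during
    tracking), a 5-parameter vector, or None for a cold grid-search start.
    """
    model = DipolePoseModel.from_frame(frame, basis_at_sensors, array, spec)
    if isinstance(init, DipolePoseResults):
        init = init.params
    return model.fit(start=init, **fit_kwargs)


def pose_to_params(pose: MagnetPose) -> np.ndarray:
    yaw, pitch, _ = angles_from_heading(pose.heading)
    return np.array([*pose.position, yaw, pitch])
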