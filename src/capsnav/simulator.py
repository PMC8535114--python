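"""Synthetic-data generation and quasi-static closed-loop plant.

The simulator produces what the physical rig produces: synchronized Hall-array
frames (dipole field + actuation field + noise, quantized through the sensor
electrical model) and capsule motion under magnetic torque and gradient force.

Dynamics are quasi-static/overdamped — the capsule in viscous or frictional
media moves at terminal velocity and aligns with the field on a short time
constant, so inertia is neglected:

* heading relaxes toward the local field direction with first-order time
  constant ``tau_align * (B_ref / |B|)`` (alignment torque scales with field
  strength);
* translation at ``v = max(0, (|F_net| - friction_threshold) / drag)`` along
  the net-force direction, projected onto the tube centerline in tube mode.

The closed loop mirrors the operator policy: estimate the pose from the
latest frame, steer toward the next waypoint (yaw/pitch), push with a fixed
gradient magnitude, allocate coil currents, advance the plant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coils import (EMAConfig, allocate_currents, build_actuation_matrix,
                    coil_basis, command_to_desired, ema_field,
                    field_gradient_tensor)
from .localization import (DipolePoseResults, SensorArray, SensorFrame,
                           estimate_pose, voltage_from_field, quantize_voltage,
                           field_from_voltage)
from .magnetics import (MagnetPose, MagnetSpec, dipole_field_z_batch,
                        heading_from_angles, magnetic_force)

#: Field magnitude at which heading alignment runs at its nominal time
#: constant; weaker fields align proportionally slower.
B_REF = 5e-3


@dataclass(frozen=True)
class CapsuleState:
    pose: MagnetPose
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "velocity", np.asarray(self.velocity, float))


@dataclass(frozen=True)
class Environment:
    """Lumped mechanical environment: viscous drag, static friction threshold
    and (tube mode) a centerline the capsule is confined to."""

    mode: str = "free_space"                 # "free_space" | "tube"
    drag_coefficient: float = 2.2            # N·s/m
    friction_threshold_force: float = 0.0    # N
    tube_centerline: np.ndarray | None = None
    tube_radius: float = 6e-3

    def __post_init__(self):
        if self.mode not in ("free_space", "tube"):
            raise ValueError(f"unknown environment mode {self.mode!r}")
        if self.drag_coefficient <= 0:
            raise ValueError("drag must be > 0")
        if self.mode == "tube" and self.tube_centerline is None:
            raise ValueError("tube mode needs a centerline polyline")
        if self.tube_centerline is not None:
            object.__setattr__(self, "tube_centerline",
                               np.atleast_2d(np.asarray(self.tube_centerline,
                                                        float)))


# ---------------------------------------------------------------------------
# Sensor-frame synthesis


def synth_sensor_frame(state: CapsuleState, currents, array: SensorArray,
                       spec: MagnetSpec, basis_at_sensors, noise_sigma: float,
                       rng: np.random.Generator | None = None,
                       quantize: bool = True) -> SensorFrame:
    """One synthetic array read: dipole z-field + actuation field + Gaussian
    noise, passed through the ratiometric sensor model (clipping to the
    measurement range, ADC quantization).

    ``quantize=False`` bypasses the ADC stage (range clipping still applies)
    for analytic checks that need readings exact to machine precision.
    """
    currents = np.asarray(currents, float)
    dipole = dipole_field_z_batch(state.pose.position[None, :],
                                  state.pose.heading[None, :],
                                  spec, array.positions)[0]
    ema_z = currents @ np.asarray(basis_at_sensors)[:, :, 2]
    b = dipole + ema_z
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        b = b + rng.normal(0.0, noise_sigma, size=b.shape)
    v, saturated = voltage_from_field(b, array)
    if quantize:
        v = quantize_voltage(v, array)
    readings = field_from_voltage(v, array)
    return SensorFrame(readings=readings, currents=currents,
                       timestamp=state.time, saturated=saturated)


# ---------------------------------------------------------------------------
# Plant dynamics


def _slerp_toward(h: np.ndarray, target: np.ndarray, frac: float) -> np.ndarray:
    """Rotate unit vector h toward unit vector target by fraction frac of the
    angle between them."""
    c = float(np.clip(h @ target, -1.0, 1.0))
    ang = np.arccos(c)
    if ang < 1e-12:
        return target.copy()
    if ang > np.pi - 1e-9:         # antiparallel: no unique plane, pick one
        perp = np.cross(h, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(h, [1.0, 0.0, 0.0])
        axis = perp / np.linalg.norm(perp)
    else:
        axis = np.cross(h, target)
        axis /= np.linalg.norm(axis)
    step = frac * ang
    # Rodrigues rotation of h about axis by step
    out = (h * np.cos(step) + np.cross(axis, h) * np.sin(step)
           + axis * (axis @ h) * (1 - np.cos(step)))
    return out / np.linalg.norm(out)


def _nearest_on_polyline(p: np.ndarray, line: np.ndarray):
    """Closest point on a polyline and the local unit tangent there."""
    best = (np.inf, None, None)
    for i in range(len(line) - 1):
        a, b = line[i], line[i + 1]
        seg = b - a
        L2 = seg @ seg
        t = 0.0 if L2 == 0 else float(np.clip((p - a) @ seg / L2, 0.0, 1.0))
        q = a + t * seg
        d = np.linalg.norm(p - q)
        if d < best[0]:
            best = (d, q, seg / np.sqrt(L2) if L2 > 0 else None)
    return best


def step_dynamics(state: CapsuleState, currents, env: Environment,
                  config: EMAConfig, spec: MagnetSpec, dt: float,
                  tau_align: float = 0.05) -> CapsuleState:
    """Advance the capsule one quasi-static step of length dt (s).

    Heading relaxes toward the local field direction; position advances at
    overdamped terminal velocity along the net gradient force, minus the
    static friction threshold.
    """
    if not (0.0 < dt <= 0.1):
        raise ValueError(f"dt must be in (0, 0.1] s, got {dt}")
    currents = np.asarray(currents, float)
    pos = state.pose.position
    heading = state.pose.heading

    if np.any(currents != 0.0):
        B = ema_field(config, currents, pos)
        Bmag = np.linalg.norm(B)
        if Bmag > 1e-12:
            # torque-driven alignment; rate scales with field strength
            rate = Bmag / (B_REF * tau_align)
            heading = _slerp_toward(heading, B / Bmag, 1.0 - np.exp(-rate * dt))
        G = field_gradient_tensor(config, currents, pos)
        F = magnetic_force(spec, heading, G)
    else:
        F = np.zeros(3)

    Fmag = np.linalg.norm(F)
    if Fmag > env.friction_threshold_force and Fmag > 0:
        speed = (Fmag - env.friction_threshold_force) / env.drag_coefficient
        v = speed * F / Fmag
    else:
        v = np.zeros(3)

    if env.mode == "tube" and np.linalg.norm(v) > 0:
        _, _, tangent = _nearest_on_polyline(pos, env.tube_centerline)
        if tangent is not None:
            v = (v @ tangent) * tangent

    new_pos = pos + v * dt
    if env.mode == "tube":
        d, q, _ = _nearest_on_polyline(new_pos, env.tube_centerline)
        if d > env.tube_radius:
            new_pos = q + (new_pos - q) * (env.tube_radius / d)

    return CapsuleState(pose=MagnetPose(position=new_pos, heading=heading),
                        velocity=v, time=state.time + dt)


# ---------------------------------------------------------------------------
# Paths and logs


def generate_ushape_path(extent: float = 0.08, spacing: float = 5e-3,
                         z: float = 0.02) -> np.ndarray:
    """U-shaped waypoint polyline inscribed in an ``extent`` x ``extent``
    square at height z: two parallel legs joined by a semicircular turn.

    Leg separation is extent/2 (turn radius extent/4), so the default 80 mm
    U fits the 100 x 100 mm ROI footprint with margin.
    """
    r = extent / 4.0
    leg = extent - r
    x_left, x_right = -r, r
    y_top, y_bot = extent / 2.0, -extent / 2.0 + r
    pts = []
    # left leg, downward
    n = max(int(np.ceil(leg / spacing)), 1)
    for y in np.linspace(y_top, y_bot, n + 1):
        pts.append((x_left, y))
    # semicircular turn about (0, y_bot), through (0, y_bot - r)
    arc_n = max(int(np.ceil(np.pi * r / spacing)), 2)
    for ang in np.linspace(np.pi, 2 * np.pi, arc_n + 1)[1:]:
        pts.append((r * np.cos(ang), y_bot + r * np.sin(ang)))
    # right leg, upward
    for y in np.linspace(y_bot, y_top, n + 1)[1:]:
        pts.append((x_right, y))
    return np.array([(x, y, z) for x, y in pts])


def path_distance(point, waypoints, planar: bool = True) -> float:
    """Perpendicular distance from a point to the desired polyline (m); 2D in
    the board plane by default (the trials are planar, viewed from above)."""
    p = np.asarray(point, float)
    line = np.asarray(waypoints, float)
    if planar:
        p = p[:2]
        line = line[:, :2]
    d, _, _ = _nearest_on_polyline(p, line)
    return d


@dataclass
class TrajectoryLog:
    """Per-tick record of a closed-loop run plus summary statistics."""

    time: list = field(default_factory=list)
    true_position: list = field(default_factory=list)
    true_heading: list = field(default_factory=list)
    est_position: list = field(default_factory=list)
    est_yaw: list = field(default_factory=list)
    est_pitch: list = field(default_factory=list)
    est_cost: list = field(default_factory=list)
    est_converged: list = field(default_factory=list)
    command: list = field(default_factory=list)        # (yaw, pitch, F)
    currents: list = field(default_factory=list)
    path_error: list = field(default_factory=list)     # true vs desired, 2D
    loc_error: list = field(default_factory=list)      # est vs true, 3D
    waypoints: np.ndarray | None = None
    seed: int | None = None
    completed: bool = False

    def append(self, t, true_pose: MagnetPose, est: DipolePoseResults,
               command, currents, waypoints):
        self.time.append(t)
        self.true_position.append(true_pose.position.copy())
        self.true_heading.append(true_pose.heading.copy())
        self.est_position.append(est.params[:3].copy())
        self.est_yaw.append(est.yaw)
        self.est_pitch.append(est.pitch)
        self.est_cost.append(est.cost)
        self.est_converged.append(est.converged)
        self.command.append(tuple(command))
        self.currents.append(np.asarray(currents).copy())
        self.path_error.append(path_distance(true_pose.position, waypoints))
        self.loc_error.append(float(np.linalg.norm(
            est.params[:3] - true_pose.position)))

    def to_dataframe(self) -> pd.DataFrame:
        tp = np.asarray(self.true_position)
        ep = np.asarray(self.est_position)
        cmd = np.asarray(self.command)
        df = pd.DataFrame({
            "time": self.time,
            "true_x": tp[:, 0], "true_y": tp[:, 1], "true_z": tp[:, 2],
            "est_x": ep[:, 0], "est_y": ep[:, 1], "est_z": ep[:, 2],
            "cmd_yaw": cmd[:, 0], "cmd_pitch": cmd[:, 1], "cmd_F": cmd[:, 2],
            "est_cost": self.est_cost, "converged": self.est_converged,
            "path_error": self.path_error, "loc_error": self.loc_error,
        })
        cur = np.asarray(self.currents)
        for k in range(cur.shape[1]):
            df[f"i{k}"] = cur[:, k]
        return df

    def summary(self) -> dict:
        pe = np.asarray(self.path_error) * 1e3     # mm
        le = np.asarray(self.loc_error) * 1e3
        return {
            "n_steps": len(self.time),
            "seed": self.seed,
            "completed": self.completed,
            "mean_path_error_mm": float(pe.mean()),
            "sd_path_error_mm": float(pe.std(ddof=1)) if len(pe) > 1 else 0.0,
            "max_path_error_mm": float(pe.max()),
            "mean_loc_error_mm": float(le.mean()),
            "sd_loc_error_mm": float(le.std(ddof=1)) if len(le) > 1 else 0.0,
            "max_loc_error_mm": float(le.max()),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


# ---------------------------------------------------------------------------
# Closed loop


@dataclass(frozen=True)
class ControllerOptions:
    """Waypoint-seeking proportional stand-in for the joystick operator."""

    push_gradient: float = 0.05      # T/m  (free-space preset: 5 mT / 50 mT/m)
    gamma: float = 0.1               # m, field:gradient ratio (1:10)
    control_rate: float = 20.0       # Hz
    capture_radius: float = 5e-3     # m, intermediate waypoints
    final_capture_radius: float = 1e-3   # m, terminal waypoint
    noise_sigma: float = 0.05e-3     # T, per-sensor additive
    tau_align: float = 0.05          # s
    max_ticks: int = 1500


def run_closed_loop(waypoints, env: Environment, config: EMAConfig,
                    array: SensorArray, spec: MagnetSpec,
                    options: ControllerOptions = ControllerOptions(),
                    seed: int = 0) -> TrajectoryLog:
    """Simulate tracking of a waypoint path under the full sense–estimate–
    actuate loop; deterministic given (inputs, seed).

    Each tick: synthesize a sensor frame at the active currents, estimate the
    pose (warm-started from the previous tick), steer toward the next
    waypoint, map the command to a (field, gradient) set-point, allocate coil
    currents, and advance the plant.  Aborts with a partial log after 10
    consecutive non-converged estimates.
    """
    waypoints = np.atleast_2d(np.asarray(waypoints, float))
    if len(waypoints) < 2:
        raise ValueError("need at least 2 waypoints")
    rng = np.random.default_rng(seed)
    dt = 1.0 / options.control_rate
    basis = coil_basis(config, array.positions)

    d0 = waypoints[1] - waypoints[0]
    state = CapsuleState(pose=MagnetPose(
        position=waypoints[0].copy(), heading=d0 / np.linalg.norm(d0)))
    currents = np.zeros(config.n_coils)
    log = TrajectoryLog(waypoints=waypoints, seed=seed)
    est = None
    wp_idx = 1
    bad_streak = 0

    for _ in range(options.max_ticks):
        frame = synth_sensor_frame(state, currents, array, spec, basis,
                                   options.noise_sigma, rng)
        est = estimate_pose(frame, basis, array, spec, init=est)
        bad_streak = 0 if est.converged else bad_streak + 1
        if bad_streak > 10:
            log.completed = False
            return log

        est_pos = est.params[:3]
        while (wp_idx < len(waypoints) - 1
               and np.linalg.norm(est_pos - waypoints[wp_idx])
               < options.capture_radius):
            wp_idx += 1
        target = waypoints[wp_idx]
        to_t = target - est_pos
        dist = np.linalg.norm(to_t)
        if wp_idx == len(waypoints) - 1 and dist < options.final_capture_radius:
            log.append(state.time, state.pose, est, (0.0, 0.0, 0.0),
                       np.zeros(config.n_coils), waypoints)
            log.completed = True
            return log

        yaw = float(np.arctan2(to_t[1], to_t[0]))
        pitch = float(np.arcsin(np.clip(to_t[2] / dist, -1.0, 1.0)))
        push = options.push_gradient
        if wp_idx == len(waypoints) - 1:
            # proportional slow-down on final approach to avoid overshoot
            push *= min(1.0, dist / options.capture_radius)
        desired = command_to_desired(yaw, pitch, push, options.gamma)
        eval_pt = np.clip(est_pos, config.roi.lo + 1e-3, config.roi.hi - 1e-3)
        X = build_actuation_matrix(config, eval_pt,
                                   heading_from_angles(yaw, pitch))
        currents = allocate_currents(X, desired)

        log.append(state.time, state.pose, est, (yaw, pitch, push),
                   currents, waypoints)
        state = step_dynamics(state, currents, env, config, spec, dt,
                              tau_align=options.tau_align)

    log.completed = False
    return log
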