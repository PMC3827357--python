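"""MARG sensor fusion: gradient-descent attitude filter and gravity removal.

The filter merges gyroscope, accelerometer, and magnetometer streams into a
per-sample unit quaternion (sensor-to-earth rotation) and uses it to split
the measured acceleration into a gravity projection and dynamic (propulsive)
acceleration, both expressed in the fish body frame.

Conventions
-----------
* Earth frame: x = magnetic north (horizontal), z = up; the earth gravity
  field vector is ``(0, 0, -g)``.
* Quaternions are stored ``(w, x, y, z)`` and map sensor-frame vectors into
  the earth frame; a logger at level rest facing north has the identity
  quaternion and reads ``(0, 0, -g)`` on its accelerometer.
* Angular velocity stays in deg s⁻¹ at the data-model level and is converted
  to rad s⁻¹ only inside the integrator.

The correction step descends the gradient of an objective aligning the
predicted gravity direction and predicted earth-frame magnetic reference
with the normalised accelerometer and magnetometer measurements; the earth
magnetic reference is recomputed each step from the rotated measurement
(horizontal norm + vertical component), which absorbs the local dip angle
without a fixed constant.  With gain ``beta = 0`` the filter reduces to pure
gyro dead-reckoning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .sensor_io import STANDARD_GRAVITY, SensorRecording, ValidationError

logger = logging.getLogger("finstart")


class DegenerateInputError(ValueError):
    """Zero-norm accelerometer or magnetometer input where one is required."""


@dataclass(frozen=True)
class FusionParams:
    """Filter configuration.

    beta
        Gradient-descent gain (dimensionless, rad s⁻¹ scale of the
        normalised correction).  0 disables accelerometer/magnetometer
        correction entirely.
    init_window
        Seconds of (assumed quasi-static) data used for the e-compass
        initial attitude.
    """

    beta: float = 0.1
    init_window: float = 0.5
    gravity_constant: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")
        if self.init_window <= 0:
            raise ValidationError("init_window must be > 0")


@dataclass
class AttitudeTrack:
    """Per-sample attitude and the additive acceleration decomposition.

    ``acc_measured == dyn_acc + gravity_sensor_frame`` holds exactly per
    sample, and every gravity vector has norm ``gravity_constant``.
    """

    quaternions: np.ndarray          # (n, 4), (w, x, y, z), unit norm
    gravity_sensor_frame: np.ndarray  # (n, 3), m s^-2
    dyn_acc: np.ndarray               # (n, 3), m s^-2, fish frame
    gravity_constant: float = STANDARD_GRAVITY


# ---------------------------------------------------------------------------
# quaternion primitives (w, x, y, z)
# ---------------------------------------------------------------------------

def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def rotate_to_earth(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate a sensor-frame vector into the earth frame (v_e = q v q*)."""
    w, qv = q[0], q[1:]
    c = np.cross(qv, v)
    return v + 2.0 * (np.cross(qv, c) + w * c)


def rotate_to_sensor(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate an earth-frame vector into the sensor frame (v_s = q* v q)."""
    w, qv = q[0], q[1:]
    c = np.cross(qv, v)
    return v + 2.0 * (np.cross(qv, c) - w * c)


def _jac_rotate_to_sensor(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Jacobian (3x4) of ``rotate_to_sensor(q, r)`` with respect to q."""
    w, qv = q[0], q[1:]
    rx = np.array([[0.0, -r[2], r[1]],
                   [r[2], 0.0, -r[0]],
                   [-r[1], r[0], 0.0]])
    J = np.empty((3, 4))
    J[:, 0] = -2.0 * np.cross(qv, r)
    J[:, 1:] = 2.0 * (
        np.dot(qv, r) * np.eye(3)
        + np.outer(qv, r)
        - 2.0 * np.outer(r, qv)
        + w * rx
    )
    return J


def quat_normalize(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if n == 0:
        raise DegenerateInputError("zero-norm quaternion")
    return q / n


def attitude_angle_deg(q1: np.ndarray, q2: np.ndarray) -> float:
    """Rotation angle (degrees) between two attitudes."""
    dq = quat_multiply(quat_conjugate(q1), q2)
    return float(np.degrees(2.0 * np.arccos(np.clip(abs(dq[0]), -1.0, 1.0))))


# ---------------------------------------------------------------------------
# initial attitude (e-compass / TRIAD construction)
# ---------------------------------------------------------------------------

def initial_attitude(acc_window: np.ndarray, mag_window: np.ndarray) -> np.ndarray:
    """Initial attitude from time-averaged accelerometer + magnetometer data.

    The averaged acceleration is taken as the gravity projection (quasi-static
    assumption): its negative is sensor-frame "up".  The horizontal component
    of the averaged magnetic vector defines sensor-frame north.  Deterministic.
    """
    acc_window = np.atleast_2d(acc_window)
    mag_window = np.atleast_2d(mag_window)
    a = np.mean(acc_window, axis=0)
    m = np.mean(mag_window, axis=0)
    if np.linalg.norm(a) < 1e-12:
        raise DegenerateInputError("mean acceleration has zero norm")
    if np.linalg.norm(m) < 1e-12:
        raise DegenerateInputError("mean magnetic vector has zero norm")
    up = -a / np.linalg.norm(a)                 # sensor-frame earth-up
    north = m - np.dot(m, up) * up              # horizontal component of field
    if np.linalg.norm(north) < 1e-12:
        raise DegenerateInputError("magnetic vector parallel to gravity")
    north /= np.linalg.norm(north)
    west = np.cross(up, north)
    # columns of R^T are the earth axes expressed in the sensor frame
    R = np.column_stack([north, west, up]).T
    q_xyzw = Rotation.from_matrix(R).as_quat()
    q = np.array([q_xyzw[3], *q_xyzw[:3]])
    return q if q[0] >= 0 else -q


# ---------------------------------------------------------------------------
# per-sample filter update
# ---------------------------------------------------------------------------

_EARTH_UP = np.array([0.0, 0.0, 1.0])


def fuse_step(
    q: np.ndarray,
    gyro_deg: np.ndarray,
    acc: np.ndarray,
    mag: np.ndarray,
    params: FusionParams,
    dt: float,
    _warn: list | None = None,
) -> np.ndarray:
    """One gradient-descent filter update over ``dt`` seconds.

    Steps: (a) quaternion rate from angular velocity, (b) gradient of the
    gravity + magnetic alignment objective, (c) corrected rate =
    gyro rate − beta × normalised gradient, (d) Euler integration and
    renormalisation.  A zero-norm accelerometer or magnetometer sample skips
    the correction (pure gyro integration) for that step.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    omega = np.radians(np.asarray(gyro_deg, dtype=float))
    qdot = 0.5 * quat_multiply(q, np.array([0.0, *omega]))

    if params.beta > 0:
        na, nm = np.linalg.norm(acc), np.linalg.norm(mag)
        if na < 1e-12 or nm < 1e-12:
            if _warn is not None and not _warn:
                logger.warning("zero-norm acc/mag sample: gyro-only step")
                _warn.append(True)
        else:
            ahat, mhat = np.asarray(acc) / na, np.asarray(mag) / nm
            # gravity objective: predicted earth "down" in sensor frame
            g_ref = -_EARTH_UP
            fg = rotate_to_sensor(q, g_ref) - ahat
            Jg = _jac_rotate_to_sensor(q, g_ref)
            # magnetic reference recomputed from the rotated measurement
            h = rotate_to_earth(q, mhat)
            b_ref = np.array([np.hypot(h[0], h[1]), 0.0, h[2]])
            fb = rotate_to_sensor(q, b_ref) - mhat
            Jb = _jac_rotate_to_sensor(q, b_ref)
            grad = Jg.T @ fg + Jb.T @ fb
            gnorm = np.linalg.norm(grad)
            if gnorm > 1e-15:
                qdot = qdot - params.beta * grad / gnorm

    return quat_normalize(q + qdot * dt)


def fuse(rec: SensorRecording, params: FusionParams = FusionParams()) -> AttitudeTrack:
    """Run the filter over a full recording.

    The first ``init_window`` seconds initialise the attitude; each
    subsequent sample advances it by one :func:`fuse_step`.  The gravity
    projection is the earth gravity vector rotated into the sensor frame, and
    ``dyn_acc = acc - gravity`` so the decomposition is additive by
    construction.
    """
    fs = rec.spec.sampling_rate
    n_init = max(1, int(round(params.init_window * fs)))
    if rec.n_samples < n_init:
        raise ValidationError(
            f"recording has {rec.n_samples} samples; "
            f"initialisation needs {n_init}"
        )
    dt = 1.0 / fs
    n = rec.n_samples
    quats = np.empty((n, 4))
    quats[0] = initial_attitude(rec.acc[:n_init], rec.mag[:n_init])
    warn: list = []
    q = quats[0]
    for i in range(1, n):
        q = fuse_step(q, rec.gyro[i], rec.acc[i], rec.mag[i], params, dt, _warn=warn)
        quats[i] = q

    g_earth = np.array([0.0, 0.0, -params.gravity_constant])
    rot = Rotation.from_quat(np.column_stack([quats[:, 1:], quats[:, :1]]))
    gravity = rot.apply(g_earth, inverse=True)
    return AttitudeTrack(
        quaternions=quats,
        gravity_sensor_frame=gravity,
        dyn_acc=rec.acc - gravity,
        gravity_constant=params.gravity_constant,
    )


__all__ = [
    "FusionParams", "AttitudeTrack", "DegenerateInputError",
    "quat_multiply", "quat_conjugate", "quat_normalize",
    "rotate_to_earth", "rotate_to_sensor", "attitude_angle_deg",
    "initial_attitude", "fuse_step", "fuse",
]
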