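"""Orientation estimation and gravity compensation for a foot-mounted IMU.

A Mahony complementary filter tracks the sensor orientation as a unit
quaternion. The accelerometer supplies an error signal — the cross product
between the normalized measured specific force and the gravity direction
predicted from the current attitude — which feeds a proportional-integral
correction of the gyroscope rates; the integral term absorbs constant gyro
bias. The corrected rates propagate the quaternion with a first-order
update followed by explicit renormalization.

Quaternion convention: scalar-last ``[q1, q2, q3, q4]`` (vector part first,
Hamilton product), representing the rotation from the sensor frame to the
navigation frame. ``quat_to_dcm`` returns the navigation-to-sensor
direction-cosine matrix C_ns, so the predicted sensor-frame gravity
direction is the third column of C_ns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, sosfilt

from .config import FilterSpec, MahonyConfig
from .io import G, ImuRecording

log = logging.getLogger(__name__)

_QUAT_TOL = 1e-6


def detect_stationary(gyr_s: np.ndarray, threshold: float = 0.0436) -> np.ndarray:
    """Per-sample stationarity mask: Euclidean gyro norm strictly below threshold.

    0.0436 rad/s (2.5 deg/s) marks "minimal movement" intervals used to
    estimate the initial gravity direction.
    """
    gyr_s = np.atleast_2d(np.asarray(gyr_s, dtype=float))
    if gyr_s.size == 0:
        raise ValueError("empty recording")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.linalg.norm(gyr_s, axis=1) < threshold


def estimate_initial_gravity(acc_s: np.ndarray, stationary_mask: np.ndarray):
    """Mean sensor-frame gravity over stationary samples and the matching
    initial attitude.

    Returns ``(g_vec, q0)`` where ``g_vec`` is the component-wise mean of
    ``acc_s`` over the mask and ``q0`` is the zero-yaw unit quaternion that
    rotates ``g_vec`` onto the navigation +z axis.
    """
    acc_s = np.atleast_2d(np.asarray(acc_s, dtype=float))
    mask = np.asarray(stationary_mask, dtype=bool)
    if not mask.any():
        raise ValueError(
            "no stationary samples found; supply an initial orientation explicitly"
        )
    g_vec = acc_s[mask].mean(axis=0)
    norm = np.linalg.norm(g_vec)
    if norm == 0:
        raise ValueError("stationary acceleration averages to zero; cannot orient")
    ghat = g_vec / norm
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(ghat, ez), -1.0, 1.0))
    axis = np.cross(ghat, ez)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            q0 = np.array([0.0, 0.0, 0.0, 1.0])
        else:  # upside down: 180 deg about x (yaw-free choice)
            q0 = np.array([1.0, 0.0, 0.0, 0.0])
    else:
        axis = axis / s
        half = 0.5 * math.atan2(s, c)
        q0 = np.array([*(math.sin(half) * axis), math.cos(half)])
    return g_vec, q0


def quat_to_dcm(q: np.ndarray) -> np.ndarray:
    """Navigation-to-sensor direction-cosine matrix for a scalar-last unit
    quaternion. Raises if ``q`` is not unit within 1e-6."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > _QUAT_TOL:
        raise ValueError(f"quaternion norm {n:.3g} deviates from 1 beyond tolerance")
    q1, q2, q3, q4 = q
    return np.array(
        [
            [1 - 2 * q2 * q2 - 2 * q3 * q3, 2 * (q1 * q2 + q3 * q4), 2 * (q1 * q3 - q2 * q4)],
            [2 * (q1 * q2 - q3 * q4), 1 - 2 * q1 * q1 - 2 * q3 * q3, 2 * (q2 * q3 + q1 * q4)],
            [2 * (q1 * q3 + q2 * q4), 2 * (q2 * q3 - q1 * q4), 1 - 2 * q1 * q1 - 2 * q2 * q2],
        ]
    )


def mahony_step(
    q: np.ndarray,
    gyr_sample: np.ndarray,
    acc_sample: np.ndarray,
    kp: float,
    ki: float,
    integral_state: np.ndarray,
    dt: float,
    acc_gate_tol: float = math.inf,
):
    """One proportional-integral attitude update.

    The error is the cross product of the unit-normalized measured
    acceleration with the predicted sensor-frame gravity direction. When
    the specific-force magnitude is (near) zero — free fall or dropout —
    or outside the optional gate around g, the correction is skipped and
    the quaternion propagates on gyro alone.

    Returns ``(q', integral_state')``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-3:
        raise ValueError("quaternion must be unit")
    q1, q2, q3, q4 = q
    wx, wy, wz = (float(v) for v in gyr_sample)
    ax, ay, az = (float(v) for v in acc_sample)
    ix, iy, iz = (float(v) for v in integral_state)

    # predicted gravity direction in the sensor frame: third column of C_ns
    gx = 2.0 * (q1 * q3 - q2 * q4)
    gy = 2.0 * (q2 * q3 + q1 * q4)
    gz = 1.0 - 2.0 * q1 * q1 - 2.0 * q2 * q2

    anorm = math.sqrt(ax * ax + ay * ay + az * az)
    if anorm > 1e-9 and abs(anorm - G) <= acc_gate_tol * G:
        ax, ay, az = ax / anorm, ay / anorm, az / anorm
        ex = ay * gz - az * gy
        ey = az * gx - ax * gz
        ez = ax * gy - ay * gx
        ix += ex * dt
        iy += ey * dt
        iz += ez * dt
        wx += kp * ex + ki * ix
        wy += kp * ey + ki * iy
        wz += kp * ez + ki * iz

    # first-order quaternion propagation with the corrected rates
    h = 0.5 * dt
    nq4 = q4 - h * (wx * q1 + wy * q2 + wz * q3)
    nq1 = q1 + h * (wx * q4 + wz * q2 - wy * q3)
    nq2 = q2 + h * (wy * q4 + wx * q3 - wz * q1)
    nq3 = q3 + h * (wz * q4 + wy * q1 - wx * q2)
    inv = 1.0 / math.sqrt(nq1 * nq1 + nq2 * nq2 + nq3 * nq3 + nq4 * nq4)
    qn = np.array([nq1 * inv, nq2 * inv, nq3 * inv, nq4 * inv])
    return qn, np.array([ix, iy, iz])


def compensate_gravity(acc_s_sample: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rotate a sensor-frame specific force into the navigation frame and
    remove gravity: ``a_n = C_ns(q)^T a_s - (0, 0, g)``."""
    C = quat_to_dcm(q)
    return C.T @ np.asarray(acc_s_sample, dtype=float) - np.array([0.0, 0.0, G])


@dataclass
class OrientationTrace:
    """Per-sample attitude and gravity-compensated navigation-frame
    acceleration."""

    q: np.ndarray  # (n, 4) scalar-last unit quaternions
    acc_n: np.ndarray  # (n, 3) m/s^2, gravity removed
    integral_state: np.ndarray  # final PI integral term


def mahony_filter(
    rec: ImuRecording,
    mahony: MahonyConfig | None = None,
    stationary_threshold: float = 0.0436,
    q0: np.ndarray | None = None,
) -> OrientationTrace:
    """Run the complementary filter over a full recording.

    The initial attitude comes from averaging acceleration over the
    stationary samples unless ``q0`` is given.
    """
    mahony = mahony or MahonyConfig()
    if q0 is None:
        mask = detect_stationary(rec.gyr_s, stationary_threshold)
        _, q0 = estimate_initial_gravity(rec.acc_s, mask)
        log.info("stationary fraction %.2f", mask.mean())
    n = rec.n_samples
    dt = 1.0 / rec.fs
    qs = np.empty((n, 4))
    qs[0] = q0
    q = np.asarray(q0, dtype=float)
    integ = np.zeros(3)
    for i in range(1, n):
        q, integ = mahony_step(
            q,
            rec.gyr_s[i],
            rec.acc_s[i],
            mahony.kp,
            mahony.ki,
            integ,
            dt,
            acc_gate_tol=mahony.acc_gate_tol,
        )
        qs[i] = q

    # vectorized C_ns^T a_s - g_n using the stored quaternions
    q1, q2, q3, q4 = qs[:, 0], qs[:, 1], qs[:, 2], qs[:, 3]
    a = rec.acc_s
    # rows of C_ns^T are the columns of C_ns
    acc_n = np.empty_like(a)
    acc_n[:, 0] = (
        (1 - 2 * q2**2 - 2 * q3**2) * a[:, 0]
        + 2 * (q1 * q2 - q3 * q4) * a[:, 1]
        + 2 * (q1 * q3 + q2 * q4) * a[:, 2]
    )
    acc_n[:, 1] = (
        2 * (q1 * q2 + q3 * q4) * a[:, 0]
        + (1 - 2 * q1**2 - 2 * q3**2) * a[:, 1]
        + 2 * (q2 * q3 - q1 * q4) * a[:, 2]
    )
    acc_n[:, 2] = (
        2 * (q1 * q3 - q2 * q4) * a[:, 0]
        + 2 * (q2 * q3 + q1 * q4) * a[:, 1]
        + (1 - 2 * q1**2 - 2 * q2**2) * a[:, 2]
        - G
    )
    resid = np.linalg.norm(acc_n[n // 2 :].mean(axis=0))
    log.info("orientation convergence residual (second half) %.4f m/s^2", resid)
    return OrientationTrace(q=qs, acc_n=acc_n, integral_state=integ)


def butterworth_lowpass(signal: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Low-pass a signal (per column for 2-D input), zero-phase by default.

    Zero-phase (forward-backward) filtering keeps event timestamps
    unshifted; the effective attenuation is the squared single-pass
    magnitude response.
    """
    spec = spec or FilterSpec()
    if spec.cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] <= 3 * spec.order:
        raise ValueError("signal too short for the filter order")
    sos = butter(spec.order, spec.cutoff_hz / (fs / 2), output="sos")
    if spec.zero_phase:
        return sosfiltfilt(sos, signal, axis=0)
    return sosfilt(sos, signal, axis=0)
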