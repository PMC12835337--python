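"""ZUPT-anchored stride reconstruction.

Navigation-frame, gravity-compensated acceleration is integrated between
consecutive mid-stance anchors, where the foot is mechanically stationary,
so each interval starts from zero velocity. The residual endpoint velocity
— accumulated integration drift — is removed by subtracting a linear ramp
(weight j/n per sample), which enforces zero velocity exactly at both
anchors and annihilates any drift linear in time. A second (trapezoidal)
integration yields the per-stride displacement; stride length is the
horizontal-plane resultant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

log = logging.getLogger(__name__)


def integrate_velocity(acc_n: np.ndarray, i0: int, i1: int, fs: float) -> np.ndarray:
    """Cumulative trapezoidal velocity over samples ``[i0, i1]`` with
    v(start) = 0 on all axes."""
    if i1 - i0 < 3:
        raise ValueError("integration interval shorter than 3 samples")
    seg = np.asarray(acc_n[i0 : i1 + 1], dtype=float)
    return cumulative_trapezoid(seg, dx=1.0 / fs, axis=0, initial=0.0)


def drift_correct(v_raw: np.ndarray) -> np.ndarray:
    """Linearly redistribute the endpoint velocity error: per axis,
    ``v_corr[j] = v_raw[j] - (j/n) * v_raw[n]``. Idempotent; exact zero at
    both ends."""
    v_raw = np.asarray(v_raw, dtype=float)
    n = v_raw.shape[0] - 1
    if n < 1:
        raise ValueError("velocity trace too short")
    w = (np.arange(n + 1) / n).reshape(-1, *([1] * (v_raw.ndim - 1)))
    return v_raw - w * v_raw[-1]


def stride_displacement(v_corr: np.ndarray, fs: float):
    """Net displacement (trapezoidal) over the interval and the stride
    length — the horizontal-plane resultant sqrt(dx^2 + dy^2)."""
    v_corr = np.asarray(v_corr, dtype=float)
    disp = np.trapezoid(v_corr, dx=1.0 / fs, axis=0)
    sl = float(np.hypot(disp[0], disp[1]))
    return disp, sl


@dataclass
class StrideKinematics:
    """Velocity and displacement of one anchor-to-anchor interval."""

    interval: tuple  # (start_s, end_s)
    v_raw: np.ndarray
    v_corr: np.ndarray
    disp: np.ndarray
    stride_length: float


def reconstruct_strides(
    t: np.ndarray, acc_n: np.ndarray, anchors: np.ndarray, fs: float
) -> list:
    """ZUPT reconstruction between consecutive anchor timestamps
    (mid-stance instants). Returns one :class:`StrideKinematics` per
    consecutive anchor pair."""
    out = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        i0 = int(np.floor((a - t[0]) * fs + 0.5))
        i1 = int(np.floor((b - t[0]) * fs + 0.5))
        v_raw = integrate_velocity(acc_n, i0, i1, fs)
        v_corr = drift_correct(v_raw)
        disp, sl = stride_displacement(v_corr, fs)
        out.append(
            StrideKinematics(
                interval=(float(t[i0]), float(t[i1])),
                v_raw=v_raw,
                v_corr=v_corr,
                disp=disp,
                stride_length=sl,
            )
        )
    log.info("reconstructed %d stride intervals", len(out))
    return out
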