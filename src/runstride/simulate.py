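"""Synthetic foot-mounted IMU recordings of running with exact ground truth.

The generator builds an analytic foot trajectory in the navigation frame
and maps it through a time-varying sagittal rotation into sensor-frame
specific force and angular rate, then adds Gaussian sensor noise and a
constant gyro bias. Because the trajectory is analytic, every event time
and every stride parameter is known exactly, standing in for an optical /
force-plate reference.

Trajectory conventions (synthetic, chosen for the qualitative morphology
of real foot-IMU running signals; see docs/methods.md):

* Each stride runs foot-strike to foot-strike (period ``stride_time``),
  with a stationary stance of ``contact_time`` and a swing that translates
  the foot forward by ``stride_length``.
* Forward velocity is a ramp-plateau-ramp: a Hann-shaped propulsive
  acceleration lobe centred exactly on TC and a Hann braking lobe centred
  exactly on IC. Centring the lobes on the events puts the kinetic event
  markers (propulsive / braking acceleration peaks) at the true instants —
  zero-phase filtering keeps a symmetric lobe's extremum at its centre —
  at the price of brief foot motion bleeding ~0.13 swing-durations into
  the adjacent stance edges, as a real foot's push-off and landing do.
* Sagittal pitch rate is a wide positive mid-swing lobe (peak
  ``peak_pitch_rate`` at the exact swing midpoint) plus negative toe-off
  and foot-strike dips; lobe areas balance so the foot returns to flat
  every stride. A rearfoot strike centres the foot-strike dip on IC; a
  forefoot strike attenuates, broadens and advances it, reproducing the
  early-trigger failure mode of conventional angular-velocity detection.
* Vertical motion is a raised-sine lift of ``foot_lift`` during swing.

The central portion of every stance is exactly stationary, which is what
mid-stance detection and the zero-velocity update require.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .io import G, ImuRecording

# morphology constants, as fractions of the swing duration
_W_PUSH = 0.13  # half-width of the propulsive acceleration lobe
_W_LAND = 0.13  # half-width of the braking acceleration lobe
_W_MSW = 0.28  # half-width of the mid-swing pitch-rate lobe
_PED_AMP = 1.0  # rad/s, late-swing positive pedestal bridging lobe to dip
_PED_START = 0.20  # pedestal start relative to mid-swing
_W_TC_DIP = {"rearfoot": 0.20, "forefoot": 0.232}  # heel-rise / toe-off dip half-width
_C_TC_DIP = 0.02  # toe-off dip centre relative to TC
# foot-strike dip: its minimum gives the conventional negative-peak IC and
# its onset pins the angular-velocity zero-crossing; a forefoot strike
# advances both and flattens the dip (amplitude relative to
# peak_pitch_rate; the toe-off dip amplitude is solved from the
# zero-net-rotation balance)
_W_IC_DIP = {"rearfoot": 0.115, "forefoot": 0.10}
_C_IC_DIP = {"rearfoot": 0.045, "forefoot": -0.08}  # centre relative to IC
_AMP_IC_REL = {"rearfoot": 1.25, "forefoot": 0.625}
_ADV_BRAKE = {"rearfoot": 0.0, "forefoot": -0.01}  # braking-lobe centre shift


class GaitProfile(BaseModel):
    """Study conditions for one simulated trial.

    Defaults follow the validated operating range of over-ground running
    at a self-selected comfortable speed: stride time 0.74 s, contact time
    0.308 s, stride length 1.93 m (hence ~2.6 m/s), 200 Hz sampling, and
    consumer-IMU noise (sigma_acc 0.3 m/s^2, sigma_gyr 0.01 rad/s,
    constant gyro bias 0.005 rad/s).
    """

    model_config = ConfigDict(extra="forbid")

    n_strides: int = 12
    stride_time: float = 0.74
    contact_time: float = 0.308
    stride_length: float = 1.93
    peak_pitch_rate: float = 8.0
    foot_lift: float = 0.10
    strike_pattern: str = "rearfoot"
    mounting_tilt_deg: float = 8.0
    mass_kg: float = 75.2
    lead_in_s: float = 2.0
    tail_s: float = 1.0
    fs: float = 200.0
    sigma_acc: float = 0.3
    sigma_gyr: float = 0.01
    gyro_bias: float = 0.005
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_strides < 2:
            raise ValueError("need at least 2 strides")
        if not 0 < self.contact_time < self.stride_time:
            raise ValueError("contact_time must lie in (0, stride_time)")
        for name in ("stride_length", "fs", "mass_kg", "lead_in_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_pitch_rate < 3.0:
            raise ValueError("peak_pitch_rate below 3 rad/s gives an undetectable mid-swing")
        if self.strike_pattern not in ("rearfoot", "forefoot"):
            raise ValueError("strike_pattern must be 'rearfoot' or 'forefoot'")
        if min(self.sigma_acc, self.sigma_gyr, self.gyro_bias, self.tail_s, self.foot_lift) < 0:
            raise ValueError("noise levels, tail and foot lift must be non-negative")
        return self


@dataclass
class SyntheticGroundTruth:
    """Exact event times and stride parameters of a simulated trial."""

    ic: np.ndarray  # (n_strides + 1,) foot-strike times, s
    tc: np.ndarray  # (n_strides,)
    ms: np.ndarray  # (n_strides,) mid-stance (stationary centre), s
    msw: np.ndarray  # (n_strides,) mid-swing, s
    params: "object"  # per-stride DataFrame: st, ct, swt, ft, sl, sv, sf, peak_vgrf_bw
    vgrf_t25: np.ndarray  # (n_strides, 2) 25 N threshold crossings within stance, s
    profile: GaitProfile = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "ic": self.ic.tolist(),
            "tc": self.tc.tolist(),
            "ms": self.ms.tolist(),
            "msw": self.msw.tolist(),
            "params": self.params.to_dict(orient="list"),
            "vgrf_t25": self.vgrf_t25.tolist(),
            "profile": self.profile.model_dump() if self.profile else None,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def _hann(t: np.ndarray, c: float, w: float) -> np.ndarray:
    """Unit-peak Hann bump on [c - w, c + w]."""
    u = (t - c) / w
    out = np.zeros_like(t)
    m = np.abs(u) < 1.0
    out[m] = 0.5 * (1.0 + np.cos(np.pi * u[m]))
    return out


def _ramp(t: np.ndarray, c: float, w: float) -> np.ndarray:
    """Integral of the unit-area-normalized Hann bump: smooth 0 -> 1 step."""
    u = np.clip((t - c) / w, -1.0, 1.0)
    return 0.5 * (u + 1.0) + np.sin(np.pi * u) / (2.0 * np.pi)


def _trajectory(profile: GaitProfile, t: np.ndarray):
    """Analytic navigation-frame kinematics and sagittal pitch.

    Returns (a_n (n,3), v_n (n,3), pitch (n,), pitch_rate (n,)).
    """
    p = profile
    T = p.stride_time - p.contact_time  # swing duration
    t0 = p.lead_in_s
    ics = t0 + np.arange(p.n_strides + 1) * p.stride_time
    tcs = ics[:-1] + p.contact_time

    adv = _ADV_BRAKE[p.strike_pattern] * T
    wp, wl = _W_PUSH * T, _W_LAND * T
    V = p.stride_length / (T + adv)  # plateau speed; lands exactly stride_length apart

    a_y = np.zeros_like(t)
    v_y = np.zeros_like(t)
    a_z = np.zeros_like(t)
    v_z = np.zeros_like(t)
    rate = np.zeros_like(t)
    angle = np.zeros_like(t)

    w_msw = _W_MSW * T
    w_tc = _W_TC_DIP[p.strike_pattern] * T
    w_ic = _W_IC_DIP[p.strike_pattern] * T
    c_ic_off = _C_IC_DIP[p.strike_pattern] * T
    amp_msw = p.peak_pitch_rate
    amp_ic = _AMP_IC_REL[p.strike_pattern] * p.peak_pitch_rate
    # late-swing pedestal: spans from inside the mid-swing lobe to the
    # foot-strike dip onset so the pitch rate stays positive until the dip
    dip_onset = c_ic_off - w_ic  # relative to IC (negative)
    ped_lo = 0.5 * T + _PED_START * T  # relative to TC
    ped_hi = T + dip_onset
    w_ped = 0.5 * (ped_hi - ped_lo)
    c_ped = 0.5 * (ped_hi + ped_lo)
    # the toe-off dip absorbs the remaining rotation: zero net per stride
    amp_tc = (amp_msw * w_msw + _PED_AMP * w_ped - amp_ic * w_ic) / w_tc

    for i in range(p.n_strides):
        tc_i, ic_next = tcs[i], ics[i + 1]
        # forward: push lobe centred on TC, braking lobe centred on IC
        a_y += (V / wp) * _hann(t, tc_i, wp) - (V / wl) * _hann(t, ic_next + adv, wl)
        v_y += V * (_ramp(t, tc_i, wp) - _ramp(t, ic_next + adv, wl))
        # vertical: raised-sine lift over the swing
        tau = (t - tc_i) / T
        m = (tau >= 0.0) & (tau <= 1.0)
        a_z[m] += 2.0 * p.foot_lift * (np.pi / T) ** 2 * np.cos(2 * np.pi * tau[m])
        v_z[m] += p.foot_lift * (np.pi / T) * np.sin(2 * np.pi * tau[m])
        # sagittal pitch rate: heel-rise/toe-off dip, mid-swing lobe,
        # late-swing pedestal, foot-strike dip
        msw_i = tc_i + 0.5 * T
        for amp, c, w in (
            (amp_msw, msw_i, w_msw),
            (_PED_AMP, tc_i + c_ped, w_ped),
            (-amp_tc, tc_i + _C_TC_DIP * T, w_tc),
            (-amp_ic, ic_next + c_ic_off, w_ic),
        ):
            rate += amp * _hann(t, c, w)
            angle += amp * w * _ramp(t, c, w)

    a_n = np.column_stack([np.zeros_like(t), a_y, a_z])
    v_n = np.column_stack([np.zeros_like(t), v_y, v_z])
    return a_n, v_n, angle, rate


def _ground_truth(profile: GaitProfile) -> SyntheticGroundTruth:
    import pandas as pd

    p = profile
    T = p.stride_time - p.contact_time
    t0 = p.lead_in_s
    ics = t0 + np.arange(p.n_strides + 1) * p.stride_time
    tcs = ics[:-1] + p.contact_time
    msw = tcs + 0.5 * T
    ms = ics[:-1] + 0.5 * p.contact_time
    st = np.full(p.n_strides, p.stride_time)
    ct = np.full(p.n_strides, p.contact_time)
    swt = st - ct
    ft = 0.5 * (swt - ct)
    bw = 0.5 * np.pi * (np.maximum(ft, 0.0) / ct + 1.0)
    params = pd.DataFrame(
        {
            "stride_id": np.arange(p.n_strides),
            "ic": ics[:-1],
            "tc": tcs,
            "ms": ms,
            "st": st,
            "ct": ct,
            "swt": swt,
            "ft": ft,
            "sl": np.full(p.n_strides, p.stride_length),
            "sv": np.full(p.n_strides, p.stride_length / p.stride_time),
            "sf": np.full(p.n_strides, 120.0 / p.stride_time),
            "peak_vgrf_bw": bw,
        }
    )
    # 25 N force-threshold convention of a force-plate reference applied to
    # the modelled half-sine vGRF: crossings sit just inside (0, CT)
    fmax_n = bw * p.mass_kg * G
    frac = np.clip(25.0 / fmax_n, 0.0, 1.0)
    dt25 = (ct / np.pi) * np.arcsin(frac)
    t25 = np.column_stack([ics[:-1] + dt25, tcs - dt25])
    return SyntheticGroundTruth(
        ic=ics, tc=tcs, ms=ms, msw=msw, params=params, vgrf_t25=t25, profile=p
    )


def simulate_run(profile: GaitProfile | None = None) -> tuple[ImuRecording, SyntheticGroundTruth]:
    """Simulate one trial; returns the sensor recording and its truth.

    The recording covers a stationary lead-in (foot flat at the mounting
    tilt), ``n_strides`` strides, and a stationary tail. Identical
    profiles (same seed) give bit-identical recordings.
    """
    p = profile or GaitProfile()
    duration = p.lead_in_s + p.n_strides * p.stride_time + p.contact_time + p.tail_s
    n = int(round(duration * p.fs))
    t = np.arange(n) / p.fs

    a_n, _, angle, rate = _trajectory(p, t)
    phi = math.radians(p.mounting_tilt_deg) + angle

    # sensor-frame specific force: f_s = C_ns(phi) (a_n + g_n)
    f_y = a_n[:, 1]
    f_z = a_n[:, 2] + G
    c, s = np.cos(phi), np.sin(phi)
    acc_s = np.column_stack([np.zeros_like(t), c * f_y + s * f_z, -s * f_y + c * f_z])
    gyr_s = np.column_stack([rate, np.zeros_like(t), np.zeros_like(t)])

    rng = np.random.default_rng(p.seed)
    acc_s = acc_s + rng.normal(0.0, p.sigma_acc, acc_s.shape)
    gyr_s = gyr_s + p.gyro_bias + rng.normal(0.0, p.sigma_gyr, gyr_s.shape)

    rec = ImuRecording(t, acc_s, gyr_s, fs=p.fs)
    return rec, _ground_truth(p)


def simulate_strike_pattern_shift(profile: GaitProfile, pattern: str):
    """The same trial with the strike pattern switched.

    Only the stance-adjacent signal shape changes (pre-IC pitch dip and
    braking-lobe placement); the true event times are identical.
    """
    variant = profile.model_copy(update={"strike_pattern": pattern})
    return simulate_run(variant)
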