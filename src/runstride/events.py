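"""Gait-event detection for running from a foot-mounted IMU.

Strides are segmented at mid-swing (MSW), the positive peaks of the
filtered sagittal angular velocity that exceed an adaptive threshold
(signal mean + k·SD). Within each stride the detectors localize:

* IC (initial contact) — conventionally (AVGS) the negative angular-velocity
  peak or its zero-crossing refinement; the fused detector reconciles the
  zero-crossing (kinematic marker) with the braking peak of the
  anterior-posterior acceleration (kinetic marker) inside a stride-adaptive
  window, weighting the accelerometer candidate dominantly.
* TC (terminal contact) — fused from the angular-velocity inflection near
  the toe-off dip and the propulsive (positive anterior) acceleration peak
  inside a forward-projected window.
* MS (mid-stance) — the quasi-stationary ZUPT anchor, from sliding-window
  minima of gyro energy and horizontal acceleration variance combined with
  a variance-continuity weight.

All timestamps are float seconds; sub-sample positions come from linear
interpolation. Sample indices round half-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import IcConfig, MsConfig, MswConfig, TcConfig

log = logging.getLogger(__name__)


def _time_to_idx(t: np.ndarray, time: float, fs: float) -> int:
    """Nearest sample index for a float timestamp (round half-up)."""
    i = int(np.floor((time - t[0]) * fs + 0.5))
    return min(max(i, 0), len(t) - 1)


def detect_msw(
    wx: np.ndarray,
    fs: float,
    k_sigma: float = 1.0,
    min_separation_s: float = 0.4,
    t0: float = 0.0,
    min_peak_rads: float = 1.0,
) -> np.ndarray:
    """Mid-swing timestamps: adaptive-threshold positive peaks of the
    filtered sagittal angular velocity.

    Threshold = mean(wx) + k_sigma·SD(wx), floored at ``min_peak_rads`` so
    a stride-free recording yields no events. Peaks closer than
    ``min_separation_s`` are deduplicated keeping the larger amplitude
    (ties: the earlier peak). Raises when fewer than two peaks survive
    (no complete stride).
    """
    wx = np.asarray(wx, dtype=float)
    if len(wx) < fs:
        raise ValueError("signal shorter than 1 s; cannot segment strides")
    theta = max(wx.mean() + k_sigma * wx.std(), min_peak_rads)
    # interior local maxima above the adaptive threshold
    idx = np.nonzero((wx[1:-1] > wx[:-2]) & (wx[1:-1] >= wx[2:]) & (wx[1:-1] > theta))[0] + 1
    if len(idx) == 0:
        raise ValueError("no complete stride: no peaks above the adaptive threshold")
    order = sorted(idx, key=lambda i: (-wx[i], i))
    min_gap = min_separation_s * fs
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(i)
    kept.sort()
    if len(kept) < 2:
        raise ValueError("no complete stride: fewer than two mid-swing peaks")
    log.info("detected %d mid-swing peaks (threshold %.2f rad/s)", len(kept), theta)
    return t0 + np.asarray(kept) / fs


def _zero_crossings_down(t: np.ndarray, wx: np.ndarray, i_lo: int, i_hi: int) -> list[float]:
    """Interpolated times of positive-to-non-positive crossings in [i_lo, i_hi]."""
    out = []
    for i in range(i_lo, min(i_hi, len(wx) - 1)):
        if wx[i] > 0 >= wx[i + 1]:
            frac = wx[i] / (wx[i] - wx[i + 1]) if wx[i] != wx[i + 1] else 0.0
            out.append(float(t[i] + frac * (t[i + 1] - t[i])))
    return out


def detect_ic_avgs(
    t: np.ndarray,
    wx: np.ndarray,
    fs: float,
    window: tuple[float, float],
    negpeak_frac: float = 0.6,
):
    """Conventional angular-velocity IC estimates within one stride window.

    Returns ``(ic_negpeak, ic_zerocross)``: the negative-peak time over the
    first ``negpeak_frac`` of the stride, and the first interpolated
    positive-to-non-positive crossing after mid-swing (``None`` when the
    signal never crosses).
    """
    i_lo = _time_to_idx(t, window[0], fs)
    i_hi = _time_to_idx(t, window[1], fs)
    if i_hi <= i_lo + 1:
        raise ValueError("degenerate stride window")
    i_cut = i_lo + max(2, int(round(negpeak_frac * (i_hi - i_lo))))
    seg = wx[i_lo : min(i_cut, i_hi) + 1]
    ic_negpeak = float(t[i_lo + int(np.argmin(seg))])
    crossings = _zero_crossings_down(t, wx, i_lo, i_hi)
    ic_zerocross = crossings[0] if crossings else None
    return ic_negpeak, ic_zerocross


def detect_ic_fused(
    t: np.ndarray,
    wx: np.ndarray,
    a_ap: np.ndarray,
    fs: float,
    ic_coarse: float,
    stride_duration: float,
    stride_window: tuple[float, float],
    cfg: IcConfig | None = None,
):
    """Fused IC: weighted combination of the angular-velocity zero-crossing
    (kinematic) and the braking-peak |a_ap| maximum (kinetic) inside a
    window of ``window_frac`` of the stride centred on the coarse estimate.

    Returns ``(ic, candidates, flags)``.
    """
    cfg = cfg or IcConfig()
    half = 0.5 * cfg.window_frac * stride_duration
    lo = max(ic_coarse - half, stride_window[0])
    hi = min(ic_coarse + half, stride_window[1])
    i_lo, i_hi = _time_to_idx(t, lo, fs), _time_to_idx(t, hi, fs)
    flags: list[str] = []
    candidates = {"kinematic": None, "kinetic": None}
    if i_hi <= i_lo:
        return ic_coarse, candidates, ["empty_ic_window"]
    seg = np.abs(a_ap[i_lo : i_hi + 1])
    t_kinetic = float(t[i_lo + int(np.argmax(seg))])
    candidates["kinetic"] = t_kinetic
    crossings = _zero_crossings_down(t, wx, i_lo, i_hi)
    if crossings:
        t_kinematic = min(crossings, key=lambda c: abs(c - ic_coarse))
        candidates["kinematic"] = t_kinematic
        ic = cfg.w_acc * t_kinetic + (1.0 - cfg.w_acc) * t_kinematic
    else:
        flags.append("no_kinematic_ic")
        ic = t_kinetic
    return float(ic), candidates, flags


def detect_tc_avgs(
    t: np.ndarray,
    wx: np.ndarray,
    fs: float,
    ic: float,
    stride_duration: float,
    lo_frac: float = 0.1,
    hi_frac: float = 0.6,
) -> float:
    """Conventional toe-off: the angular-velocity minimum (toe-off dip)
    inside the forward-projected window after IC."""
    i_lo = _time_to_idx(t, ic + lo_frac * stride_duration, fs)
    i_hi = _time_to_idx(t, ic + hi_frac * stride_duration, fs)
    if i_hi <= i_lo:
        raise ValueError("empty toe-off search window")
    return float(t[i_lo + int(np.argmin(wx[i_lo : i_hi + 1]))])


def detect_tc_fused(
    t: np.ndarray,
    wx: np.ndarray,
    a_ap: np.ndarray,
    fs: float,
    ic: float,
    stride_duration: float,
    cfg: TcConfig | None = None,
):
    """Fused TC: weighted combination of the angular-velocity inflection
    nearest the conventional toe-off dip (kinematic) and the propulsive
    positive a_ap peak (kinetic) inside the forward window.

    Returns ``(tc, candidates, flags)``; ``tc > ic`` is guaranteed by
    falling back to the toe-off dip when the fusion degenerates.
    """
    cfg = cfg or TcConfig()
    i_lo = _time_to_idx(t, ic + cfg.search_lo_frac * stride_duration, fs)
    i_hi = _time_to_idx(t, ic + cfg.search_hi_frac * stride_duration, fs)
    flags: list[str] = []
    candidates = {"kinematic": None, "kinetic": None}
    if i_hi <= i_lo + 2:
        return ic + 0.5 * cfg.search_hi_frac * stride_duration, candidates, ["empty_tc_window"]
    tc_avgs = float(t[i_lo + int(np.argmin(wx[i_lo : i_hi + 1]))])
    seg = a_ap[i_lo : i_hi + 1]
    t_kinetic = float(t[i_lo + int(np.argmax(seg))])
    candidates["kinetic"] = t_kinetic
    # inflection: zero crossing of the second difference nearest the dip
    d2 = np.gradient(np.gradient(wx))
    infl = []
    for i in range(i_lo, i_hi):
        if d2[i] == 0.0 or (d2[i] < 0 < d2[i + 1]) or (d2[i] > 0 > d2[i + 1]):
            denom = d2[i] - d2[i + 1]
            frac = d2[i] / denom if denom != 0 else 0.0
            infl.append(float(t[i] + frac * (t[i + 1] - t[i])))
    if infl:
        t_kinematic = min(infl, key=lambda c: abs(c - tc_avgs))
        candidates["kinematic"] = t_kinematic
        tc = cfg.w_acc * t_kinetic + (1.0 - cfg.w_acc) * t_kinematic
    else:
        flags.append("no_kinematic_tc")
        tc = t_kinetic
    if tc <= ic:
        flags.append("tc_fallback_avgs")
        tc = tc_avgs
    return float(tc), candidates, flags


def ms_weight(var_a: float, prev_var: float | None) -> float:
    """Variance-continuity weight between the gyro-energy and
    acceleration-variance mid-stance candidates:
    ``w = var / (var + |var - prev_var|)``, clamped to [0, 1]; the first
    stride (no previous variance) takes w = 1."""
    if prev_var is None:
        return 1.0
    denom = var_a + abs(var_a - float(prev_var))
    if denom <= 0:
        return 1.0
    return min(max(var_a / denom, 0.0), 1.0)


def detect_ms(
    t: np.ndarray,
    gyr: np.ndarray,
    acc_h: np.ndarray,
    fs: float,
    ic: float,
    tc: float,
    prev_var: float | None = None,
    cfg: MsConfig | None = None,
):
    """Mid-stance: the ZUPT anchor inside the trimmed stance phase.

    The first and last ``trim_frac`` of stance are excluded; a sliding
    window of ``window_frac`` of stance locates the minimum mean tri-axial
    gyro energy (t_omega) and the minimum horizontal acceleration variance
    (t_v). The two are blended with the variance-continuity weight
    ``w = var / (var + |var - prev_var|)`` (clamped to [0, 1]; first stride
    w = 1).

    Returns ``(ms, var, flags)``.
    """
    cfg = cfg or MsConfig()
    ct = tc - ic
    flags: list[str] = []
    i_lo = _time_to_idx(t, ic + cfg.trim_frac * ct, fs)
    i_hi = _time_to_idx(t, tc - cfg.trim_frac * ct, fs)
    L = max(int(round(cfg.window_frac * ct * fs)), 2)
    n_pos = i_hi - i_lo + 1 - L + 1
    if ct * fs <= 10 or n_pos < 1:
        flags.append("stance_too_short")
        return float(ic + 0.5 * ct), float(prev_var) if prev_var is not None else 0.0, flags

    g = np.asarray(gyr[i_lo : i_hi + 1], dtype=float)
    a = np.asarray(acc_h[i_lo : i_hi + 1], dtype=float)
    gw = np.lib.stride_tricks.sliding_window_view(g, L, axis=0)  # (n_pos, 3, L)
    aw = np.lib.stride_tricks.sliding_window_view(a, L, axis=0)
    energy = (gw**2).sum(axis=1).mean(axis=1)  # mean of wx^2+wy^2+wz^2 per window
    var = aw.var(axis=2).sum(axis=1)  # var(a_x) + var(a_y) per window
    j_w = int(np.argmin(energy))  # first minimum on ties
    j_v = int(np.argmin(var))
    center = (L - 1) / (2.0 * fs)
    t_omega = float(t[i_lo + j_w] + center)
    t_v = float(t[i_lo + j_v] + center)
    var_a = float(var[j_v])
    w = ms_weight(var_a, prev_var)
    ms = w * t_omega + (1.0 - w) * t_v
    return float(ms), var_a, flags


@dataclass
class StrideEvents:
    """Events of one stride (the interval between consecutive mid-swings)."""

    ic: float
    tc: float
    ms: float
    ic_candidates: dict = field(default_factory=dict)
    tc_candidates: dict = field(default_factory=dict)
    method: str = "mfdged"
    flags: list = field(default_factory=list)
    window: tuple = (np.nan, np.nan)


@dataclass
class GaitEvents:
    """All detected events of a trial."""

    msw: np.ndarray
    strides: list
    method: str = "mfdged"

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.strides):
            rows.append(
                {
                    "stride_id": k,
                    "msw": self.msw[k],
                    "ic": s.ic,
                    "ms": s.ms,
                    "tc": s.tc,
                    "method": s.method,
                    "flags": ";".join(s.flags),
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "msw": [float(x) for x in self.msw],
            "strides": [
                {
                    "ic": s.ic,
                    "ms": s.ms,
                    "tc": s.tc,
                    "ic_candidates": s.ic_candidates,
                    "tc_candidates": s.tc_candidates,
                    "method": s.method,
                    "flags": s.flags,
                }
                for s in self.strides
            ],
        }


def detect_events(
    t: np.ndarray,
    wx_f: np.ndarray,
    a_ap_f: np.ndarray,
    gyr_f: np.ndarray,
    acc_h_f: np.ndarray,
    fs: float,
    method: str = "mfdged",
    msw_cfg: MswConfig | None = None,
    ic_cfg: IcConfig | None = None,
    tc_cfg: TcConfig | None = None,
    ms_cfg: MsConfig | None = None,
) -> GaitEvents:
    """Run the full event-detection chain on filtered signals.

    ``wx_f``: filtered sagittal angular velocity; ``a_ap_f``: filtered
    anterior-posterior acceleration (sensor frame); ``gyr_f``: filtered
    tri-axial gyro; ``acc_h_f``: filtered horizontal-plane (navigation
    frame) acceleration, shape (n, 2).
    """
    msw_cfg = msw_cfg or MswConfig()
    ic_cfg = ic_cfg or IcConfig()
    tc_cfg = tc_cfg or TcConfig()
    ms_cfg = ms_cfg or MsConfig()
    msw = detect_msw(
        wx_f, fs, msw_cfg.k_sigma, msw_cfg.min_separation_s,
        t0=float(t[0]), min_peak_rads=msw_cfg.min_peak_rads,
    )
    strides = []
    prev_var: float | None = None
    for k in range(len(msw) - 1):
        window = (float(msw[k]), float(msw[k + 1]))
        sd = window[1] - window[0]
        flags: list[str] = []
        negpeak, zerocross = detect_ic_avgs(t, wx_f, fs, window, ic_cfg.negpeak_frac)
        if ic_cfg.avgs_convention == "negpeak" or zerocross is None:
            if ic_cfg.avgs_convention == "zerocross" and zerocross is None:
                flags.append("ic_zerocross_fallback_negpeak")
            ic_coarse = negpeak
        else:
            ic_coarse = zerocross
        if method == "avgs":
            ic = ic_coarse
            ic_cand = {"kinematic": zerocross, "kinetic": None}
            tc = detect_tc_avgs(t, wx_f, fs, ic, sd, tc_cfg.search_lo_frac, tc_cfg.search_hi_frac)
            tc_cand = {"kinematic": tc, "kinetic": None}
        else:
            ic, ic_cand, f_ic = detect_ic_fused(t, wx_f, a_ap_f, fs, ic_coarse, sd, window, ic_cfg)
            flags += f_ic
            tc, tc_cand, f_tc = detect_tc_fused(t, wx_f, a_ap_f, fs, ic, sd, tc_cfg)
            flags += f_tc
        ms, prev_var, f_ms = detect_ms(t, gyr_f, acc_h_f, fs, ic, tc, prev_var, ms_cfg)
        flags += f_ms
        if not (window[0] < ic < ms < tc < window[1]):
            flags.append("ordering_violation")
        strides.append(
            StrideEvents(
                ic=float(ic),
                tc=float(tc),
                ms=float(ms),
                ic_candidates=ic_cand,
                tc_candidates=tc_cand,
                method=method,
                flags=flags,
                window=window,
            )
        )
    log.info("detected %d strides (%s)", len(strides), method)
    return GaitEvents(msw=msw, strides=strides, method=method)
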