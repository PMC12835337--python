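"""Per-stride spatiotemporal and kinetic parameters.

From the event timestamps and the reconstructed stride displacement the
package derives, per stride: stride time ST (ipsilateral foot-strike to
foot-strike), contact time CT (IC to TC), swing time SWT (TC to next IC),
flight time FT = (SWT - CT) / 2 (single-sided estimate under left-right
symmetry), stride frequency SF = 120 / ST steps/min (two steps per
stride), stride length SL (horizontal resultant displacement between
mid-stance anchors), stride velocity SV = SL / ST, and the spring-mass
peak vertical ground reaction force.

The vGRF model approximates stance loading as a half-sine,
``F(t) = (pi/2) m g (FT/CT + 1) sin(pi t / CT)``, whose impulse over
stance balances body weight over a full step (CT + FT); the peak in body
weights is therefore ``(pi/2) (FT/CT + 1)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import G

log = logging.getLogger(__name__)


def temporal_parameters(ic_i: float, tc_i: float, ic_next: float):
    """(ST, CT, SWT) from consecutive-stride event times."""
    if not ic_i < tc_i < ic_next:
        raise ValueError(
            f"event ordering violated: ic={ic_i:.3f}, tc={tc_i:.3f}, next ic={ic_next:.3f}"
        )
    st = ic_next - ic_i
    ct = tc_i - ic_i
    swt = ic_next - tc_i
    return st, ct, swt


def flight_time(swt: float, ct: float):
    """FT = (SWT - CT) / 2; negative values are returned with a
    'no_flight' flag rather than clamped."""
    ft = 0.5 * (swt - ct)
    return ft, (["no_flight"] if ft < 0 else [])


def stride_frequency(st: float) -> float:
    """Steps per minute: 120 / ST (a stride is two steps)."""
    if st <= 0:
        raise ValueError("stride time must be positive")
    return 120.0 / st


def stride_velocity(sl: float, st: float) -> float:
    if st <= 0:
        raise ValueError("stride time must be positive")
    return sl / st


def vgrf_waveform(mass_kg: float, ft: float, ct: float, t_grid: np.ndarray) -> np.ndarray:
    """Spring-mass vGRF in Newtons on ``t_grid`` (0 <= t <= CT).

    Negative flight time is clipped to zero inside the model to keep the
    force physical.
    """
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    if ct <= 0:
        raise ValueError("contact time must be positive")
    ft = max(ft, 0.0)
    t_grid = np.asarray(t_grid, dtype=float)
    return 0.5 * np.pi * mass_kg * G * (ft / ct + 1.0) * np.sin(np.pi * t_grid / ct)


def peak_vgrf(ft: float, ct: float):
    """Modeled stance peak in body weights: (pi/2)(FT/CT + 1).

    Negative FT is clipped to zero (flagged)."""
    if ct <= 0:
        raise ValueError("contact time must be positive")
    flags = []
    if ft < 0:
        flags.append("ft_clipped")
        ft = 0.0
    return 0.5 * np.pi * (ft / ct + 1.0), flags


def compute_parameters(events, kinematics, mass_kg: float | None = None) -> pd.DataFrame:
    """Per-stride parameter table from detected events and reconstructed
    kinematics.

    Stride k uses events of stride records k and k+1 and the k-th
    anchor-to-anchor displacement; the table therefore has
    ``len(events.strides) - 1`` rows.
    """
    rows = []
    strides = events.strides
    for k in range(len(strides) - 1):
        s, s_next = strides[k], strides[k + 1]
        flags = list(s.flags)
        st, ct, swt = temporal_parameters(s.ic, s.tc, s_next.ic)
        ft, f_ft = flight_time(swt, ct)
        flags += f_ft
        sf = stride_frequency(st)
        sl = kinematics[k].stride_length if k < len(kinematics) else np.nan
        sv = stride_velocity(sl, st) if np.isfinite(sl) else np.nan
        bw, f_bw = peak_vgrf(ft, ct)
        flags += f_bw
        rows.append(
            {
                "stride_id": k,
                "ic": s.ic,
                "tc": s.tc,
                "ms": s.ms,
                "sv": sv,
                "sl": sl,
                "sf": sf,
                "st": st,
                "ct": ct,
                "swt": swt,
                "ft": ft,
                "peak_vgrf_bw": bw,
                "peak_vgrf_n": bw * mass_kg * G if mass_kg else np.nan,
                "flags": ";".join(flags),
            }
        )
    df = pd.DataFrame(rows)
    log.info("computed parameters for %d strides", len(df))
    return df


PARAMETER_COLUMNS = ["sv", "sl", "sf", "st", "ct", "swt", "ft", "peak_vgrf_bw"]


def summarize(df: pd.DataFrame) -> dict:
    """Trial-level mean +- SD per parameter (ddof=1)."""
    out = {}
    for c in PARAMETER_COLUMNS:
        vals = df[c].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        out[c] = {
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            "n": int(len(vals)),
        }
    return out
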