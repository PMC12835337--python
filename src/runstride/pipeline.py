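"""End-to-end orchestration: recording -> orientation -> events ->
stride reconstruction -> parameters, plus method comparison against a
reference parameter set.

The analysis path is fully deterministic: identical input and config give
byte-identical outputs. Randomness exists only in the simulator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import agreement_report, paired_t_and_cohens_d
from .config import PipelineConfig
from .events import GaitEvents, detect_events
from .io import ImuRecording
from .orientation import OrientationTrace, butterworth_lowpass, mahony_filter
from .parameters import PARAMETER_COLUMNS, compute_parameters, summarize
from .reconstruction import reconstruct_strides

log = logging.getLogger(__name__)


@dataclass
class GaitResults:
    """Everything one trial produces: events, per-stride kinematics and the
    parameter table, with the frozen config that made them."""

    parameters: pd.DataFrame
    events: GaitEvents
    orientation: OrientationTrace
    kinematics: list
    config: PipelineConfig
    flags: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Trial-level mean +- SD per parameter."""
        s = summarize(self.parameters)
        return pd.DataFrame(
            {
                "parameter": list(s),
                "mean": [s[k]["mean"] for k in s],
                "sd": [s[k]["sd"] for k in s],
                "n": [s[k]["n"] for k in s],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.model_dump(),
            "events": self.events.to_json_dict(),
            "summary": summarize(self.parameters),
        }


def analyze(rec: ImuRecording, config: PipelineConfig | None = None) -> GaitResults:
    """Run the full pipeline on one recording.

    The orientation filter consumes unfiltered samples; the event
    detectors consume the 6 Hz zero-phase filtered signals; the ZUPT
    integration consumes the unfiltered gravity-compensated acceleration
    (filtering before integration would distort displacement amplitude;
    config-exposed).
    """
    cfg = config or PipelineConfig()
    orient = mahony_filter(rec, cfg.mahony, cfg.stationary_threshold_rads)
    wx_f = butterworth_lowpass(rec.gyr_s[:, 0], rec.fs, cfg.filter)
    a_ap_f = butterworth_lowpass(rec.acc_s[:, 1], rec.fs, cfg.filter)
    gyr_f = butterworth_lowpass(rec.gyr_s, rec.fs, cfg.filter)
    acc_h_f = butterworth_lowpass(orient.acc_n[:, :2], rec.fs, cfg.filter)
    events = detect_events(
        rec.t, wx_f, a_ap_f, gyr_f, acc_h_f, rec.fs,
        method=cfg.method, msw_cfg=cfg.msw, ic_cfg=cfg.ic, tc_cfg=cfg.tc, ms_cfg=cfg.ms,
    )
    if not events.strides:
        raise ValueError("no strides found")
    if cfg.reconstruction.anchor == "ms":
        anchors = np.array([s.ms for s in events.strides])
    else:
        anchors = np.asarray(events.msw[1:-1] if len(events.msw) > 2 else events.msw)
    acc_int = (
        butterworth_lowpass(orient.acc_n, rec.fs, cfg.filter)
        if cfg.reconstruction.filter_before_integration
        else orient.acc_n
    )
    kin = reconstruct_strides(rec.t, acc_int, anchors, rec.fs)
    params = compute_parameters(events, kin, cfg.mass_kg)
    flags = sorted({f for s in events.strides for f in s.flags})
    return GaitResults(
        parameters=params, events=events, orientation=orient, kinematics=kin,
        config=cfg, flags=flags,
    )


def align_by_ic(est: pd.DataFrame, ref: pd.DataFrame, gate_s: float = 0.05) -> pd.DataFrame:
    """Pair estimated and reference strides by nearest IC within a gate.

    Unmatched strides are dropped (with a warning in the log). Returns a
    merged frame with ``_est`` / ``_ref`` suffixed columns.
    """
    rows = []
    used = set()
    for _, e in est.iterrows():
        d = (ref["ic"] - e["ic"]).abs()
        j = int(d.idxmin())
        if d[j] <= gate_s and j not in used:
            used.add(j)
            r = ref.loc[j]
            rows.append({**{f"{k}_est": v for k, v in e.items()},
                         **{f"{k}_ref": v for k, v in r.items()}})
    if len(rows) < len(est):
        log.warning("dropped %d unmatched strides", len(est) - len(rows))
    return pd.DataFrame(rows)


def compare(
    rec: ImuRecording,
    truth: pd.DataFrame,
    config: PipelineConfig | None = None,
    gate_s: float = 0.05,
) -> dict:
    """Analyze one recording with both methods and score each against a
    reference parameter table (simulator truth or an external reference).

    Returns per-parameter error summaries (reference - estimate) for the
    fused and conventional methods plus a paired t / Cohen's d between
    their error series.
    """
    cfg = config or PipelineConfig()
    out: dict = {"methods": {}, "paired": {}}
    errors: dict = {}
    for method in ("mfdged", "avgs"):
        res = analyze(rec, cfg.model_copy(update={"method": method}))
        pairs = align_by_ic(res.parameters, truth, gate_s)
        errs = {}
        summary = {}
        for p in PARAMETER_COLUMNS:
            if f"{p}_ref" not in pairs or f"{p}_est" not in pairs:
                continue
            e = (pairs[f"{p}_ref"] - pairs[f"{p}_est"]).to_numpy(float)
            e = e[np.isfinite(e)]
            errs[p] = e
            summary[p] = {
                "bias": float(np.mean(e)) if len(e) else float("nan"),
                "sd": float(np.std(e, ddof=1)) if len(e) > 1 else float("nan"),
                "mae": float(np.mean(np.abs(e))) if len(e) else float("nan"),
                "n": int(len(e)),
            }
        errors[method] = errs
        out["methods"][method] = summary
    for p in PARAMETER_COLUMNS:
        a, b = errors.get("avgs", {}).get(p), errors.get("mfdged", {}).get(p)
        if a is None or b is None:
            continue
        m = min(len(a), len(b))
        if m < 3:
            continue
        try:
            t, pv, d = paired_t_and_cohens_d(np.abs(a[:m]), np.abs(b[:m]))
            out["paired"][p] = {"t": t, "p": pv, "cohens_d": d}
        except ValueError:
            out["paired"][p] = {"t": float("nan"), "p": float("nan"), "cohens_d": float("nan")}
    return out


def validate_tables(ref_df: pd.DataFrame, est_df: pd.DataFrame, gate_s: float = 0.05) -> dict:
    """Agreement report per parameter between two per-stride tables
    (aligned by IC when both carry an ``ic`` column, else row-by-row)."""
    if "ic" in ref_df.columns and "ic" in est_df.columns:
        pairs = align_by_ic(est_df, ref_df, gate_s)
        get = lambda p: (pairs[f"{p}_ref"].to_numpy(float), pairs[f"{p}_est"].to_numpy(float))
        cols = [p for p in PARAMETER_COLUMNS if f"{p}_ref" in pairs]
    else:
        cols = [p for p in PARAMETER_COLUMNS if p in ref_df.columns and p in est_df.columns]
        get = lambda p: (ref_df[p].to_numpy(float), est_df[p].to_numpy(float))
    out = {}
    for p in cols:
        r, e = get(p)
        m = np.isfinite(r) & np.isfinite(e)
        if m.sum() < 3:
            continue
        try:
            out[p] = agreement_report(r[m], e[m]).to_dict()
        except ValueError as exc:
            out[p] = {"error": str(exc)}
    return out


def save_results(res: GaitResults, out_dir, stem: str = "trial") -> None:
    """Write the per-stride CSV and the events/summary JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.parameters.to_csv(out / f"{stem}_parameters.csv", index=False)
    kin = pd.DataFrame(
        {
            "stride_id": range(len(res.kinematics)),
            "t_start": [k.interval[0] for k in res.kinematics],
            "t_end": [k.interval[1] for k in res.kinematics],
            "disp_x": [k.disp[0] for k in res.kinematics],
            "disp_y": [k.disp[1] for k in res.kinematics],
            "disp_z": [k.disp[2] for k in res.kinematics],
            "sl": [k.stride_length for k in res.kinematics],
        }
    )
    kin.to_csv(out / f"{stem}_kinematics.csv", index=False)
    with open(out / f"{stem}_events.json", "w") as fh:
        json.dump(res.to_json_dict(), fh, indent=1)
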