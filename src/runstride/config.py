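"""Pipeline configuration: schema-validated, unknown keys rejected.

All algorithm parameters live here with their defaults. A frozen copy is
embedded in every output for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSpec(_Strict):
    """Low-pass filter used before event detection (Butterworth)."""

    order: int = 4
    cutoff_hz: float = 6.0
    zero_phase: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        return self


class MahonyConfig(_Strict):
    """Complementary-filter gains and accelerometer gating.

    kp/ki are the proportional/integral correction gains. The correction is
    applied only when the specific-force magnitude is within
    ``acc_gate_tol`` (relative) of g, so high-dynamics swing samples
    propagate gyro-only; set ``acc_gate_tol`` to ``inf`` to disable gating.
    """

    kp: float = 2.0
    ki: float = 0.05
    acc_gate_tol: float = 0.10


class MswConfig(_Strict):
    k_sigma: float = 1.0
    min_separation_s: float = 0.4
    # absolute floor below which no peak counts as a mid-swing: guards the
    # purely adaptive threshold against stride-free (stationary) recordings
    min_peak_rads: float = 1.0


class IcConfig(_Strict):
    window_frac: float = 0.3  # total stride fraction, centred on the coarse estimate
    w_acc: float = 0.7
    negpeak_frac: float = 0.5  # portion of the stride searched for the negative peak
    # conventional IC definition: the classic negative peak, or its
    # zero-crossing refinement (also used as the fused coarse estimate)
    avgs_convention: Literal["negpeak", "zerocross"] = "negpeak"


class TcConfig(_Strict):
    search_lo_frac: float = 0.1
    search_hi_frac: float = 0.6
    w_acc: float = 0.7


class MsConfig(_Strict):
    trim_frac: float = 0.1
    window_frac: float = 0.3


class ReconstructionConfig(_Strict):
    # ZUPT anchor: mid-stance (physically valid zero-velocity instant) or
    # mid-swing segmentation points; filter_before_integration applies the
    # event low-pass to the navigation-frame acceleration before integrating
    # (off by default: it distorts displacement amplitude).
    anchor: Literal["ms", "msw"] = "ms"
    filter_before_integration: bool = False


class PipelineConfig(_Strict):
    fs: Optional[float] = None
    acc_units: Literal["g", "ms2"] = "ms2"
    gyr_units: Literal["rads", "degs"] = "rads"
    stationary_threshold_rads: float = 0.0436
    method: Literal["mfdged", "avgs"] = "mfdged"
    mass_kg: Optional[float] = None
    filter: FilterSpec = FilterSpec()
    mahony: MahonyConfig = MahonyConfig()
    msw: MswConfig = MswConfig()
    ic: IcConfig = IcConfig()
    tc: TcConfig = TcConfig()
    ms: MsConfig = MsConfig()
    reconstruction: ReconstructionConfig = ReconstructionConfig()

    @model_validator(mode="after")
    def _check(self):
        if self.stationary_threshold_rads <= 0:
            raise ValueError("stationary_threshold_rads must be positive")
        if self.mass_kg is not None and self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        for w in (self.ic.w_acc, self.tc.w_acc):
            if not 0.0 <= w <= 1.0:
                raise ValueError("fusion weights must lie in [0, 1]")
        if not self.tc.search_lo_frac < self.tc.search_hi_frac:
            raise ValueError("tc search window fractions must be ordered")
        return self


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a JSON or YAML config file; missing keys take defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    data.update(overrides)
    return PipelineConfig(**data)
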