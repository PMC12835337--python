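"""Reading, validating and writing foot-IMU recordings.

The on-disk dialect is a plain CSV with header ``time,ax,ay,az,gx,gy,gz``;
time in seconds on a uniform grid. Input units are declared, never guessed:
acceleration in g or m/s^2, angular rate in rad/s or deg/s. Internally
everything is SI (m/s^2, rad/s).

Sensor axes follow the instep mounting convention: x medial-lateral,
y anterior-posterior, z vertical (foot flat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

G = 9.81  # m/s^2, exact by convention throughout the package

ACC_UNIT_FACTORS = {"ms2": 1.0, "g": G}
GYR_UNIT_FACTORS = {"rads": 1.0, "degs": np.pi / 180.0}

CSV_COLUMNS = ["time", "ax", "ay", "az", "gx", "gy", "gz"]


@dataclass
class ImuRecording:
    """Uniformly sampled tri-axial accelerometer + gyroscope trace.

    Attributes
    ----------
    t : (n,) float array, seconds, strictly increasing uniform grid.
    acc_s : (n, 3) float array, specific force in the sensor frame, m/s^2.
    gyr_s : (n, 3) float array, angular rate in the sensor frame, rad/s.
    fs : sampling rate, Hz.
    """

    t: np.ndarray
    acc_s: np.ndarray
    gyr_s: np.ndarray
    fs: float
    units_in: dict = field(default_factory=lambda: {"acc": "ms2", "gyr": "rads"})

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.acc_s = np.asarray(self.acc_s, dtype=float)
        self.gyr_s = np.asarray(self.gyr_s, dtype=float)
        n = len(self.t)
        if n < 2:
            raise ValueError("empty recording: need at least 2 samples")
        if self.acc_s.shape != (n, 3) or self.gyr_s.shape != (n, 3):
            raise ValueError(
                f"shape mismatch: t has {n} samples, acc {self.acc_s.shape}, gyr {self.gyr_s.shape}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (
            np.all(np.isfinite(self.t))
            and np.all(np.isfinite(self.acc_s))
            and np.all(np.isfinite(self.gyr_s))
        ):
            raise ValueError("non-finite samples in recording")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time vector must be strictly increasing")
        # jitter bound: each interval within half a nominal sample of 1/fs
        if np.max(np.abs(dt - 1.0 / self.fs)) >= 0.5 / self.fs:
            raise ValueError("time grid jitter exceeds half a sample interval")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def read_imu_csv(
    path,
    fs: float | None = None,
    acc_units: str = "ms2",
    gyr_units: str = "rads",
) -> ImuRecording:
    """Read a ``time,ax,ay,az,gx,gy,gz`` CSV into SI units.

    ``fs`` is taken from the config when given, otherwise inferred from the
    median sample interval.
    """
    if acc_units not in ACC_UNIT_FACTORS:
        raise ValueError(f"acc_units must be one of {sorted(ACC_UNIT_FACTORS)}")
    if gyr_units not in GYR_UNIT_FACTORS:
        raise ValueError(f"gyr_units must be one of {sorted(GYR_UNIT_FACTORS)}")
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed CSV {path}: missing columns {missing}")
    bad = df[CSV_COLUMNS].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise ValueError(f"malformed CSV {path}: non-numeric or missing value at row {row}")
    t = df["time"].to_numpy(float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    acc = df[["ax", "ay", "az"]].to_numpy(float) * ACC_UNIT_FACTORS[acc_units]
    gyr = df[["gx", "gy", "gz"]].to_numpy(float) * GYR_UNIT_FACTORS[gyr_units]
    rec = ImuRecording(
        t, acc, gyr, fs=fs, units_in={"acc": acc_units, "gyr": gyr_units}
    )
    log.info("read %d samples (%.1f s at %.1f Hz) from %s", rec.n_samples, rec.duration, fs, path)
    return rec


def write_imu_csv(path, rec: ImuRecording) -> None:
    """Write a recording in the package CSV dialect (SI units)."""
    df = pd.DataFrame(
        {
            "time": rec.t,
            "ax": rec.acc_s[:, 0],
            "ay": rec.acc_s[:, 1],
            "az": rec.acc_s[:, 2],
            "gx": rec.gyr_s[:, 0],
            "gy": rec.gyr_s[:, 1],
            "gz": rec.gyr_s[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
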