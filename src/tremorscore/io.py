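"""Reading and writing IMU recordings, feature tables, and packaged data.

Recording files are plain CSV with a header row and columns
``t, ax, ay, az, gx, gy, gz`` (``t`` optional; without it the file is taken
to be uniformly sampled at the declared rate).  All downstream code works in
SI units, so unit conversion (g to m/s^2, deg/s to rad/s) happens here, at
read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix

G_TO_MS2 = 9.80665
DPS_TO_RADS = np.pi / 180.0

ACCEL_UNITS = ("m/s^2", "g")
GYRO_UNITS = ("rad/s", "dps")

ACCEL_COLS = ("ax", "ay", "az")
GYRO_COLS = ("gx", "gy", "gz")

__all__ = [
    "RawRecording",
    "read_recording",
    "write_recording",
    "write_features",
    "read_features",
    "load_table5_fixture",
    "read_confusion_text",
]


@dataclass
class RawRecording:
    """Six-channel IMU time series in SI units (m/s^2 and rad/s).

    ``accel`` and ``gyro`` are (3, N) arrays sharing the same length N.
    ``label`` is the UPDRS resting-tremor score 0-4, or None when the
    recording is unlabelled (inference only).
    """

    accel: np.ndarray
    gyro: np.ndarray
    sample_rate: float = 125.0
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.accel.shape[0] != 3 or self.gyro.shape[0] != 3:
            raise ValueError("accel and gyro must each have 3 axes")
        if self.accel.shape[1] != self.gyro.shape[1]:
            raise ValueError("accelerometer and gyroscope lengths differ")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.label is not None and self.label not in range(5):
            raise ValueError("label must be in 0..4 when present")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


def read_recording(
    path,
    sample_rate: float = 125.0,
    accel_unit: str = "m/s^2",
    gyro_unit: str = "rad/s",
    label: int | None = None,
) -> RawRecording:
    """Read a recording CSV, converting channels to SI units.

    If a ``t`` column is present the sample rate is derived from its median
    increment (and must be uniform); otherwise ``sample_rate`` applies.
    """
    if accel_unit not in ACCEL_UNITS:
        raise ValueError(f"accel_unit must be one of {ACCEL_UNITS}")
    if gyro_unit not in GYRO_UNITS:
        raise ValueError(f"gyro_unit must be one of {GYRO_UNITS}")
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ACCEL_COLS + GYRO_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    for col in ACCEL_COLS + GYRO_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path.name}: non-numeric value in column {col!r} at row {row}")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValueError(f"{path.name}: empty cell in column {col!r} at row {row}")
        df[col] = vals

    if "t" in df.columns:
        dt = np.diff(df["t"].to_numpy(dtype=float))
        if len(dt) == 0 or dt.min() <= 0:
            raise ValueError(f"{path.name}: time column is not strictly increasing")
        sample_rate = 1.0 / float(np.median(dt))

    accel = df.loc[:, list(ACCEL_COLS)].to_numpy(dtype=float).T
    gyro = df.loc[:, list(GYRO_COLS)].to_numpy(dtype=float).T
    if accel_unit == "g":
        accel = accel * G_TO_MS2
    if gyro_unit == "dps":
        gyro = gyro * DPS_TO_RADS
    return RawRecording(
        accel=accel,
        gyro=gyro,
        sample_rate=sample_rate,
        label=label,
        meta={"source": str(path)},
    )


def write_recording(rec: RawRecording, path, include_time: bool = True) -> None:
    """Write a recording to CSV in SI units (lossless round-trip)."""
    cols = {}
    if include_time:
        cols["t"] = np.arange(rec.n_samples) / rec.sample_rate
    for name, row in zip(ACCEL_COLS, rec.accel):
        cols[name] = row
    for name, row in zip(GYRO_COLS, rec.gyro):
        cols[name] = row
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_features(matrix: pd.DataFrame, path) -> None:
    """Write a feature matrix (canonical ``signal.feature`` columns) to CSV.

    The ``label`` column, if present, is moved last.  Values round-trip at
    full double precision.
    """
    cols = [c for c in matrix.columns if c != "label"]
    if "label" in matrix.columns:
        cols = cols + ["label"]
    matrix.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_confusion_text(path) -> ConfusionMatrix:
    """Read a whitespace-delimited 5x5 integer table ('#' comments allowed)."""
    counts = np.loadtxt(path, dtype=int, comments="#")
    return ConfusionMatrix(counts)


def load_table5_fixture() -> ConfusionMatrix:
    """Packaged confusion matrix of the published decision-tree scorer.

    131 resting-tremor recordings; rows true UPDRS, columns predicted UPDRS.
    """
    ref = resources.files("tremorscore.data").joinpath("table5_confusion.txt")
    with resources.as_file(ref) as p:
        return read_confusion_text(p)
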