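"""Reading and writing IMU logs, stride tables and walk summaries.

The on-disk formats are deliberately plain: comma-separated, dot-decimal,
UTF-8 CSV with a header row.  Raw IMU logs carry seven columns
``t,ax,ay,az,gx,gy,gz`` (seconds, m/s^2, rad/s by default); a configurable
column mapping and unit-conversion flags accommodate logs recorded in g,
deg/s or milliseconds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "ImuRecording",
    "FormatError",
    "DataError",
    "read_imu_csv",
    "write_imu_csv",
    "write_stride_table",
    "read_stride_table",
    "write_summary_json",
    "read_summary_json",
    "read_cohort_csv",
    "write_cohort_csv",
]

log = logging.getLogger(__name__)

G_PER_MPS2 = 9.80665  # standard gravity used for the g <-> m/s^2 flag


class FormatError(ValueError):
    """Raised when a file does not match the expected schema."""


class DataError(ValueError):
    """Raised when a file parses but its contents are unusable."""


@dataclass
class ImuRecording:
    """Timestamped 6-axis inertial samples from one foot-mounted sensor.

    Attributes
    ----------
    t : (N,) float array, seconds, strictly increasing.
    accel : (N, 3) specific force in m/s^2, body frame.
    gyro : (N, 3) angular rate in rad/s, body frame.
    sample_rate_hz : nominal sampling rate.
    meta : free-form metadata (subject id, sensor id, foot side, ...).
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate_hz: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.t.shape[0]
        if n < 2:
            raise DataError("recording needs at least 2 samples")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise DataError("accel and gyro must be (N, 3) arrays matching t")
        if not np.all(np.diff(self.t) > 0):
            raise DataError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.accel))
                and np.all(np.isfinite(self.gyro))):
            raise DataError("recording contains non-finite values")
        if self.sample_rate_hz <= 0:
            raise DataError("sample_rate_hz must be > 0")
        med_dt = float(np.median(np.diff(self.t)))
        nominal = 1.0 / self.sample_rate_hz
        if not (0.8 * nominal <= med_dt <= 1.2 * nominal):
            raise DataError(
                f"median sampling interval {med_dt:.4g}s deviates more than 20% "
                f"from nominal {nominal:.4g}s")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


def read_imu_csv(path: str | Path, config: RunConfig | None = None) -> ImuRecording:
    """Read a raw IMU log.

    Rows containing non-finite values are dropped (with a logged count);
    timestamps are sorted and must then be strictly increasing.  Unit
    conversions (g to m/s^2, deg/s to rad/s, ms to s) follow the io section
    of ``config``.
    """
    config = config or RunConfig()
    cols = config.io.columns
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for key in ("t", "ax", "ay", "az", "gx", "gy", "gz"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing required column '{cols[key]}' in {path}")
    data = df[[cols[k] for k in ("t", "ax", "ay", "az", "gx", "gy", "gz")]].to_numpy(float)
    finite = np.all(np.isfinite(data), axis=1)
    if not finite.all():
        log.warning("dropping %d rows with non-finite values", int((~finite).sum()))
        data = data[finite]
    if data.shape[0] < 2:
        raise DataError(f"{path}: fewer than 2 usable rows")
    data = data[np.argsort(data[:, 0], kind="stable")]
    if not np.all(np.diff(data[:, 0]) > 0):
        raise DataError(f"{path}: timestamps not strictly increasing after sorting")
    t = data[:, 0].copy()
    if config.io.time_unit == "ms" or (
            config.io.time_unit == "auto" and np.median(np.diff(t)) > 0.5):
        # a median interval above 0.5 "seconds" at walking rates means ms
        t = t / 1000.0
    accel = data[:, 1:4].copy()
    gyro = data[:, 4:7].copy()
    if config.io.accel_in_g:
        accel *= G_PER_MPS2
    if config.io.gyro_in_deg:
        gyro = np.deg2rad(gyro)
    return ImuRecording(t=t, accel=accel, gyro=gyro,
                        sample_rate_hz=config.sample_rate_hz,
                        meta={"source": str(path)})


def write_imu_csv(rec: ImuRecording, path: str | Path) -> None:
    df = pd.DataFrame({
        "t": rec.t,
        "ax": rec.accel[:, 0], "ay": rec.accel[:, 1], "az": rec.accel[:, 2],
        "gx": rec.gyro[:, 0], "gy": rec.gyro[:, 1], "gz": rec.gyro[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.12g")


def write_stride_table(strides: list, path: str | Path) -> None:
    """Write per-stride parameters as CSV, one row per stride.

    Column order follows the :class:`~gstride.metrics.StrideParams` field
    order and is deterministic.  An empty list yields a header-only file.
    """
    from .metrics import StrideParams, stride_field_names

    names = stride_field_names()
    rows = []
    for s in strides:
        if isinstance(s, StrideParams):
            rows.append([getattr(s, n) for n in names])
        else:  # mapping
            rows.append([s[n] for n in names])
    pd.DataFrame(rows, columns=names).to_csv(path, index=False, float_format="%.12g")


def read_stride_table(path: str | Path) -> list:
    from .metrics import StrideParams, stride_field_names

    df = pd.read_csv(path)
    names = stride_field_names()
    missing = set(names) - set(df.columns)
    if missing:
        raise FormatError(f"stride table missing columns: {sorted(missing)}")
    return [StrideParams(**{n: float(row[n]) for n in names})
            for _, row in df.iterrows()]


def write_summary_json(summary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)


def read_summary_json(path: str | Path) -> dict[str, float]:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_trajectory_csv(traj, path: str | Path) -> None:
    """Trajectory CSV: t,px,py,pz,vx,vy,vz,qw,qx,qy,qz (quaternion scalar-first
    on disk for readability)."""
    q = traj.quat
    df = pd.DataFrame({
        "t": traj.t,
        "px": traj.pos[:, 0], "py": traj.pos[:, 1], "pz": traj.pos[:, 2],
        "vx": traj.vel[:, 0], "vy": traj.vel[:, 1], "vz": traj.vel[:, 2],
        "qw": q[:, 3], "qx": q[:, 0], "qy": q[:, 1], "qz": q[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(path: str | Path):
    from .ins import NavTrajectory

    df = pd.read_csv(path)
    required = ["t", "px", "py", "pz", "vx", "vy", "vz", "qw", "qx", "qy", "qz"]
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"trajectory CSV missing columns: {sorted(missing)}")
    quat = df[["qx", "qy", "qz", "qw"]].to_numpy(float)
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return NavTrajectory(
        t=df["t"].to_numpy(float),
        pos=df[["px", "py", "pz"]].to_numpy(float),
        vel=df[["vx", "vy", "vz"]].to_numpy(float),
        quat=quat)


def write_stance_csv(mask, path: str | Path) -> None:
    pd.DataFrame({"stance": mask.mask.astype(int)}).to_csv(path, index=False)


def read_stance_csv(path: str | Path):
    from .ins import StanceMask

    df = pd.read_csv(path)
    if "stance" not in df.columns:
        raise FormatError("stance CSV must contain a 'stance' column")
    return StanceMask.from_mask(df["stance"].to_numpy().astype(bool))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "FALLS" not in df.columns:
        raise FormatError("cohort table must contain a FALLS column")
    df["FALLS"] = df["FALLS"].astype(bool)
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
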