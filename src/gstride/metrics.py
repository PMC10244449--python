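"""Stride segmentation and gait-parameter estimation.

A gait cycle of the instrumented foot runs from one heel strike (HS) to the
next and decomposes into four phases: loading (HS to foot-flat start),
foot-flat (the stationary sub-interval of stance), pushing (foot-flat end
to toe-off, TO) and swing (TO to the next HS).  From the navigation
trajectory each stride yields:

* gait cycle time (GCT) and the four phase durations as % of GCT,
* stride length (SL): horizontal distance between the mid-foot-flat
  positions of consecutive stances (the drift-minimal stance reference),
* 2D/3D path lengths of the foot between those references,
* clearance: peak foot height during swing above the mean foot-flat height
  of the bracketing stances (sensor height, no mounting offset),
* heel-strike and toe-off pitch angles (toes-up positive, so heel strike
  is positive and toe-off negative),
* step speed: mean horizontal foot speed during swing.

Walk-level summaries aggregate strides into means and inter-stride
standard deviations; cadence is reported as gait cycles of the instrumented
foot per minute (60 / mean GCT).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .config import RunConfig
from .ins import NavTrajectory, StanceMask

__all__ = [
    "StrideSegment",
    "StrideParams",
    "WalkSummary",
    "MEAN_LABELS",
    "STD_LABELS",
    "stride_field_names",
    "pitch_from_orientation",
    "pitch_series",
    "segment_strides",
    "compute_stride_params",
    "is_plausible",
    "strides_from_trajectory",
    "summarize",
]

log = logging.getLogger(__name__)

#: Walk-summary row labels for the seventeen per-walk mean parameters.
MEAN_LABELS = [
    "Total distance (m)",
    "Total time (s)",
    "Total steps",
    "Gait cycle time - GCT (s)",
    "Stance-pushing time (% GCT)",
    "Swing (% GCT)",
    "Stance-loading time (% GCT)",
    "Stance-FootFlat time (% GCT)",
    "Toe off angle (deg)",
    "Heel strike angle (deg)",
    "Cadence (steps/min)",
    "StepSpeed (m/s)",
    "StrideLength - SL (m)",
    "3D path (m)",
    "2D path (m)",
    "Clearance (m)",
    "Velocity (m/s)",
]

#: Row labels for the thirteen inter-stride variability (STD) parameters.
STD_LABELS = [
    "GCT STD",
    "Stance-pushing time STD",
    "Swing STD",
    "Stance-loading time STD",
    "Stance-FootFlat time STD",
    "Toe off angle STD",
    "Heel strike angle STD",
    "Cadence STD",
    "StepSpeed STD",
    "StrideLength STD",
    "3D path STD",
    "2D path STD",
    "Clearance STD",
]


@dataclass
class StrideSegment:
    """Sample indices of the events bounding one gait cycle.

    ``next_ff_start``/``next_ff_end`` locate the foot-flat of the following
    stance, needed as the far stance reference for stride length and
    clearance.
    """

    hs: int
    ff_start: int
    ff_end: int
    to: int
    next_hs: int
    next_ff_start: int
    next_ff_end: int

    def __post_init__(self) -> None:
        if not (self.hs <= self.ff_start <= self.ff_end <= self.to < self.next_hs):
            raise ValueError("stride events must satisfy HS <= FFs <= FFe <= TO < nextHS")
        if not (self.next_hs <= self.next_ff_start <= self.next_ff_end):
            raise ValueError("next foot-flat must follow the next heel strike")


@dataclass
class StrideParams:
    """Gait parameters of one stride."""

    t_hs_s: float
    gct_s: float
    swing_pct: float
    loading_pct: float
    footflat_pct: float
    pushing_pct: float
    heel_strike_angle_deg: float
    toe_off_angle_deg: float
    stride_length_m: float
    path2d_m: float
    path3d_m: float
    clearance_m: float
    step_speed_mps: float


def stride_field_names() -> list[str]:
    return [f.name for f in dataclasses.fields(StrideParams)]


_AGG_FIELDS = [f for f in stride_field_names() if f != "t_hs_s"]


@dataclass
class WalkSummary:
    """Walk-level aggregation of per-stride parameters."""

    total_distance_m: float
    total_time_s: float
    total_steps: int
    cadence_per_min: float
    velocity_mps: float
    means: dict[str, float]
    stds: dict[str, float]
    cadence_std: float

    def to_dict(self) -> dict[str, float]:
        out = {
            "total_distance_m": self.total_distance_m,
            "total_time_s": self.total_time_s,
            "total_steps": self.total_steps,
            "cadence_per_min": self.cadence_per_min,
            "velocity_mps": self.velocity_mps,
            "cadence_std": self.cadence_std,
        }
        out.update({f"mean_{k}": v for k, v in self.means.items()})
        out.update({f"std_{k}": v for k, v in self.stds.items()})
        return out

    def to_labeled_row(self) -> dict[str, float]:
        """Walk summary keyed by the cohort-table row labels."""
        m, s = self.means, self.stds
        return {
            "Total distance (m)": self.total_distance_m,
            "Total time (s)": self.total_time_s,
            "Total steps": float(self.total_steps),
            "Gait cycle time - GCT (s)": m["gct_s"],
            "Stance-pushing time (% GCT)": m["pushing_pct"],
            "Swing (% GCT)": m["swing_pct"],
            "Stance-loading time (% GCT)": m["loading_pct"],
            "Stance-FootFlat time (% GCT)": m["footflat_pct"],
            "Toe off angle (deg)": m["toe_off_angle_deg"],
            "Heel strike angle (deg)": m["heel_strike_angle_deg"],
            "Cadence (steps/min)": self.cadence_per_min,
            "StepSpeed (m/s)": m["step_speed_mps"],
            "StrideLength - SL (m)": m["stride_length_m"],
            "3D path (m)": m["path3d_m"],
            "2D path (m)": m["path2d_m"],
            "Clearance (m)": m["clearance_m"],
            "Velocity (m/s)": self.velocity_mps,
            "GCT STD": s["gct_s"],
            "Stance-pushing time STD": s["pushing_pct"],
            "Swing STD": s["swing_pct"],
            "Stance-loading time STD": s["loading_pct"],
            "Stance-FootFlat time STD": s["footflat_pct"],
            "Toe off angle STD": s["toe_off_angle_deg"],
            "Heel strike angle STD": s["heel_strike_angle_deg"],
            "Cadence STD": self.cadence_std,
            "StepSpeed STD": s["step_speed_mps"],
            "StrideLength STD": s["stride_length_m"],
            "3D path STD": s["path3d_m"],
            "2D path STD": s["path2d_m"],
            "Clearance STD": s["clearance_m"],
        }


def pitch_from_orientation(q) -> float:
    """Sagittal pitch (degrees) of a body-to-nav quaternion, toes-up positive.

    The pitch is the elevation of the foot's forward axis above the
    horizontal plane, in (-90, 90).  Accepts a scalar-last quaternion or a
    :class:`scipy.spatial.transform.Rotation`.
    """
    if isinstance(q, Rotation):
        rot = q
    else:
        q = np.asarray(q, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError("quaternion must be unit norm")
        rot = Rotation.from_quat(q)
    fwd = rot.apply([1.0, 0.0, 0.0])
    return float(np.degrees(np.arctan2(fwd[2], np.hypot(fwd[0], fwd[1]))))


def pitch_series(quat: np.ndarray) -> np.ndarray:
    """Vectorised pitch extraction over an (N, 4) quaternion array."""
    fwd = Rotation.from_quat(quat).apply(np.array([1.0, 0.0, 0.0]))
    return np.degrees(np.arctan2(fwd[:, 2], np.hypot(fwd[:, 0], fwd[:, 1])))


def _footflat_run(gyro: np.ndarray, start: int, end: int, thresh: float) -> tuple[int, int]:
    """Longest sub-run of [start, end) where the gyro magnitude is below thresh."""
    mag = np.linalg.norm(gyro[start:end], axis=1)
    quiet = mag < thresh
    best: tuple[int, int] | None = None
    run_s = None
    for i, flag in enumerate(np.concatenate([quiet, [False]])):
        if flag and run_s is None:
            run_s = i
        elif not flag and run_s is not None:
            if best is None or (i - run_s) > (best[1] - best[0]):
                best = (run_s, i)
            run_s = None
    if best is None:
        # no quiet samples: fall back to the single minimum-rate sample
        j = int(np.argmin(mag))
        best = (j, j + 1)
    return start + best[0], start + best[1]


def segment_strides(traj: NavTrajectory, mask: StanceMask,
                    gyro: np.ndarray, config: RunConfig | None = None
                    ) -> list[StrideSegment]:
    """One :class:`StrideSegment` per consecutive pair of stance intervals.

    Heel strike and toe-off are taken as the stance-interval boundaries;
    the foot-flat sub-interval is the longest run within stance where the
    angular rate magnitude stays below the foot-flat threshold.
    """
    config = config or RunConfig()
    thresh = config.events.footflat_gyro_thresh
    intervals = mask.intervals
    if len(intervals) < 2:
        log.warning("fewer than 2 stance intervals: no strides to segment")
        return []
    ffs = [_footflat_run(gyro, s, e, thresh) for s, e in intervals]
    segments = []
    for i in range(len(intervals) - 1):
        s0, e0 = intervals[i]
        s1, _ = intervals[i + 1]
        segments.append(StrideSegment(
            hs=s0, ff_start=ffs[i][0], ff_end=ffs[i][1], to=e0, next_hs=s1,
            next_ff_start=ffs[i + 1][0], next_ff_end=ffs[i + 1][1]))
    return segments


def compute_stride_params(traj: NavTrajectory, seg: StrideSegment,
                          config: RunConfig | None = None) -> StrideParams:
    """Gait parameters of a single stride from the navigation trajectory."""
    config = config or RunConfig()
    t = traj.t
    pos = traj.pos
    gct = float(t[seg.next_hs] - t[seg.hs])
    if gct <= 0:
        raise ValueError("non-positive gait cycle time")
    loading = float(t[seg.ff_start] - t[seg.hs]) / gct * 100.0
    footflat = float(t[seg.ff_end] - t[seg.ff_start]) / gct * 100.0
    pushing = float(t[seg.to] - t[seg.ff_end]) / gct * 100.0
    swing = float(t[seg.next_hs] - t[seg.to]) / gct * 100.0

    m0 = (seg.ff_start + seg.ff_end) // 2
    m1 = (seg.next_ff_start + seg.next_ff_end) // 2
    sl = float(np.hypot(pos[m1, 0] - pos[m0, 0], pos[m1, 1] - pos[m0, 1]))
    d = np.diff(pos[m0:m1 + 1], axis=0)
    # clamp the theoretical ordering against floating-point rounding
    path2d = max(float(np.sum(np.hypot(d[:, 0], d[:, 1]))), sl)
    path3d = max(float(np.sum(np.linalg.norm(d, axis=1))), path2d)

    base = np.mean(np.concatenate([pos[seg.ff_start:seg.ff_end, 2],
                                   pos[seg.next_ff_start:seg.next_ff_end, 2]]))
    swing_z = pos[seg.to:seg.next_hs + 1, 2]
    clearance = max(0.0, float(swing_z.max() - base))

    pitch = pitch_series(traj.quat)
    w = config.events.event_window
    hs_lo, hs_hi = max(0, seg.hs - w), min(len(t), seg.hs + w + 1)
    to_lo, to_hi = max(0, seg.to - w), min(len(t), seg.to + w + 1)
    hs_angle = float(pitch[hs_lo:hs_hi].max())
    to_angle = float(pitch[to_lo:to_hi].min())

    dsw = np.diff(pos[seg.to:seg.next_hs + 1], axis=0)
    dt_sw = np.diff(t[seg.to:seg.next_hs + 1])
    speeds = np.hypot(dsw[:, 0], dsw[:, 1]) / dt_sw
    step_speed = float(speeds.mean()) if speeds.size else 0.0

    return StrideParams(
        t_hs_s=float(t[seg.hs]), gct_s=gct, swing_pct=swing, loading_pct=loading,
        footflat_pct=footflat, pushing_pct=pushing,
        heel_strike_angle_deg=hs_angle, toe_off_angle_deg=to_angle,
        stride_length_m=sl, path2d_m=path2d, path3d_m=path3d,
        clearance_m=clearance, step_speed_mps=step_speed)


def is_plausible(p: StrideParams, config: RunConfig | None = None) -> bool:
    """Physiological plausibility filter for a stride."""
    config = config or RunConfig()
    ev = config.events
    if not (ev.gct_min_s <= p.gct_s <= ev.gct_max_s):
        return False
    for pct in (p.swing_pct, p.loading_pct, p.footflat_pct, p.pushing_pct):
        if not (0.0 <= pct <= 100.0):
            return False
    return True


def strides_from_trajectory(traj: NavTrajectory, mask: StanceMask,
                            gyro: np.ndarray, config: RunConfig | None = None
                            ) -> list[StrideParams]:
    """Segment, parameterise and plausibility-filter a full walk."""
    config = config or RunConfig()
    segments = segment_strides(traj, mask, gyro, config)
    params = [compute_stride_params(traj, seg, config) for seg in segments]
    valid = [p for p in params if is_plausible(p, config)]
    dropped = len(params) - len(valid)
    if dropped:
        log.info("excluded %d implausible stride(s)", dropped)
    return valid


def summarize(strides: list[StrideParams]) -> WalkSummary:
    """Aggregate per-stride parameters into a walk summary.

    Velocity is total distance over total time (sum of stride lengths over
    sum of gait cycle times); cadence is 60 over the mean gait cycle time.
    Standard deviations use the n-1 sample form and are zero for a single
    stride.
    """
    if not strides:
        raise ValueError("cannot summarise an empty stride list")
    arrays = {name: np.array([getattr(s, name) for s in strides])
              for name in _AGG_FIELDS}
    n = len(strides)
    means = {k: float(v.mean()) for k, v in arrays.items()}
    stds = {k: (float(v.std(ddof=1)) if n > 1 else 0.0) for k, v in arrays.items()}
    total_distance = float(arrays["stride_length_m"].sum())
    total_time = float(arrays["gct_s"].sum())
    cadences = 60.0 / arrays["gct_s"]
    return WalkSummary(
        total_distance_m=total_distance,
        total_time_s=total_time,
        total_steps=n,
        cadence_per_min=60.0 / means["gct_s"],
        velocity_mps=total_distance / total_time,
        means=means,
        stds=stds,
        cadence_std=(float(cadences.std(ddof=1)) if n > 1 else 0.0),
    )
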