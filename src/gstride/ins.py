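"""Strapdown inertial navigation with zero-velocity updates (INS-ZUPT).

The foot trajectory is recovered in three steps: (1) a sliding-window
likelihood statistic flags the samples where the sensor is not translating
(stance); (2) open-loop strapdown mechanisation integrates gyro and
accelerometer signals into orientation, velocity and position; (3) an
error-state Kalman filter over nine error states (attitude, velocity,
position) applies a zero-velocity pseudo-measurement at every stance sample
and feeds the corrections back, which bounds the drift to a small amount
per stride.

Conventions: local level navigation frame with z up and the origin at the
first sample; gravity acts along -z; body frame x forward along the foot,
y left, z up when the foot is flat.  Yaw is unobservable from a single
IMU, so trajectories should only ever be compared through per-stride
displacements and path lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import RunConfig
from .io import ImuRecording

__all__ = [
    "StanceMask",
    "NavTrajectory",
    "InitializationError",
    "estimate_initial_attitude",
    "detect_stance",
    "strapdown",
    "run_zupt_ekf",
]

log = logging.getLogger(__name__)


class InitializationError(RuntimeError):
    """No quasi-static segment found for attitude initialisation."""


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) index pairs of the True runs in a boolean array."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))


@dataclass
class StanceMask:
    """Per-sample stationarity flags with derived stance intervals."""

    mask: np.ndarray
    intervals: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_mask(cls, mask: np.ndarray, min_stance_n: int = 1,
                  min_swing_n: int = 1) -> "StanceMask":
        """Clean a raw per-sample mask by minimum stance/swing durations.

        Swing gaps shorter than ``min_swing_n`` are merged into stance first,
        then stance intervals shorter than ``min_stance_n`` are removed.
        """
        m = np.asarray(mask, dtype=bool).copy()
        for s, e in _bool_runs(~m):
            interior = s > 0 and e < m.size
            if interior and (e - s) < min_swing_n:
                m[s:e] = True
        for s, e in _bool_runs(m):
            if (e - s) < min_stance_n:
                m[s:e] = False
        return cls(mask=m, intervals=_bool_runs(m))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.intervals:
            self.intervals = _bool_runs(self.mask)


@dataclass
class NavTrajectory:
    """Per-sample foot pose in the local level frame.

    ``quat`` stores body-to-nav unit quaternions in scalar-last (x, y, z, w)
    order.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    quat: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (self.pos.shape == (n, 3) and self.vel.shape == (n, 3)
                and self.quat.shape == (n, 4)):
            raise ValueError("trajectory arrays must share length with t")
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must be unit norm")

    def rotations(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    def __len__(self) -> int:
        return int(len(self.t))


def estimate_initial_attitude(rec: ImuRecording, still_window_s: float = 1.0,
                              config: RunConfig | None = None) -> Rotation:
    """Roll/pitch initial attitude from accelerometer levelling.

    Searches the recording head for the first window of ``still_window_s``
    during which the angular rate stays below the quasi-static threshold,
    averages the specific force over it and returns the minimal rotation
    aligning that mean with the vertical.  Yaw is set to zero (unobservable).
    """
    config = config or RunConfig()
    n_w = max(2, int(round(still_window_s * rec.sample_rate_hz)))
    gyro_mag = np.linalg.norm(rec.gyro, axis=1)
    quiet = gyro_mag < config.events.still_gyro_thresh
    # first index where a full window is quiet
    csum = np.cumsum(np.concatenate(([0], quiet.astype(int))))
    start = -1
    for k in range(0, len(rec) - n_w + 1):
        if csum[k + n_w] - csum[k] == n_w:
            start = k
            break
    if start < 0:
        raise InitializationError(
            "no quasi-static segment found for attitude initialisation; "
            "record a longer standstill before walking")
    a_mean = rec.accel[start:start + n_w].mean(axis=0)
    norm = np.linalg.norm(a_mean)
    if norm == 0:
        raise InitializationError("zero mean specific force in still window")
    up_body = a_mean / norm
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [up_body])
    return rot


def detect_stance(rec: ImuRecording, config: RunConfig | None = None) -> StanceMask:
    """Flag the zero-translation (stance) samples of a recording.

    The per-sample statistic combines the squared deviation of the specific
    force magnitude from gravity with the squared angular rate, each scaled
    by its noise variance and a configurable weight.  A sliding window of
    ``detector.window_s`` averages the statistic; every sample covered by at
    least one sub-threshold window is marked stationary, which keeps the
    stance boundaries unbiased.  The mask is then cleaned with the minimum
    stance and swing durations.
    """
    config = (config or RunConfig()).validate()
    det = config.detector
    g = config.gravity_mps2
    a_mag = np.linalg.norm(rec.accel, axis=1)
    stat = det.accel_weight * (a_mag - g) ** 2 / det.accel_sigma ** 2
    if det.gyro_weight > 0:
        stat = stat + det.gyro_weight * (
            np.linalg.norm(rec.gyro, axis=1) ** 2 / det.gyro_sigma ** 2)
    w = max(3, int(round(det.window_s * rec.sample_rate_hz)))
    w = min(w, len(rec))
    csum = np.cumsum(np.concatenate(([0.0], stat)))
    t_win = (csum[w:] - csum[:-w]) / w  # statistic of window starting at k
    passing = t_win < det.threshold
    cover = np.zeros(len(rec) + 1, dtype=int)
    starts = np.flatnonzero(passing)
    np.add.at(cover, starts, 1)
    np.add.at(cover, starts + w, -1)
    raw = np.cumsum(cover[:-1]) > 0
    fs = rec.sample_rate_hz
    return StanceMask.from_mask(
        raw,
        min_stance_n=max(1, int(round(det.min_stance_s * fs))),
        min_swing_n=max(1, int(round(det.min_swing_s * fs))),
    )


def _qmul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product of scalar-last quaternions (q1 then rotate by... q1*q2)."""
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array([
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    ])


def _quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(rv)
    if angle < 1e-12:
        return np.array([0.5 * rv[0], 0.5 * rv[1], 0.5 * rv[2], 1.0]) / np.sqrt(
            1.0 + 0.25 * angle ** 2)
    axis = rv / angle
    s = np.sin(0.5 * angle)
    return np.array([axis[0] * s, axis[1] * s, axis[2] * s, np.cos(0.5 * angle)])


def _rotmat(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def strapdown(rec: ImuRecording, init_attitude: Rotation,
              init_velocity: np.ndarray | None = None,
              gravity: float = 9.81) -> NavTrajectory:
    """Open-loop strapdown mechanisation (no corrections).

    Orientation is propagated by quaternion integration of the angular rate
    (midpoint rule); velocity integrates the rotated specific force plus
    gravity and position integrates velocity, both trapezoidally.
    """
    n = len(rec)
    dt = np.diff(rec.t)
    q = np.empty((n, 4))
    q[0] = init_attitude.as_quat()
    if abs(np.linalg.norm(q[0]) - 1.0) > 1e-6:
        raise ValueError("initial attitude quaternion must be unit norm")
    omega_bar = 0.5 * (rec.gyro[:-1] + rec.gyro[1:])
    dq = Rotation.from_rotvec(omega_bar * dt[:, None]).as_quat()
    for k in range(n - 1):
        qk = _qmul(q[k], dq[k])
        q[k + 1] = qk / np.linalg.norm(qk)
    g_vec = np.array([0.0, 0.0, -gravity])
    f_nav = Rotation.from_quat(q).apply(rec.accel) + g_vec
    vel = np.empty((n, 3))
    vel[0] = np.zeros(3) if init_velocity is None else np.asarray(init_velocity, float)
    vel[1:] = vel[0] + np.cumsum(0.5 * (f_nav[:-1] + f_nav[1:]) * dt[:, None], axis=0)
    pos = np.empty((n, 3))
    pos[0] = 0.0
    pos[1:] = np.cumsum(0.5 * (vel[:-1] + vel[1:]) * dt[:, None], axis=0)
    return NavTrajectory(t=rec.t.copy(), pos=pos, vel=vel, quat=q)


def run_zupt_ekf(rec: ImuRecording, mask: StanceMask,
                 config: RunConfig | None = None,
                 init_attitude: Rotation | None = None) -> NavTrajectory:
    """ZUPT-aided trajectory estimate via a 9-state error Kalman filter.

    Error state: attitude (nav frame, rad), velocity (m/s), position (m).
    Prediction follows the strapdown mechanisation; at every stance sample a
    zero-velocity measurement is applied and the estimated errors are fed
    back into the nominal state.
    """
    config = (config or RunConfig()).validate()
    if len(mask.mask) != len(rec):
        raise ValueError("stance mask length must match recording")
    if init_attitude is None:
        init_attitude = estimate_initial_attitude(
            rec, config.events.still_window_s, config)
    if not mask.mask.any():
        log.warning("all-false stance mask: returning open-loop strapdown result")
        return strapdown(rec, init_attitude, gravity=config.gravity_mps2)

    gyro = rec.gyro
    if config.filter.estimate_gyro_bias:
        # calibrate the constant gyro bias on the quiet samples of the
        # leading stance (a persistent bias is otherwise unobservable to a
        # 9-state filter and causes a slow systematic position drift)
        s0, e0 = mask.intervals[0]
        head = gyro[s0:e0]
        quiet = np.linalg.norm(head, axis=1) < config.events.footflat_gyro_thresh
        if quiet.sum() >= 20:
            # median per axis: robust to stray motion samples at the
            # stance boundary
            bias = np.median(head[quiet], axis=0)
            gyro = gyro - bias
            log.info("initial-standstill gyro bias %s rad/s removed", bias)
        else:
            log.warning("no quiet leading stance: gyro bias not calibrated")

    n = len(rec)
    g_vec = np.array([0.0, 0.0, -config.gravity_mps2])
    fc = config.filter
    q = np.empty((n, 4))
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    q[0] = init_attitude.as_quat()

    P = np.diag([fc.init_att_std ** 2] * 3 + [fc.init_vel_std ** 2] * 3
                + [fc.init_pos_std ** 2] * 3)
    R_meas = np.eye(3) * fc.zupt_noise ** 2
    stance = mask.mask

    dt_arr = np.diff(rec.t)
    omega_bar = 0.5 * (gyro[:-1] + gyro[1:])
    dq_all = Rotation.from_rotvec(omega_bar * dt_arr[:, None]).as_quat()

    f_nav_prev = _rotmat(q[0]) @ rec.accel[0] + g_vec
    I9 = np.eye(9)
    for k in range(1, n):
        dt = dt_arr[k - 1]
        qk = _qmul(q[k - 1], dq_all[k - 1])
        q[k] = qk / np.linalg.norm(qk)
        Rk = _rotmat(q[k])
        f_nav = Rk @ rec.accel[k] + g_vec
        vel[k] = vel[k - 1] + 0.5 * (f_nav_prev + f_nav) * dt
        pos[k] = pos[k - 1] + 0.5 * (vel[k - 1] + vel[k]) * dt

        F = I9.copy()
        F[3:6, 0:3] = -_skew(f_nav) * dt
        F[6:9, 3:6] = np.eye(3) * dt
        Q = np.diag([fc.gyro_noise ** 2 * dt] * 3
                    + [fc.accel_noise ** 2 * dt] * 3 + [0.0] * 3)
        P = F @ P @ F.T + Q

        if stance[k]:
            S = P[3:6, 3:6] + R_meas
            K = np.linalg.solve(S.T, P[:, 3:6].T).T  # P H^T S^-1
            dx = K @ vel[k]
            dq_corr = _quat_from_rotvec(-dx[0:3])
            qc = _qmul(dq_corr, q[k])
            q[k] = qc / np.linalg.norm(qc)
            vel[k] = vel[k] - dx[3:6]
            pos[k] = pos[k] - dx[6:9]
            P = P - K @ P[3:6, :]
            P = 0.5 * (P + P.T)
            f_nav = _rotmat(q[k]) @ rec.accel[k] + g_vec
        f_nav_prev = f_nav

    traj = NavTrajectory(t=rec.t.copy(), pos=pos, vel=vel, quat=q)
    stance_speed = np.linalg.norm(vel[stance], axis=1)
    if stance_speed.size and stance_speed.mean() > fc.stance_speed_contract:
        log.warning("mean stance speed %.3f m/s exceeds the ZUPT contract %.3f",
                    stance_speed.mean(), fc.stance_speed_contract)
    return traj
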