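"""Synthetic gait: ground-truth foot trajectories, IMU signals and cohorts.

The walking model is a planar sagittal gait cycle.  Each stride consists of
a push-off (pitch rolls from flat to the toe-off angle), a swing (the foot
advances one stride length along the heading and rises to the clearance
apex while the pitch sweeps from the toe-off to the heel-strike angle), a
loading phase (pitch returns to flat) and a stationary foot-flat.  All
transitions use quintic smoothstep blends, so position, velocity and
acceleration are continuous and the velocity is exactly zero outside the
swing.  The sensor is treated as a point on the foot: the pivoting at
loading and push-off rotates it but does not translate it.

Because kinematics are available in closed form, the synthetic IMU signal
(specific force and body angular rate) is exact up to the configured sensor
noise, which makes the generator a quantitative oracle for the INS-ZUPT
pipeline.

Phase durations are snapped to whole samples (and the swing to an even
sample count so the apex is sampled exactly); the realised profile is
reported alongside the requested one.

The cohort generator draws a two-group (fallers / non-fallers) table of
clinical and gait variables from truncated normal marginals coupled through
a single latent "mobility" factor, so that gait speed, TUG, SPPB and
fear-of-falling scores correlate with realistic signs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.spatial.transform import Rotation

from .io import ImuRecording
from .metrics import MEAN_LABELS, STD_LABELS, StrideParams, StrideSegment

__all__ = [
    "GaitProfile",
    "NoiseModel",
    "GroundTruth",
    "VarSpec",
    "CatSpec",
    "CohortSimConfig",
    "synth_trajectory",
    "synth_imu",
    "synth_walk",
    "synth_cohort",
    "random_profile",
]


# quintic smoothstep and derivatives: s(0)=0, s(1)=1, s'=s''=0 at both ends
def _s(u):
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


def _s1(u):
    return 30.0 * u * u * (1.0 - u) ** 2


def _s2(u):
    return 60.0 * u * (1.0 - u) * (1.0 - 2.0 * u)


def _bump(u):
    """Single-apex swing arc: 0 at both ends, exactly 1 at u = 0.5, C^2."""
    u = np.asarray(u, dtype=float)
    return np.where(u <= 0.5, _s(2.0 * u), _s(2.0 * (1.0 - u)))


def _bump1(u):
    u = np.asarray(u, dtype=float)
    return np.where(u <= 0.5, 2.0 * _s1(2.0 * u), -2.0 * _s1(2.0 * (1.0 - u)))


def _bump2(u):
    u = np.asarray(u, dtype=float)
    return np.where(u <= 0.5, 4.0 * _s2(2.0 * u), 4.0 * _s2(2.0 * (1.0 - u)))


@dataclass
class GaitProfile:
    """Parameters of a constant-profile walk.

    Phase percentages refer to the gait cycle time (GCT) and must sum to
    100.  Defaults correspond to a slow elderly gait: 0.9 m strides at
    1.2 s per cycle (0.75 m/s).
    """

    n_strides: int = 20
    stride_length_m: float = 0.9
    gct_s: float = 1.2
    loading_pct: float = 11.0
    footflat_pct: float = 42.9
    pushing_pct: float = 17.8
    swing_pct: float = 28.3
    heel_strike_angle_deg: float = 14.8
    toe_off_angle_deg: float = -52.3
    clearance_m: float = 0.16
    sample_rate_hz: float = 100.0
    heading_deg: float = 0.0
    lead_still_s: float = 3.5
    trail_still_s: float = 2.0

    def validate(self) -> "GaitProfile":
        total = self.loading_pct + self.footflat_pct + self.pushing_pct + self.swing_pct
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"phase percentages must sum to 100, got {total}")
        if min(self.loading_pct, self.footflat_pct, self.pushing_pct,
               self.swing_pct) <= 0:
            raise ValueError("phase percentages must be strictly positive")
        if self.stride_length_m <= 0 or self.gct_s <= 0:
            raise ValueError("stride_length_m and gct_s must be > 0")
        if self.clearance_m < 0:
            raise ValueError("clearance_m must be >= 0")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.heel_strike_angle_deg <= 0:
            raise ValueError("heel_strike_angle_deg must be > 0 (toes-up)")
        if self.toe_off_angle_deg >= 0:
            raise ValueError("toe_off_angle_deg must be < 0 (toes-down)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.lead_still_s < 0 or self.trail_still_s < 0:
            raise ValueError("standstill durations must be >= 0")
        return self


@dataclass
class NoiseModel:
    """Additive sensor error model: constant bias plus white noise.

    Sigmas are per-sample standard deviations; the bias is a constant
    vector of the given magnitude with a seed-determined random direction.
    Identical seeds give identical noise realisations.
    """

    accel_white_sigma: float = 0.05   # m/s^2
    gyro_white_sigma: float = 0.005   # rad/s
    accel_bias: float = 0.02          # m/s^2
    gyro_bias: float = 0.002          # rad/s
    seed: int = 0

    def validate(self) -> "NoiseModel":
        if min(self.accel_white_sigma, self.gyro_white_sigma,
               self.accel_bias, self.gyro_bias) < 0:
            raise ValueError("noise magnitudes must be >= 0")
        return self


@dataclass
class GroundTruth:
    """Exact foot kinematics of a simulated walk plus per-stride truth."""

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    quat: np.ndarray          # body-to-nav, scalar-last
    pitch_deg: np.ndarray
    omega_body: np.ndarray
    mask: np.ndarray          # True where the foot does not translate
    stance_intervals: list[tuple[int, int]]
    events: list[StrideSegment]          # complete strides only
    true_strides: list[StrideParams]
    realized: dict[str, float]
    profile: GaitProfile
    sample_rate_hz: float
    gravity_mps2: float = 9.81


def _phase_counts(profile: GaitProfile) -> dict[str, int]:
    fs = profile.sample_rate_hz
    n = {}
    for name, pct in (("loading", profile.loading_pct),
                      ("footflat", profile.footflat_pct),
                      ("pushing", profile.pushing_pct)):
        n[name] = max(1, int(round(pct / 100.0 * profile.gct_s * fs)))
    n_swing = int(round(profile.swing_pct / 100.0 * profile.gct_s * fs))
    n_swing = max(2, n_swing + (n_swing % 2))  # even so the apex is sampled
    n["swing"] = n_swing
    return n


def synth_trajectory(profile: GaitProfile) -> GroundTruth:
    """Generate the exact foot trajectory of a constant-profile walk."""
    profile = profile.validate()
    fs = profile.sample_rate_hz
    dt = 1.0 / fs
    counts = _phase_counts(profile)
    n_lead = int(round(profile.lead_still_s * fs))
    n_trail = int(round(profile.trail_still_s * fs))
    n_cycle = sum(counts.values())
    sl = profile.stride_length_m
    clr = profile.clearance_m
    hs_deg = profile.heel_strike_angle_deg
    to_deg = profile.toe_off_angle_deg

    # phase schedule: lead still, then per stride push/swing/load/footflat,
    # then trail still
    phases: list[tuple[str, int]] = [("still", n_lead)]
    for _ in range(profile.n_strides):
        phases += [("pushing", counts["pushing"]), ("swing", counts["swing"]),
                   ("loading", counts["loading"]), ("footflat", counts["footflat"])]
    phases.append(("still", n_trail))

    n_total = sum(n for _, n in phases)
    d = np.zeros(n_total)        # along-heading displacement
    dd = np.zeros(n_total)
    ddd = np.zeros(n_total)
    z = np.zeros(n_total)
    dz = np.zeros(n_total)
    ddz = np.zeros(n_total)
    theta = np.zeros(n_total)    # pitch, degrees, toes-up positive
    dtheta = np.zeros(n_total)   # deg/s

    swing_starts: list[int] = []
    hs_idx: list[int] = []
    ff_bounds: list[tuple[int, int]] = []

    cursor = 0
    x_c = 0.0
    for kind, n in phases:
        if n == 0:
            continue
        sl_idx = slice(cursor, cursor + n)
        u = np.arange(n) / n
        T = n * dt
        if kind in ("still", "footflat"):
            d[sl_idx] = x_c
        elif kind == "pushing":
            d[sl_idx] = x_c
            theta[sl_idx] = to_deg * _s(u)
            dtheta[sl_idx] = to_deg * _s1(u) / T
        elif kind == "swing":
            swing_starts.append(cursor)
            d[sl_idx] = x_c + sl * _s(u)
            dd[sl_idx] = sl * _s1(u) / T
            ddd[sl_idx] = sl * _s2(u) / T ** 2
            z[sl_idx] = clr * _bump(u)
            dz[sl_idx] = clr * _bump1(u) / T
            ddz[sl_idx] = clr * _bump2(u) / T ** 2
            theta[sl_idx] = to_deg + (hs_deg - to_deg) * _s(u)
            dtheta[sl_idx] = (hs_deg - to_deg) * _s1(u) / T
            x_c += sl
        elif kind == "loading":
            hs_idx.append(cursor)
            d[sl_idx] = x_c
            theta[sl_idx] = hs_deg * (1.0 - _s(u))
            dtheta[sl_idx] = -hs_deg * _s1(u) / T
            ff_bounds.append((cursor + n, cursor + n + counts["footflat"]))
        cursor += n
    # the final foot-flat merges with the trailing standstill
    if ff_bounds:
        s_last, _ = ff_bounds[-1]
        ff_bounds[-1] = (s_last, n_total)

    t = np.arange(n_total) * dt
    psi = np.deg2rad(profile.heading_deg)
    c, s_ = np.cos(psi), np.sin(psi)
    pos = np.column_stack([d * c, d * s_, z])
    vel = np.column_stack([dd * c, dd * s_, dz])
    acc = np.column_stack([ddd * c, ddd * s_, ddz])
    th_rad = np.deg2rad(theta)
    quat = Rotation.from_euler(
        "ZY", np.column_stack([np.full(n_total, psi), -th_rad])).as_quat()
    omega_body = np.column_stack(
        [np.zeros(n_total), -np.deg2rad(dtheta), np.zeros(n_total)])

    mask = np.ones(n_total, dtype=bool)
    for ss in swing_starts:
        mask[ss:ss + counts["swing"]] = False
    stance_intervals = []
    prev = 0
    for ss in swing_starts:
        stance_intervals.append((prev, ss))
        prev = ss + counts["swing"]
    stance_intervals.append((prev, n_total))

    realized_gct = n_cycle * dt
    realized = {
        "gct_s": realized_gct,
        "loading_pct": counts["loading"] / n_cycle * 100.0,
        "footflat_pct": counts["footflat"] / n_cycle * 100.0,
        "pushing_pct": counts["pushing"] / n_cycle * 100.0,
        "swing_pct": counts["swing"] / n_cycle * 100.0,
        "stride_length_m": sl,
        "clearance_m": clr,
        "heel_strike_angle_deg": hs_deg,
        "toe_off_angle_deg": to_deg,
        "step_speed_mps": sl / (counts["swing"] * dt),
        "velocity_mps": sl / realized_gct,
        "cadence_per_min": 60.0 / realized_gct,
    }

    # 3D path over one stride: arc length of the swing (stance contributes 0)
    ug = np.linspace(0.0, 1.0, 4001)
    speed_u = np.sqrt((sl * _s1(ug)) ** 2 + (clr * _bump1(ug)) ** 2)
    path3d = float(simpson(speed_u, x=ug))

    events: list[StrideSegment] = []
    true_strides: list[StrideParams] = []
    for j in range(len(hs_idx) - 1):
        seg = StrideSegment(
            hs=hs_idx[j], ff_start=ff_bounds[j][0], ff_end=ff_bounds[j][1],
            to=swing_starts[j + 1], next_hs=hs_idx[j + 1],
            next_ff_start=ff_bounds[j + 1][0], next_ff_end=ff_bounds[j + 1][1])
        events.append(seg)
        true_strides.append(StrideParams(
            t_hs_s=t[seg.hs], gct_s=realized_gct,
            swing_pct=realized["swing_pct"], loading_pct=realized["loading_pct"],
            footflat_pct=realized["footflat_pct"], pushing_pct=realized["pushing_pct"],
            heel_strike_angle_deg=hs_deg, toe_off_angle_deg=to_deg,
            stride_length_m=sl, path2d_m=sl, path3d_m=path3d,
            clearance_m=clr, step_speed_mps=realized["step_speed_mps"]))

    return GroundTruth(
        t=t, pos=pos, vel=vel, acc=acc, quat=quat, pitch_deg=theta,
        omega_body=omega_body, mask=mask, stance_intervals=stance_intervals,
        events=events, true_strides=true_strides, realized=realized,
        profile=profile, sample_rate_hz=fs)


def synth_imu(truth: GroundTruth, noise: NoiseModel | None = None) -> ImuRecording:
    """Synthesise the IMU recording that would observe a ground-truth walk.

    The specific force is the navigation-frame acceleration minus gravity,
    rotated into the body frame; the angular rate is the exact body rate of
    the planar pitch motion.  Bias and white noise follow the noise model
    and are deterministic given its seed.
    """
    noise = (noise or NoiseModel()).validate()
    n = len(truth.t)
    if n < 3:
        raise ValueError("need at least 3 samples to synthesise an IMU signal")
    g_vec = np.array([0.0, 0.0, -truth.gravity_mps2])
    f_body = Rotation.from_quat(truth.quat).inv().apply(truth.acc - g_vec)
    gyro = truth.omega_body.copy()

    rng = np.random.default_rng(noise.seed)

    def _bias_vec(magnitude: float) -> np.ndarray:
        v = rng.normal(size=3)
        nv = np.linalg.norm(v)
        return magnitude * (v / nv if nv > 0 else np.array([0.0, 0.0, 1.0]))

    accel = f_body + _bias_vec(noise.accel_bias)
    gyro = gyro + _bias_vec(noise.gyro_bias)
    if noise.accel_white_sigma > 0:
        accel = accel + rng.normal(0.0, noise.accel_white_sigma, (n, 3))
    if noise.gyro_white_sigma > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_white_sigma, (n, 3))
    return ImuRecording(
        t=truth.t.copy(), accel=accel, gyro=gyro,
        sample_rate_hz=truth.sample_rate_hz,
        meta={"synthetic": True, "seed": noise.seed})


def synth_walk(profile: GaitProfile | None = None,
               noise: NoiseModel | None = None
               ) -> tuple[ImuRecording, GroundTruth]:
    """Convenience wrapper: trajectory plus its noisy IMU recording."""
    truth = synth_trajectory(profile or GaitProfile())
    return synth_imu(truth, noise), truth


def random_profile(rng: np.random.Generator,
                   speed_range: tuple[float, float] = (0.4, 1.4),
                   n_strides: int = 20,
                   sample_rate_hz: float = 100.0) -> GaitProfile:
    """Draw a plausible profile spanning the requested walking-speed range."""
    speed = rng.uniform(*speed_range)
    gct = rng.uniform(1.0, 1.4)
    phases = np.array([11.0, 42.9, 17.8, 28.3]) + rng.uniform(-2, 2, 4)
    phases = phases / phases.sum() * 100.0
    return GaitProfile(
        n_strides=n_strides,
        stride_length_m=speed * gct,
        gct_s=gct,
        loading_pct=phases[0], footflat_pct=phases[1],
        pushing_pct=phases[2], swing_pct=phases[3],
        heel_strike_angle_deg=rng.uniform(8.0, 25.0),
        toe_off_angle_deg=rng.uniform(-70.0, -30.0),
        clearance_m=rng.uniform(0.08, 0.30),
        sample_rate_hz=sample_rate_hz,
        heading_deg=rng.uniform(0.0, 360.0),
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class VarSpec:
    """Group-wise truncated-normal marginal of one continuous variable."""

    mean_nonfaller: float
    sd_nonfaller: float
    mean_faller: float
    sd_faller: float
    lo: float = -np.inf
    hi: float = np.inf
    integer: bool = False


@dataclass
class CatSpec:
    """Group-wise level probabilities of one categorical variable."""

    levels: list[str]
    p_nonfaller: list[float]
    p_faller: list[float]


def _default_variables() -> dict[str, VarSpec]:
    v = {
        # demographics and clinical scales
        "Age": VarSpec(80.9, 6.5, 84.2, 5.5, 70, 100, integer=True),
        "Weight": VarSpec(65.6, 12.7, 63.1, 13.4, 30, 110),
        "Height": VarSpec(1.62, 0.10, 1.52, 0.08, 1.30, 1.90),
        "IMC": VarSpec(25.0, 4.1, 26.2, 7.5, 12, 45),
        "GDS": VarSpec(1.7, 1.4, 2.3, 1.7, 1, 7, integer=True),
        "Time_4m_walk": VarSpec(4.5, 1.9, 7.3, 4.8, 2.0, 40.0),
        "Speed_4m_walk": VarSpec(1.0, 0.3, 0.7, 0.2, 0.05, 2.0),
        "FRG_Total": VarSpec(0.1, 0.3, 0.7, 1.0, 0, 4, integer=True),
        "SPPB_Total": VarSpec(9.8, 2.4, 7.5, 2.5, 0, 12, integer=True),
        "TUG": VarSpec(11.8, 4.7, 17.8, 6.9, 3.0, 60.0),
        "FES1": VarSpec(8.5, 2.7, 12.2, 5.0, 7, 28, integer=True),
        # gait means
        "Total distance (m)": VarSpec(1321.4, 614.3, 724.5, 449.9, 50, 3000),
        "Total time (s)": VarSpec(1443.5, 397.3, 1136.6, 396.0, 120, 2400),
        "Total steps": VarSpec(1268.6, 373.8, 916.2, 376.6, 100, 2500, integer=True),
        "Gait cycle time - GCT (s)": VarSpec(1.2, 0.1, 1.3, 0.2, 0.5, 3.0),
        "Stance-pushing time (% GCT)": VarSpec(18.6, 2.7, 17.0, 2.6, 1, 40),
        "Swing (% GCT)": VarSpec(30.0, 2.3, 26.8, 3.7, 5, 50),
        "Stance-loading time (% GCT)": VarSpec(11.8, 2.3, 10.2, 2.2, 1, 30),
        "Stance-FootFlat time (% GCT)": VarSpec(39.4, 6.1, 46.2, 7.5, 10, 80),
        "Toe off angle (deg)": VarSpec(-58.7, 13.2, -46.7, 11.2, -90, -5),
        "Heel strike angle (deg)": VarSpec(17.9, 7.0, 12.0, 5.6, 0, 45),
        "Cadence (steps/min)": VarSpec(52.1, 5.8, 46.6, 8.0, 20, 80),
        "StepSpeed (m/s)": VarSpec(1.0, 0.3, 0.7, 0.2, 0.05, 2.0),
        "StrideLength - SL (m)": VarSpec(1.0, 0.2, 0.8, 0.2, 0.2, 1.8),
        "3D path (m)": VarSpec(1.1, 0.3, 0.9, 0.2, 0.2, 2.0),
        "2D path (m)": VarSpec(1.1, 0.3, 0.8, 0.2, 0.2, 1.9),
        "Clearance (m)": VarSpec(0.20, 0.14, 0.13, 0.09, 0.01, 0.6),
        "Velocity (m/s)": VarSpec(0.9, 0.3, 0.6, 0.2, 0.05, 1.8),
        # gait inter-stride variability
        "GCT STD": VarSpec(0.08, 0.04, 0.12, 0.04, 0.0, 0.3),
        "Stance-pushing time STD": VarSpec(1.79, 0.60, 1.95, 0.59, 0.0, 5.0),
        "Swing STD": VarSpec(2.10, 0.71, 2.62, 0.66, 0.0, 6.0),
        "Stance-loading time STD": VarSpec(1.65, 0.36, 1.71, 0.49, 0.0, 4.0),
        "Stance-FootFlat time STD": VarSpec(3.68, 1.46, 4.60, 1.38, 0.0, 10.0),
        "Toe off angle STD": VarSpec(5.61, 1.41, 5.64, 1.41, 0.0, 12.0),
        "Heel strike angle STD": VarSpec(2.84, 0.83, 2.31, 0.83, 0.0, 6.0),
        "Cadence STD": VarSpec(3.79, 1.14, 4.45, 1.33, 0.0, 9.0),
        "StepSpeed STD": VarSpec(0.11, 0.02, 0.10, 0.03, 0.0, 0.3),
        "StrideLength STD": VarSpec(0.11, 0.03, 0.10, 0.03, 0.0, 0.3),
        "3D path STD": VarSpec(0.10, 0.03, 0.10, 0.02, 0.0, 0.3),
        "2D path STD": VarSpec(0.12, 0.04, 0.11, 0.03, 0.0, 0.3),
        "Clearance STD": VarSpec(0.06, 0.04, 0.04, 0.02, 0.0, 0.2),
    }
    return v


def _default_categoricals() -> dict[str, CatSpec]:
    return {
        "Sex": CatSpec(["Male", "Female"], [26 / 77, 51 / 77], [19 / 86, 67 / 86]),
        "Living_Site": CatSpec(["Home", "Residence"],
                               [55 / 77, 22 / 77], [55 / 86, 31 / 86]),
        "Terrain": CatSpec(["Flat terrain", "Mix terrain"],
                           [33 / 77, 44 / 77], [77 / 86, 9 / 86]),
        "Test_Site": CatSpec(["Hospital", "Residence", "Home"],
                             [12 / 77, 22 / 77, 43 / 77],
                             [52 / 86, 30 / 86, 4 / 86]),
    }


@dataclass
class CohortSimConfig:
    """Two-group cohort simulation settings.

    Continuous variables use group means/SDs with range truncation; a
    single latent mobility factor (loading ``latent_loading``) couples them
    so cross-variable correlations carry the expected signs: each variable
    loads with the sign of its non-faller minus faller group difference.
    """

    n_fallers: int = 86
    n_nonfallers: int = 77
    latent_loading: float = 0.6
    seed: int = 0
    variables: dict[str, VarSpec] = field(default_factory=_default_variables)
    categoricals: dict[str, CatSpec] = field(default_factory=_default_categoricals)

    def validate(self) -> "CohortSimConfig":
        if self.n_fallers < 1 or self.n_nonfallers < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 <= self.latent_loading < 1.0:
            raise ValueError("latent_loading must be in [0, 1)")
        for name, spec in self.variables.items():
            if spec.sd_nonfaller < 0 or spec.sd_faller < 0:
                raise ValueError(f"negative SD for variable {name}")
            if spec.lo >= spec.hi:
                raise ValueError(f"empty truncation range for variable {name}")
        for name, spec in self.categoricals.items():
            for p in (spec.p_nonfaller, spec.p_faller):
                if len(p) != len(spec.levels) or abs(sum(p) - 1.0) > 1e-6:
                    raise ValueError(f"invalid level probabilities for {name}")
        return self


def default_cohort_config(**overrides) -> CohortSimConfig:
    cfg = CohortSimConfig(**overrides)
    cfg.variables = copy.deepcopy(cfg.variables)
    return cfg.validate()


def synth_cohort(config: CohortSimConfig | None = None) -> pd.DataFrame:
    """Simulate a faller / non-faller cohort table.

    Returns one row per subject with the clinical variables, the walk
    summary variables and the FALLS label.  Deterministic given the seed.
    """
    config = (config or CohortSimConfig()).validate()
    rng = np.random.default_rng(config.seed)
    lam = config.latent_loading
    rows = []
    sid = 0
    for falls, n_group in ((False, config.n_nonfallers), (True, config.n_fallers)):
        z = rng.standard_normal(n_group)  # latent mobility factor
        group_cols: dict[str, np.ndarray] = {}
        for name, spec in config.variables.items():
            mu = spec.mean_faller if falls else spec.mean_nonfaller
            sd = spec.sd_faller if falls else spec.sd_nonfaller
            sign = np.sign(spec.mean_nonfaller - spec.mean_faller) or 1.0
            eps = rng.standard_normal(n_group)
            x = mu + sd * (lam * sign * z + np.sqrt(1.0 - lam ** 2) * eps)
            x = np.clip(x, spec.lo, spec.hi)
            if spec.integer:
                x = np.round(x)
            group_cols[name] = x
        cat_cols: dict[str, np.ndarray] = {}
        for name, spec in config.categoricals.items():
            p = spec.p_faller if falls else spec.p_nonfaller
            cat_cols[name] = rng.choice(spec.levels, size=n_group, p=p)
        for i in range(n_group):
            row = {"id": f"S{sid:04d}", "FALLS": falls}
            for name in config.categoricals:
                row[name] = cat_cols[name][i]
            for name in config.variables:
                row[name] = group_cols[name][i]
            rows.append(row)
            sid += 1
    df = pd.DataFrame(rows)
    front = ["id", "FALLS", "Age", "Sex", "Weight", "Height", "IMC", "GDS",
             "Living_Site", "Terrain", "Test_Site", "Time_4m_walk",
             "Speed_4m_walk", "FRG_Total", "SPPB_Total", "TUG", "FES1"]
    ordered = front + MEAN_LABELS + STD_LABELS
    return df[[c for c in ordered if c in df.columns]]
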