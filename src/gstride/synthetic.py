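"""Forward simulation: ground-truth-known IMU walks and clinical cohorts.

Two generators make every downstream stage testable without any recording:

* :func:`generate_gait_imu` forward-simulates a foot-mounted IMU during a
  straight, level walk whose stride length, cycle time, clearance, contact
  angles and phase split are commanded exactly, and returns both the noisy
  sensor stream and the ground truth (events, stance schedule, true
  trajectory) for oracle comparisons.
* :func:`generate_cohort` draws a two-group faller / non-faller cohort with
  per-variable group means and SDs, emulating a case-control study table.

Foot model
----------
The walk alternates motionless stance dwells and swings.  During stance the
sensor position is pinned while the foot pitches: a smooth ramp from the
heel-strike angle down to flat (loading), a flat dwell (foot-flat), and a
smooth ramp down to the toe-off angle (pushing).  The swing advances the
foot by one stride length with a minimum-jerk horizontal profile and a
single symmetric vertical arc whose apex is the commanded clearance, while
the pitch ramps from the toe-off angle back up to the heel-strike angle.
All profiles are C1, so the exact specific force and angular rate follow
in closed form and integrate cleanly at ordinary sample rates.

Sign convention: the heel-strike angle is positive (toes up), the toe-off
angle negative (toes down).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .reconstruct import DEFAULT_GRAVITY, ImuRecording

DEFAULT_PHASE_FRACTIONS = {
    "loading": 0.11,
    "foot_flat": 0.42,
    "pushing": 0.18,
    "swing": 0.29,
}

DEFAULT_SAMPLE_RATE = 100.0
DEFAULT_ACCEL_NOISE = 0.05  # m/s^2, typical consumer MEMS white noise at 100 Hz
DEFAULT_GYRO_NOISE = 0.005  # rad/s


# ---------------------------------------------------------------------------
# smooth motion primitives (u in [0, 1])


def _smoothstep(u):
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_d1(u):
    return 6.0 * u * (1.0 - u)


def _quintic(u):
    return u**3 * (10.0 - 15.0 * u + 6.0 * u * u)


def _quintic_d1(u):
    return 30.0 * (u * (1.0 - u)) ** 2


def _quintic_d2(u):
    return 60.0 * u * (1.0 - u) * (1.0 - 2.0 * u)


def _bump(u):
    return 64.0 * (u * (1.0 - u)) ** 3


def _bump_d1(u):
    return 64.0 * (3 * u**2 - 12 * u**3 + 15 * u**4 - 6 * u**5)


def _bump_d2(u):
    return 64.0 * (6 * u - 36 * u**2 + 60 * u**3 - 30 * u**4)


# ---------------------------------------------------------------------------


@dataclass
class GaitGroundTruth:
    """Commanded gait parameters plus the generator-filled ground truth.

    The scalar fields are inputs; ``stance_schedule`` (the n foot-flat
    dwells concluding each stride, the intervals a ZUPT detector should
    find), ``events`` (per complete heel-strike-to-heel-strike cycle) and
    the ``truth_*`` sample arrays are filled in by
    :func:`generate_gait_imu` for use as test oracles.
    """

    stride_length: float = 0.94
    gait_cycle_time: float = 1.20
    clearance: float = 0.18
    heel_strike_angle: float = 15.6  # deg, > 0 toes-up
    toe_off_angle: float = -53.9  # deg, < 0 toes-down
    phase_fractions: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS))
    n_strides: int = 20
    lead_dwell: float = 1.0
    tail_dwell: float = 1.0
    # --- filled by the generator ---
    stance_schedule: list | None = None
    events: list | None = None
    truth_time: np.ndarray | None = field(default=None, repr=False)
    truth_position: np.ndarray | None = field(default=None, repr=False)
    truth_velocity: np.ndarray | None = field(default=None, repr=False)
    truth_pitch_deg: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.gait_cycle_time <= 0:
            raise ValueError("gait_cycle_time must be > 0")
        if self.stride_length <= 0:
            raise ValueError("stride_length must be > 0")
        if self.clearance < 0:
            raise ValueError("clearance must be >= 0")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        keys = {"loading", "foot_flat", "pushing", "swing"}
        if set(self.phase_fractions) != keys:
            raise ValueError(f"phase_fractions must have keys {sorted(keys)}")
        vals = np.array([self.phase_fractions[k] for k in sorted(keys)])
        if np.any(vals < 0):
            raise ValueError("phase fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"phase fractions must sum to 1.0, got {vals.sum():.6f}"
            )
        if self.phase_fractions["swing"] <= 0:
            raise ValueError("swing fraction must be > 0")
        if self.heel_strike_angle < 0 or self.toe_off_angle > 0:
            raise ValueError(
                "sign convention: heel_strike_angle >= 0, toe_off_angle <= 0"
            )

    @property
    def total_displacement(self) -> float:
        return self.n_strides * self.stride_length

    def to_json(self, path) -> None:
        """Scalar ground truth + schedule/events as a JSON sidecar."""
        d = asdict(self)
        for k in ("truth_time", "truth_position", "truth_velocity", "truth_pitch_deg"):
            d.pop(k, None)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GaitGroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _build_segments(truth: GaitGroundTruth):
    """Lay the walk out on the time axis.

    Returns (segments, schedule, events): segments are tuples
    (kind, t0, duration, x0) with kind in {dwell, push, swing, load};
    schedule lists the n foot-flat dwells (toe-strike .. heel-off);
    events lists dicts for the n-1 complete HS->HS stride cycles.
    """
    gct = truth.gait_cycle_time
    pf = truth.phase_fractions
    t_load, t_ff = pf["loading"] * gct, pf["foot_flat"] * gct
    t_push, t_sw = pf["pushing"] * gct, pf["swing"] * gct
    sl, n = truth.stride_length, truth.n_strides

    segs = []
    schedule = []
    hs, ts, ho, to = [], [], [], []
    t, x = 0.0, 0.0
    segs.append(("dwell", t, truth.lead_dwell, x))
    t += truth.lead_dwell
    for i in range(n):
        if t_push > 0:
            segs.append(("push", t, t_push, x))
            t += t_push
        to.append(t)  # toe-off launching swing i
        segs.append(("swing", t, t_sw, x))
        t += t_sw
        x += sl
        hs.append(t)  # heel-strike landing swing i
        if t_load > 0:
            segs.append(("load", t, t_load, x))
            t += t_load
        ts.append(t)
        dwell = t_ff + (truth.tail_dwell if i == n - 1 else 0.0)
        ho.append(t + t_ff)
        if dwell > 0:
            segs.append(("dwell", t, dwell, x))
            t += dwell
        # the motionless dwell of the last stride runs to the recording end
        schedule.append([ts[-1], t if i == n - 1 else ho[-1]])

    events = [
        {
            "heel_strike": hs[j],
            "toe_strike": ts[j],
            "heel_off": ho[j],
            "toe_off": to[j + 1],
            "end": hs[j + 1],
        }
        for j in range(n - 1)
    ]
    return segs, schedule, events, t


def generate_gait_imu(
    truth: GaitGroundTruth,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    accel_noise: float = DEFAULT_ACCEL_NOISE,
    gyro_noise: float = DEFAULT_GYRO_NOISE,
    seed: int | None = None,
    gravity: float = DEFAULT_GRAVITY,
) -> tuple[ImuRecording, GaitGroundTruth]:
    """Simulate the IMU stream of a commanded walk.

    The returned recording, stripped of its noise, double-integrates back
    to the commanded trajectory exactly (up to quadrature error); identical
    seeds give bit-identical recordings.

    Parameters
    ----------
    truth
        Commanded gait; validated, then returned with ground-truth fields
        (schedule, events, true trajectory) filled in.
    sample_rate
        Hz, >= 50.
    accel_noise, gyro_noise
        White-noise SDs added per sample (m/s^2, rad/s); >= 0.
    seed
        Seed for the noise stream.
    """
    truth.validate()
    if sample_rate < 50:
        raise ValueError("sample_rate must be >= 50 Hz")
    if accel_noise < 0 or gyro_noise < 0:
        raise ValueError("noise SDs must be >= 0")

    segs, schedule, events, t_total = _build_segments(truth)
    n_samp = int(round(t_total * sample_rate)) + 1
    t = np.arange(n_samp) / sample_rate
    t = t[t <= t_total + 1e-12]

    starts = np.array([s[1] for s in segs])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(segs) - 1)

    pos = np.zeros((t.size, 3))
    vel = np.zeros((t.size, 3))
    acc = np.zeros((t.size, 3))
    pitch = np.zeros(t.size)  # rad
    pitch_rate = np.zeros(t.size)

    th_hs = np.radians(truth.heel_strike_angle)
    th_to = np.radians(truth.toe_off_angle)
    sl, c = truth.stride_length, truth.clearance

    for k, (kind, t0, dur, x0) in enumerate(segs):
        sel = idx == k
        if not sel.any():
            continue
        u = (t[sel] - t0) / dur
        u = np.clip(u, 0.0, 1.0)
        pos[sel, 0] = x0
        if kind == "dwell":
            pass  # flat, motionless
        elif kind == "push":
            pitch[sel] = th_to * _smoothstep(u)
            pitch_rate[sel] = th_to * _smoothstep_d1(u) / dur
        elif kind == "load":
            pitch[sel] = th_hs * (1.0 - _smoothstep(u))
            pitch_rate[sel] = -th_hs * _smoothstep_d1(u) / dur
        elif kind == "swing":
            pos[sel, 0] = x0 + sl * _quintic(u)
            pos[sel, 2] = c * _bump(u)
            vel[sel, 0] = sl * _quintic_d1(u) / dur
            vel[sel, 2] = c * _bump_d1(u) / dur
            acc[sel, 0] = sl * _quintic_d2(u) / dur**2
            acc[sel, 2] = c * _bump_d2(u) / dur**2
            pitch[sel] = th_to + (th_hs - th_to) * _smoothstep(u)
            pitch_rate[sel] = (th_hs - th_to) * _smoothstep_d1(u) / dur

    # specific force in the sensor frame: f_b = R(pitch)^T (a_w - g_w)
    cth, sth = np.cos(pitch), np.sin(pitch)
    az_g = acc[:, 2] + gravity
    f_b = np.zeros_like(acc)
    f_b[:, 0] = cth * acc[:, 0] + sth * az_g
    f_b[:, 2] = -sth * acc[:, 0] + cth * az_g
    # pure pitch about the world/body y-axis; Rdot = R [w]x gives w_y = -dpitch/dt
    gyr = np.zeros_like(acc)
    gyr[:, 1] = -pitch_rate

    rng = np.random.default_rng(seed)
    if accel_noise > 0:
        f_b = f_b + rng.normal(0.0, accel_noise, f_b.shape)
    if gyro_noise > 0:
        gyr = gyr + rng.normal(0.0, gyro_noise, gyr.shape)

    rec = ImuRecording(t=t, accel=f_b, gyro=gyr, sample_rate=sample_rate)
    truth.stance_schedule = schedule
    truth.events = events
    truth.truth_time = t
    truth.truth_position = pos
    truth.truth_velocity = vel
    truth.truth_pitch_deg = np.degrees(pitch)
    return rec, truth


def generate_stationary_imu(
    duration: float = 10.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    accel_noise: float = 0.0,
    gyro_noise: float = 0.0,
    seed: int | None = None,
    gravity: float = DEFAULT_GRAVITY,
) -> ImuRecording:
    """A motionless, level foot: accelerometer reads gravity only."""
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    accel = np.zeros((n, 3))
    accel[:, 2] = gravity
    gyro = np.zeros((n, 3))
    rng = np.random.default_rng(seed)
    if accel_noise > 0:
        accel += rng.normal(0.0, accel_noise, accel.shape)
    if gyro_noise > 0:
        gyro += rng.normal(0.0, gyro_noise, gyro.shape)
    return ImuRecording(t=t, accel=accel, gyro=gyro, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# cohort generator


@dataclass
class VariableSpec:
    """Group-wise distribution of one cohort variable.

    kind: 'continuous' (Gaussian), 'ordinal' (Gaussian rounded to integers
    and clipped to [lo, hi]) or 'binary' (Bernoulli with the group mean as
    success probability).
    """

    faller_mean: float
    faller_sd: float
    nonfaller_mean: float
    nonfaller_sd: float
    kind: str = "continuous"
    lo: float | None = None
    hi: float | None = None

    def validate(self, name: str) -> None:
        if self.faller_sd < 0 or self.nonfaller_sd < 0:
            raise ValueError(f"variable {name!r}: SDs must be >= 0")
        if self.kind not in ("continuous", "ordinal", "binary"):
            raise ValueError(f"variable {name!r}: unknown kind {self.kind!r}")


@dataclass
class CohortSpec:
    """Two-group cohort recipe: group sizes plus per-variable group
    means/SDs, with an optional logistic label model replacing the
    group-membership labels."""

    n_fallers: int
    n_nonfallers: int
    variables: dict
    label_model: dict | None = None  # {"intercept": b0, "coefficients": {var: b}}
    seed: int | None = None

    def validate(self) -> None:
        if self.n_fallers < 0 or self.n_nonfallers < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_fallers + self.n_nonfallers < 1:
            raise ValueError("cohort must have at least one participant")
        for name, v in self.variables.items():
            v.validate(name)
        if self.label_model is not None:
            missing = [
                k for k in self.label_model.get("coefficients", {}) if k not in self.variables
            ]
            if missing:
                raise ValueError(f"label_model references undefined variables: {missing}")

    def ensure_covers(self, names) -> None:
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise ValueError(
                f"cohort spec is missing variable definitions: {missing}"
            )


# Group defaults (faller_mean, faller_sd, nonfaller_mean, nonfaller_sd,
# kind, lo, hi).  Age/Sex/Weight/Height/BMI/GDS follow the published
# descriptives of the study cohort this generator emulates; every other
# entry is a documented synthetic-only default placing the group midpoint
# near the corresponding published univariate cut-off with roughly a
# 0.8-1 SD group separation.
_DEFAULT_VARIABLES: dict[str, tuple] = {
    "Age": (84.17, 5.48, 80.9, 6.5, "continuous", 70, 98),
    "Sex": (0.221, 0, 0.338, 0, "binary", None, None),  # 1 = male
    "Weight": (63.08, 13.44, 65.62, 12.68, "continuous", 33, 105),
    "Height": (1.52, 0.08, 1.61, 0.09, "continuous", 1.32, 1.84),
    "BMI": (26.21, 7.45, 25.02, 4.05, "continuous", 14, 43),
    "GDS": (2.35, 1.7, 1.71, 1.4, "ordinal", 1, 7),
    "FRG_Total": (2.6, 1.2, 1.6, 1.2, "ordinal", 0, 5),
    "FRG_strength": (16.0, 6.0, 20.0, 7.0, "continuous", 0, None),
    "FRG_physical_activity": (0.55, 0, 0.25, 0, "binary", None, None),
    "Time_4m": (6.2, 2.0, 4.4, 1.2, "continuous", 2.0, None),
    "Speed_4m_walk": (0.72, 0.22, 0.98, 0.23, "continuous", 0.1, None),
    "SPPB_equilibrium": (2.9, 1.1, 3.7, 0.6, "ordinal", 0, 4),
    "SPPB_4mSpeed_score": (2.8, 1.1, 3.6, 0.7, "ordinal", 0, 4),
    "SPPB_ChairStand_score": (2.3, 1.4, 3.2, 1.1, "ordinal", 0, 4),
    "SPPB_Total": (8.0, 2.8, 10.2, 2.0, "ordinal", 0, 12),
    "TUG": (15.5, 5.5, 11.0, 3.5, "continuous", 3, None),
    "FES1": (11.5, 4.0, 8.5, 1.8, "ordinal", 7, 28),
    # kinematic summaries (single foot-mounted IMU, free walk)
    "Total_distance": (900.0, 450.0, 1250.0, 500.0, "continuous", 50, None),
    "Total_time": (1150.0, 420.0, 1550.0, 460.0, "continuous", 120, None),
    "Total_steps": (950.0, 420.0, 1350.0, 500.0, "continuous", 50, None),
    "GCT": (1.32, 0.18, 1.10, 0.12, "continuous", 0.6, None),
    "GCT_STD": (0.13, 0.06, 0.07, 0.03, "continuous", 0.005, None),
    "Pushing_pct": (16.5, 4.0, 20.0, 4.0, "continuous", 2, None),
    "Pushing_pct_STD": (1.8, 0.7, 1.5, 0.6, "continuous", 0.05, None),
    "Swing_pct": (26.5, 3.5, 31.5, 3.0, "continuous", 5, None),
    "Swing_pct_STD": (2.9, 1.2, 1.7, 0.8, "continuous", 0.05, None),
    "Loading_pct": (9.9, 2.8, 12.9, 3.1, "continuous", 1, None),
    "Loading_pct_STD": (1.45, 0.55, 1.25, 0.5, "continuous", 0.05, None),
    "FootFlat_pct": (45.5, 6.5, 38.5, 6.0, "continuous", 5, None),
    "FootFlat_pct_STD": (4.6, 1.6, 3.2, 1.2, "continuous", 0.05, None),
    "Toe_off_angle": (-48.0, 9.0, -60.0, 9.0, "continuous", None, 0),
    "Toe_off_angle_STD": (5.3, 1.7, 4.9, 1.5, "continuous", 0.05, None),
    "Heel_strike_angle": (13.2, 3.2, 18.0, 3.4, "continuous", 0, None),
    "Heel_strike_angle_STD": (2.45, 0.8, 3.0, 0.8, "continuous", 0.05, None),
    "Cadence": (45.0, 11.0, 56.0, 11.0, "continuous", 10, None),
    "Cadence_STD": (4.4, 1.5, 3.3, 1.2, "continuous", 0.05, None),
    "StepSpeed": (0.66, 0.18, 1.00, 0.20, "continuous", 0.1, None),
    "StepSpeed_STD": (0.095, 0.035, 0.125, 0.04, "continuous", 0.005, None),
    "StrideLength": (0.80, 0.22, 1.09, 0.23, "continuous", 0.15, None),
    "StrideLength_STD": (0.105, 0.04, 0.135, 0.045, "continuous", 0.005, None),
    "Path2D": (0.82, 0.22, 1.11, 0.23, "continuous", 0.15, None),
    "Path2D_STD": (0.11, 0.04, 0.14, 0.045, "continuous", 0.005, None),
    "Path3D": (0.88, 0.22, 1.17, 0.23, "continuous", 0.15, None),
    "Path3D_STD": (0.040, 0.02, 0.030, 0.015, "continuous", 0.002, None),
    "Clearance": (0.155, 0.045, 0.205, 0.045, "continuous", 0.02, None),
    "Clearance_STD": (0.042, 0.015, 0.058, 0.017, "continuous", 0.002, None),
    "Velocity": (0.65, 0.20, 0.93, 0.21, "continuous", 0.05, None),
}


def default_cohort_spec(
    n_fallers: int = 86,
    n_nonfallers: int = 77,
    effect_scale: float = 1.0,
    seed: int | None = None,
) -> CohortSpec:
    """The default two-group cohort recipe.

    ``effect_scale`` shrinks (0) or stretches (>1) every group-mean
    difference about its midpoint, leaving SDs untouched, so the
    separability of the synthetic cohort is a single dial.
    """
    variables = {}
    for name, (fm, fsd, nm, nsd, kind, lo, hi) in _DEFAULT_VARIABLES.items():
        mid = 0.5 * (fm + nm)
        fm_s = mid + effect_scale * (fm - mid)
        nm_s = mid + effect_scale * (nm - mid)
        if kind == "binary":
            fm_s, nm_s = np.clip([fm_s, nm_s], 0.0, 1.0)
        variables[name] = VariableSpec(fm_s, fsd, nm_s, nsd, kind, lo, hi)
    return CohortSpec(
        n_fallers=n_fallers, n_nonfallers=n_nonfallers, variables=variables, seed=seed
    )


def generate_cohort(
    spec: CohortSpec,
    seed: int | None = None,
    require_variables=None,
) -> pd.DataFrame:
    """Draw a cohort table: one row per participant, binary ``faller`` label.

    Fallers occupy the first ``n_fallers`` rows (shuffled order is
    irrelevant to any downstream fit).  If ``label_model`` is set on the
    spec, the label column is redrawn from a Bernoulli with logistic
    probability on the named columns instead of group membership.
    """
    spec.validate()
    if require_variables is not None:
        spec.ensure_covers(require_variables)
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    n_f, n_nf = spec.n_fallers, spec.n_nonfallers
    group = np.concatenate([np.ones(n_f, dtype=int), np.zeros(n_nf, dtype=int)])

    data = {"faller": group}
    for name, v in spec.variables.items():
        mean = np.where(group == 1, v.faller_mean, v.nonfaller_mean)
        sd = np.where(group == 1, v.faller_sd, v.nonfaller_sd)
        if v.kind == "binary":
            col = (rng.random(group.size) < mean).astype(int)
        else:
            col = rng.normal(mean, sd)
            if v.kind == "ordinal":
                col = np.round(col)
            if v.lo is not None or v.hi is not None:
                col = np.clip(col, v.lo, v.hi)
            if v.kind == "ordinal":
                col = col.astype(int)
        data[name] = col

    df = pd.DataFrame(data)
    if spec.label_model is not None:
        b0 = float(spec.label_model.get("intercept", 0.0))
        coefs = spec.label_model.get("coefficients", {})
        eta = b0 + sum(float(b) * df[k].to_numpy(float) for k, b in coefs.items())
        p = expit(eta)
        df["faller"] = (rng.random(len(df)) < p).astype(int)
    return df
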