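"""Strapdown inertial navigation with zero-velocity updates (INS-ZUPT).

A single IMU strapped to the instep observes specific force and angular
rate in the sensor frame.  During the foot-flat part of stance the foot is
motionless, which gives the navigation filter a zero-velocity
pseudo-measurement once per stride.  This module detects those stance
intervals, integrates orientation / velocity / position, and removes the
integration drift by de-trending the velocity between consecutive stance
anchors (the classic pedestrian dead-reckoning ZUPT correction), plus a
pitch re-anchor from accelerometer levelling at every stance.

Frames and conventions
----------------------
* world frame: X forward, Y left, Z vertical-up; gravity is (0, 0, -g).
* sensor frame: x toward the toes, y left, z up through the instep; at
  zero pitch the sensor frame coincides with the world frame.
* pitch: sagittal foot-ground angle in degrees, positive toes-up
  (heel-strike posture), negative toes-down (toe-off posture).
* the accelerometer reads specific force f = a - g_w, so a motionless,
  level foot reads (0, 0, +g).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

DEFAULT_GRAVITY = 9.81


class NoStanceAnchorError(RuntimeError):
    """No zero-velocity interval found: the ZUPT correction cannot anchor."""


class DivergentIntegrationError(RuntimeError):
    """Strapdown state became non-finite during integration."""


@dataclass
class ImuRecording:
    """Raw timestamped IMU stream.

    Parameters
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    accel : ndarray, shape (n, 3)
        Specific force in the sensor frame, m/s^2.
    gyro : ndarray, shape (n, 3)
        Angular rate in the sensor frame, rad/s.
    sample_rate : float
        Nominal rate in Hz; must agree with the median sample spacing
        within 5%.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.t.shape[0]
        if n < 2:
            raise ValueError("recording needs at least 2 samples")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must have shape (n, 3) matching t")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        med = float(np.median(dt))
        if not 0.95 <= med * self.sample_rate <= 1.05:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz inconsistent with median "
                f"sample spacing {med:.6f} s (>5% off)"
            )

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class StanceMask:
    """Per-sample zero-velocity flags with the run structure pre-computed."""

    flags: np.ndarray
    min_duration: float = 0.0

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    def intervals(self) -> list[tuple[int, int]]:
        """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
        f = np.concatenate(([False], self.flags, [False]))
        edges = np.flatnonzero(np.diff(f.astype(np.int8)))
        return list(zip(edges[::2].tolist(), edges[1::2].tolist()))

    @property
    def n_intervals(self) -> int:
        return len(self.intervals())

    def __len__(self) -> int:
        return self.flags.shape[0]


@dataclass
class FootTrajectory:
    """Reconstructed foot state: position/velocity (m, m/s, world frame,
    Z vertical-up) and sagittal pitch in degrees."""

    t: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    pitch_deg: np.ndarray
    stance_flags: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)


def detect_stance(
    rec: ImuRecording,
    accel_band: float = 0.4,
    gyro_thresh: float = 0.6,
    min_duration: float = 0.1,
    gravity: float = DEFAULT_GRAVITY,
) -> StanceMask:
    """Flag samples where the foot is at zero velocity.

    A sample is a stance candidate when the specific-force magnitude is
    within ``accel_band`` (m/s^2) of gravity AND the angular-rate magnitude
    is below ``gyro_thresh`` (rad/s); candidate runs shorter than
    ``min_duration`` seconds are dropped.  Note that a foot pivoting about
    a planted heel or toe still reads |f| ~ g but has a loud gyro, so the
    detected intervals are the foot-flat dwells - exactly the intervals a
    zero-velocity update may trust.
    """
    rec.validate()
    a_mag = np.linalg.norm(rec.accel, axis=1)
    g_mag = np.linalg.norm(rec.gyro, axis=1)
    raw = (np.abs(a_mag - gravity) < accel_band) & (g_mag < gyro_thresh)

    flags = np.zeros_like(raw)
    f = np.concatenate(([False], raw, [False]))
    edges = np.flatnonzero(np.diff(f.astype(np.int8)))
    for a, b in zip(edges[::2], edges[1::2]):
        if rec.t[b - 1] - rec.t[a] >= min_duration - 1e-12:
            flags[a:b] = True
    return StanceMask(flags=flags, min_duration=min_duration)


# ---------------------------------------------------------------------------
# strapdown integration helpers


def _integrate_orientation(rec: ImuRecording, anchor_idx: int, r0: Rotation) -> np.ndarray:
    """Integrate gyro to per-sample rotation matrices (body -> world).

    Midpoint-rule incremental rotations, composed forward and backward from
    the anchor sample where the absolute attitude ``r0`` is known
    (accelerometer levelling during a stance).
    """
    n = len(rec)
    w_mid = 0.5 * (rec.gyro[1:] + rec.gyro[:-1])
    dt = np.diff(rec.t)[:, None]
    d_mats = Rotation.from_rotvec(w_mid * dt).as_matrix()  # (n-1, 3, 3)

    mats = np.empty((n, 3, 3))
    mats[anchor_idx] = r0.as_matrix()
    for i in range(anchor_idx, n - 1):
        mats[i + 1] = mats[i] @ d_mats[i]
    for i in range(anchor_idx, 0, -1):
        mats[i - 1] = mats[i] @ d_mats[i - 1].T
    return mats


def _pitch_from_matrices(mats: np.ndarray) -> np.ndarray:
    """Sagittal pitch (rad): elevation of the body x-axis above horizontal."""
    bx = mats[:, :, 0]
    return np.arctan2(bx[:, 2], np.hypot(bx[:, 0], bx[:, 1]))


def _levelling_pitch(accel_mean: np.ndarray) -> float:
    """Pitch implied by the gravity direction seen by a motionless sensor."""
    fx, fy, fz = accel_mean
    return float(np.arctan2(fx, np.hypot(fy, fz)))


def _world_y_rotation(angles: np.ndarray) -> np.ndarray:
    """Stack of rotations about the world y-axis (used for pitch trimming)."""
    c, s = np.cos(angles), np.sin(angles)
    out = np.zeros((angles.shape[0], 3, 3))
    out[:, 0, 0] = c
    out[:, 0, 2] = s
    out[:, 1, 1] = 1.0
    out[:, 2, 0] = -s
    out[:, 2, 2] = c
    return out


def reconstruct_trajectory(
    rec: ImuRecording,
    mask: StanceMask,
    gravity: float = DEFAULT_GRAVITY,
    apply_zupt: bool = True,
    anchor_pitch: bool = True,
) -> FootTrajectory:
    """Reconstruct the foot trajectory from a recording and its stance mask.

    Pipeline: accelerometer levelling at the first stance fixes the initial
    attitude (yaw is unobservable and irrelevant to per-stride quantities);
    gyro integration propagates attitude; pitch is re-anchored at every
    stance by levelling; specific force is rotated to the world frame,
    gravity removed and integrated to velocity; the velocity is forced to
    zero during each stance and linearly de-trended across each swing
    (the ZUPT correction); position is the integral of the corrected
    velocity.

    Setting ``apply_zupt=False`` (and ``anchor_pitch=False``) yields the
    free-inertial solution, useful only to demonstrate how fast an
    uncorrected strapdown solution drifts.

    Raises
    ------
    NoStanceAnchorError
        If the mask contains no stance interval.
    DivergentIntegrationError
        If the integrated state becomes non-finite.
    """
    rec.validate()
    runs = mask.intervals()
    if not runs:
        raise NoStanceAnchorError(
            "no zero-velocity interval detected; cannot anchor the ZUPT "
            "correction (running, spinning or noise-only input?)"
        )
    if len(mask) != len(rec):
        raise ValueError("mask length does not match recording length")

    # --- initial attitude from accelerometer levelling at the first stance
    a0, b0 = runs[0]
    f_mean = rec.accel[a0:b0].mean(axis=0)
    norm = np.linalg.norm(f_mean)
    if norm == 0:
        raise NoStanceAnchorError("zero specific force during stance; cannot level")
    r0, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [f_mean / norm])
    anchor_idx = (a0 + b0) // 2

    mats = _integrate_orientation(rec, anchor_idx, r0)

    # --- pitch re-anchoring at every stance (gyro drift containment)
    if anchor_pitch:
        pitch = _pitch_from_matrices(mats)
        mids, deltas = [], []
        for a, b in runs:
            meas = _levelling_pitch(rec.accel[a:b].mean(axis=0))
            mids.append(0.5 * (rec.t[a] + rec.t[b - 1]))
            deltas.append(float(np.mean(pitch[a:b])) - meas)
        trim = np.interp(rec.t, mids, deltas)
        mats = _world_y_rotation(trim) @ mats

    pitch = _pitch_from_matrices(mats)

    # --- specific force to world frame, gravity removal, velocity
    a_w = np.einsum("nij,nj->ni", mats, rec.accel)
    a_w[:, 2] -= gravity
    v = cumulative_simpson(a_w, x=rec.t, axis=0, initial=0.0)

    if apply_zupt:
        v = _zupt_detrend(v, rec.t, runs)

    p = cumulative_simpson(v, x=rec.t, axis=0, initial=0.0)

    for name, arr in (("velocity", v), ("position", p)):
        bad = ~np.isfinite(arr)
        if bad.any():
            idx = int(np.flatnonzero(bad.any(axis=1))[0])
            raise DivergentIntegrationError(
                f"non-finite {name} at sample {idx} (t={rec.t[idx]:.3f} s)"
            )

    return FootTrajectory(
        t=rec.t.copy(),
        position=p,
        velocity=v,
        pitch_deg=np.degrees(pitch),
        stance_flags=mask.flags.copy(),
    )


def _zupt_detrend(v: np.ndarray, t: np.ndarray, runs: list[tuple[int, int]]) -> np.ndarray:
    """Zero the velocity during stance and de-trend it across each swing.

    The mean integrated velocity over a stance run estimates the drift at
    that anchor; between consecutive anchors the drift is assumed to grow
    linearly in time (white accelerometer noise plus small attitude error),
    which is the standard per-stride ZUPT correction.
    """
    v = v.copy()
    drift = [v[a:b].mean(axis=0) for a, b in runs]

    # before the first and after the last stance: constant correction
    first_a, _ = runs[0]
    _, last_b = runs[-1]
    v[:first_a] -= drift[0]
    v[last_b:] -= drift[-1]

    for k in range(len(runs) - 1):
        _, b1 = runs[k]
        a2, _ = runs[k + 1]
        if a2 > b1:
            seg = slice(b1, a2)
            w = (t[seg] - t[b1 - 1]) / (t[a2] - t[b1 - 1])
            v[seg] -= drift[k] + (drift[k + 1] - drift[k]) * w[:, None]

    for a, b in runs:
        v[a:b] = 0.0
    return v
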