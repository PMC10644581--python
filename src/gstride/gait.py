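"""Stride segmentation, gait-event detection and the gait-parameter set.

Works on a reconstructed :class:`~gstride.reconstruct.FootTrajectory` plus
its stance mask.  Strides are heel-strike-to-heel-strike cycles of the one
instrumented foot; the four events per cycle are

* heel-strike  - stance onset (pitch maximum at landing),
* toe-strike   - foot-flat onset,
* heel-off     - foot-flat end,
* toe-off      - stance end (pitch minimum at push-off),

splitting the cycle into loading, foot-flat, pushing and swing phases
whose durations are reported as % of the gait cycle time (GCT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .reconstruct import FootTrajectory, StanceMask

logger = logging.getLogger(__name__)


class InsufficientStridesError(ValueError):
    """Fewer than two stance intervals: no stride can be delimited."""


@dataclass
class StrideWindow:
    """One complete heel-strike-to-heel-strike cycle (sample indices)."""

    heel_strike: int
    toe_strike: int
    heel_off: int
    toe_off: int
    end: int  # next heel-strike
    stance_in: tuple[int, int]  # foot-flat run entered at this heel-strike
    stance_out: tuple[int, int]  # foot-flat run entered at the next heel-strike
    degenerate_footflat: bool = False

    def events(self, t: np.ndarray) -> dict:
        """Event times in seconds; validates the within-cycle ordering."""
        ev = {
            "heel_strike": float(t[self.heel_strike]),
            "toe_strike": float(t[self.toe_strike]),
            "heel_off": float(t[self.heel_off]),
            "toe_off": float(t[self.toe_off]),
            "end": float(t[self.end]),
        }
        order = [ev["heel_strike"], ev["toe_strike"], ev["heel_off"], ev["toe_off"], ev["end"]]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError(f"gait events out of order: {ev}")
        return ev


@dataclass
class StrideMetrics:
    """The per-stride kinematic record."""

    heel_strike: float
    toe_strike: float
    heel_off: float
    toe_off: float
    gct: float
    stride_length: float
    clearance: float
    path2d: float
    path3d: float
    loading_pct: float
    footflat_pct: float
    pushing_pct: float
    swing_pct: float
    heel_strike_angle: float
    toe_off_angle: float
    step_speed: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class WalkSummary:
    """Per-walk totals plus mean/STD of every stride parameter."""

    total_distance: float
    total_time: float
    total_steps: int
    cadence: float
    velocity: float
    n_strides: int
    steps_per_stride: int
    stride_means: dict = field(default_factory=dict)
    stride_stds: dict = field(default_factory=dict)

    _FEATURES = {
        "gct": "GCT",
        "stride_length": "StrideLength",
        "step_speed": "StepSpeed",
        "clearance": "Clearance",
        "path2d": "Path2D",
        "path3d": "Path3D",
        "loading_pct": "Loading_pct",
        "footflat_pct": "FootFlat_pct",
        "pushing_pct": "Pushing_pct",
        "swing_pct": "Swing_pct",
        "heel_strike_angle": "Heel_strike_angle",
        "toe_off_angle": "Toe_off_angle",
        "cadence": "Cadence",
    }

    def to_feature_row(self) -> dict:
        """Flatten to the canonical cohort-table column names."""
        row = {
            "Total_distance": self.total_distance,
            "Total_time": self.total_time,
            "Total_steps": self.total_steps,
            "Cadence": self.cadence,
            "Velocity": self.velocity,
        }
        for key, col in self._FEATURES.items():
            if key == "cadence":
                row["Cadence_STD"] = self.stride_stds.get(key, np.nan)
                continue
            row[col] = self.stride_means.get(key, np.nan)
            row[f"{col}_STD"] = self.stride_stds.get(key, np.nan)
        return row


# ---------------------------------------------------------------------------


def _footflat_runs(
    traj: FootTrajectory,
    intervals: list[tuple[int, int]],
    pitch_rate_thresh: float,
    min_samples: int,
) -> list[tuple[int, int, bool]]:
    """Refine each stance interval to its foot-flat (pitch-quiet) run.

    Returns (toe_strike_idx, heel_off_idx, degenerate) per interval; when
    no quiet run of ``min_samples`` exists the foot-flat collapses to the
    single quietest sample (degenerate=True).
    """
    rate = np.gradient(traj.pitch_deg, traj.t)
    out = []
    for a, b in intervals:
        quiet = np.abs(rate[a:b]) < pitch_rate_thresh
        best = None
        start = None
        for i, q in enumerate(np.concatenate([quiet, [False]])):
            if q and start is None:
                start = i
            elif not q and start is not None:
                if best is None or i - start > best[1] - best[0]:
                    best = (start, i)
                start = None
        if best is not None and best[1] - best[0] >= min_samples:
            out.append((a + best[0], a + best[1] - 1, False))
        else:
            j = a + int(np.argmin(np.abs(rate[a:b])))
            out.append((j, j, True))
    return out


def segment_strides(
    traj: FootTrajectory,
    mask: StanceMask,
    pitch_rate_thresh: float = 30.0,
    min_footflat_duration: float = 0.05,
    min_pitch_range: float = 2.0,
    trim_first_last: bool = False,
) -> list[StrideWindow]:
    """Delimit complete heel-strike-to-heel-strike cycles.

    With m detected stance intervals there are m-1 swings and m-2 complete
    cycles (the swings into the first stance and out of the last one lack a
    matching end event); partial boundary cycles are therefore never
    emitted.  ``trim_first_last`` additionally drops the first and last
    complete cycle (start/stop transients in field recordings).

    Event placement: toe-strike / heel-off bound the pitch-quiet run inside
    each stance (rate below ``pitch_rate_thresh`` deg/s); toe-off is the
    pitch minimum between a heel-off and the next toe-strike; heel-strike
    is the pitch maximum between that toe-off and the next toe-strike.
    When the pitch swing in that search window is below ``min_pitch_range``
    degrees (flat-pitch gait) the events fall back to the stance-interval
    edges.
    """
    intervals = mask.intervals()
    if len(intervals) < 2:
        raise InsufficientStridesError(
            f"need >= 2 stance intervals to delimit a stride, found {len(intervals)}"
        )
    dt = float(np.median(np.diff(traj.t)))
    min_samples = max(1, int(round(min_footflat_duration / dt)))
    ff = _footflat_runs(traj, intervals, pitch_rate_thresh, min_samples)

    pitch = traj.pitch_deg
    # per gap k (between stance k and k+1): toe-off and heel-strike indices
    toe_offs, heel_strikes = [], []
    for k in range(len(intervals) - 1):
        ho_k = ff[k][1]
        ts_next = ff[k + 1][0]
        lo, hi = ho_k, ts_next + 1
        if hi - lo < 3 or np.ptp(pitch[lo:hi]) < min_pitch_range:
            toe_offs.append(intervals[k][1] - 1)
            heel_strikes.append(intervals[k + 1][0])
            continue
        to = lo + int(np.argmin(pitch[lo:hi]))
        hs_lo = to
        hs = hs_lo + int(np.argmax(pitch[hs_lo:hi]))
        toe_offs.append(to)
        heel_strikes.append(hs)

    windows = []
    for j in range(len(intervals) - 2):
        ts_j, ho_j, degen = ff[j + 1]
        win = StrideWindow(
            heel_strike=heel_strikes[j],
            toe_strike=ts_j,
            heel_off=ho_j,
            toe_off=toe_offs[j + 1],
            end=heel_strikes[j + 1],
            stance_in=intervals[j + 1],
            stance_out=intervals[j + 2],
            degenerate_footflat=degen,
        )
        if degen:
            logger.warning(
                "foot-flat undetectable in stance %d; collapsed to quietest sample", j + 1
            )
        windows.append(win)

    if trim_first_last and len(windows) > 2:
        windows = windows[1:-1]
    return windows


def detect_events(window: StrideWindow, traj: FootTrajectory) -> dict:
    """Event times (s) of one stride window, ordering-validated."""
    return window.events(traj.t)


def compute_stride_metrics(window: StrideWindow, traj: FootTrajectory) -> StrideMetrics:
    """All per-stride parameters from one segmented window.

    Stride length is the straight-line horizontal distance between the
    stance anchor entered at this heel-strike and the next one; the 2D/3D
    paths sum the horizontal / full position increments across the cycle;
    clearance is the peak height during swing above the ground level of the
    stance preceding that swing.
    """
    ev = window.events(traj.t)
    gct = ev["end"] - ev["heel_strike"]
    if gct <= 0:
        raise ValueError("non-positive gait cycle time")

    p = traj.position
    a_in = slice(*window.stance_in)
    a_out = slice(*window.stance_out)
    anchor_in = p[a_in].mean(axis=0)
    anchor_out = p[a_out].mean(axis=0)
    sl = float(np.hypot(*(anchor_out[:2] - anchor_in[:2])))

    seg = slice(window.heel_strike, window.end + 1)
    d = np.diff(p[seg], axis=0)
    path2d = float(np.sum(np.hypot(d[:, 0], d[:, 1])))
    path3d = float(np.sum(np.linalg.norm(d, axis=1)))

    ground_z = float(p[a_in][:, 2].mean())
    swing = slice(window.toe_off, window.end + 1)
    clearance = float(np.max(p[swing][:, 2]) - ground_z)

    loading = (ev["toe_strike"] - ev["heel_strike"]) / gct * 100.0
    footflat = (ev["heel_off"] - ev["toe_strike"]) / gct * 100.0
    pushing = (ev["toe_off"] - ev["heel_off"]) / gct * 100.0
    swing_pct = (ev["end"] - ev["toe_off"]) / gct * 100.0

    return StrideMetrics(
        heel_strike=ev["heel_strike"],
        toe_strike=ev["toe_strike"],
        heel_off=ev["heel_off"],
        toe_off=ev["toe_off"],
        gct=float(gct),
        stride_length=sl,
        clearance=clearance,
        path2d=path2d,
        path3d=path3d,
        loading_pct=float(loading),
        footflat_pct=float(footflat),
        pushing_pct=float(pushing),
        swing_pct=float(swing_pct),
        heel_strike_angle=float(traj.pitch_deg[window.heel_strike]),
        toe_off_angle=float(traj.pitch_deg[window.toe_off]),
        step_speed=sl / float(gct),
    )


def summarize_walk(
    strides: list[StrideMetrics],
    traj: FootTrajectory,
    steps_per_stride: int = 2,
    std: str = "population",
) -> WalkSummary:
    """Aggregate per-stride records into the per-walk feature vector.

    A single foot-mounted IMU observes strides; total steps and cadence are
    reported under a configurable convention (default: both feet inferred
    by symmetry, steps = 2 x strides).  Cadence is per-stride
    ``steps_per_stride * 60 / GCT`` averaged across strides.  ``std`` picks
    the population (divide by n, default) or sample estimator.
    """
    if not strides:
        raise ValueError("empty stride list")
    if std not in ("population", "sample"):
        raise ValueError("std must be 'population' or 'sample'")
    ddof = 0 if std == "population" else 1

    total_time = float(traj.t[-1] - traj.t[0])
    total_distance = float(sum(s.stride_length for s in strides))
    n = len(strides)
    total_steps = steps_per_stride * n

    series = {
        key: np.array([getattr(s, key) for s in strides])
        for key in WalkSummary._FEATURES
        if key != "cadence"
    }
    series["cadence"] = steps_per_stride * 60.0 / series["gct"]

    means = {k: float(v.mean()) for k, v in series.items()}
    stds = {
        # exactly 0 for identical strides (no floating residue from the mean)
        k: (float(v.std(ddof=ddof)) if v.size > ddof and np.ptp(v) > 0 else 0.0)
        for k, v in series.items()
    }

    return WalkSummary(
        total_distance=total_distance,
        total_time=total_time,
        total_steps=total_steps,
        cadence=means["cadence"],
        velocity=total_distance / total_time if total_time > 0 else np.nan,
        n_strides=n,
        steps_per_stride=steps_per_stride,
        stride_means=means,
        stride_stds=stds,
    )


def extract_gait(
    traj: FootTrajectory,
    mask: StanceMask,
    steps_per_stride: int = 2,
    std: str = "population",
    trim_first_last: bool = False,
    **segment_kwargs,
) -> tuple[list[StrideMetrics], WalkSummary]:
    """Convenience chain: segment -> metrics -> summary."""
    windows = segment_strides(traj, mask, trim_first_last=trim_first_last, **segment_kwargs)
    if not windows:
        raise InsufficientStridesError("no complete stride between detected stances")
    metrics = [compute_stride_metrics(w, traj) for w in windows]
    summary = summarize_walk(metrics, traj, steps_per_stride=steps_per_stride, std=std)
    return metrics, summary


def strides_to_frame(strides: list[StrideMetrics]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in strides])
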