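"""Per-cycle kinematic variables from 3D landmark trajectories.

A trial supplies 3D trajectories (in body lengths, BL) of four landmarks
sampled at 500 frames/s — nose tip, caudal fin tip, pectoral fin tip and
pectoral fin base — plus stroke-cycle annotations splitting each fin beat
into a propulsive phase (adduction while swimming; stance while walking)
and a recovery phase (abduction; swing).  From these the module derives
the per-cycle variables: speed over ground, swing distances, fin elevation
extrema, fin adduction angle extrema, signed angular-velocity summaries,
and the stroke-phase polar timing of each extreme.

Polar timing convention: the propulsive phase maps linearly onto
[0, 180) deg and the recovery phase onto [180, 360) deg, so the phase
boundary is pinned at 180 deg regardless of the propulsion fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkTrajectory",
    "StrokeCycle",
    "CycleKinematics",
    "to_polar_timing",
    "speed_over_ground",
    "swing_distance",
    "elevation_stats",
    "adduction_angle",
    "angular_velocity_summary",
    "cycle_kinematics",
]

LANDMARKS = ("nose_tip", "caudal_tip", "pect_tip", "pect_base")


@dataclass(frozen=True)
class LandmarkTrajectory:
    """One landmark's 3D path, uniformly sampled, coordinates in BL."""

    landmark: str
    t: np.ndarray
    xyz: np.ndarray  # (n, 3)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (t.size, 3):
            raise ValueError("xyz must be (n, 3) matching t")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ValueError("time must be uniformly spaced")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xyz", xyz)

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def window(self, t0: float, t1: float) -> "LandmarkTrajectory":
        """Samples with t0 <= t <= t1 (inclusive ends)."""
        eps = 0.5 / self.fs * 1e-6
        m = (self.t >= t0 - eps) & (self.t <= t1 + eps)
        if not m.any():
            raise ValueError(
                f"window [{t0}, {t1}] outside trajectory "
                f"[{self.t[0]}, {self.t[-1]}]: misaligned annotation?"
            )
        return LandmarkTrajectory(self.landmark, self.t[m], self.xyz[m])


@dataclass(frozen=True)
class StrokeCycle:
    """One fin-beat: propulsion [t_start, t_mid), recovery [t_mid, t_end)."""

    t_start: float
    t_mid: float
    t_end: float
    behaviour: str = ""

    def __post_init__(self):
        if not (self.t_start < self.t_mid < self.t_end):
            raise ValueError("require t_start < t_mid < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class CycleKinematics:
    behaviour: str
    speed_over_ground: float
    caudal_swing: float
    pect_swing: float
    nose_swing: float  # walking only; nan otherwise
    elev_max: float
    elev_min: float
    elev_range: float
    add_max: float
    add_min: float
    add_range: float
    abd_vel_max: float
    abd_vel_routine: float
    add_vel_max: float
    add_vel_routine: float
    t_elev_max_deg: float
    t_elev_min_deg: float
    t_add_max_deg: float
    t_add_min_deg: float
    t_nose_max_deg: float = float("nan")
    t_nose_min_deg: float = float("nan")


def to_polar_timing(t: float, cycle: StrokeCycle, mode: str = "phase") -> float:
    """Map an event time to the 0-360 deg stroke circle.

    ``mode="phase"`` (default) maps propulsion linearly onto [0, 180) and
    recovery onto [180, 360), pinning t_mid at 180 deg.  ``mode="time"``
    maps raw elapsed cycle fraction onto [0, 360).
    """
    if not (cycle.t_start <= t < cycle.t_end):
        raise ValueError(f"t={t} outside cycle [{cycle.t_start}, {cycle.t_end})")
    if mode == "time":
        return 360.0 * (t - cycle.t_start) / cycle.duration
    if mode != "phase":
        raise ValueError(f"unknown polar mapping {mode!r}")
    if t < cycle.t_mid:
        return 180.0 * (t - cycle.t_start) / (cycle.t_mid - cycle.t_start)
    return 180.0 + 180.0 * (t - cycle.t_mid) / (cycle.t_end - cycle.t_mid)


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sqrt((np.diff(points, axis=0) ** 2).sum(axis=1)).sum())


def speed_over_ground(nose: LandmarkTrajectory, t0: float, t1: float,
                      use_3d: bool = True) -> float:
    """Distance travelled along the nose path over elapsed time (BL/s).

    The 3D path length is used by default; ``use_3d=False`` projects onto
    the horizontal x-y plane first.
    """
    w = nose.window(t0, t1)
    if w.t.size < 2:
        raise ValueError("need at least 2 samples in window")
    pts = w.xyz if use_3d else w.xyz[:, :2]
    return _polyline_length(pts) / (w.t[-1] - w.t[0])


def swing_distance(tip: LandmarkTrajectory, cycle: StrokeCycle) -> float:
    """Total x-y plane path length of a landmark over one full cycle (BL)."""
    w = tip.window(cycle.t_start, cycle.t_end)
    return _polyline_length(w.xyz[:, :2])


def _extreme_with_timing(t: np.ndarray, z: np.ndarray, cycle: StrokeCycle,
                         mode: str, which: str) -> tuple[float, float]:
    idx = int(np.argmax(z) if which == "max" else np.argmin(z))
    val = float(z[idx])
    ties = np.flatnonzero(np.isclose(z, val, rtol=0, atol=0))
    if ties.size > 1:
        warnings.warn(f"tied {which} at {ties.size} frames; first occurrence used")
    t_ev = min(float(t[idx]), np.nextafter(cycle.t_end, cycle.t_start))
    return val, to_polar_timing(t_ev, cycle, mode=mode)


def elevation_stats(tip: LandmarkTrajectory, cycle: StrokeCycle,
                    mode: str = "phase") -> dict:
    """Max/min/range of the vertical (z) coordinate over one cycle.

    Larger values mean the fin sits more dorsally.  Timings of the extrema
    are returned on the polar stroke circle.
    """
    w = tip.window(cycle.t_start, cycle.t_end)
    z = w.xyz[:, 2]
    emax, t_max = _extreme_with_timing(w.t, z, cycle, mode, "max")
    emin, t_min = _extreme_with_timing(w.t, z, cycle, mode, "min")
    return {
        "elev_max": emax,
        "elev_min": emin,
        "elev_range": emax - emin,
        "t_max_deg": t_max,
        "t_min_deg": t_min,
    }


def adduction_angle(nose_xy: np.ndarray, base_xy: np.ndarray,
                    tip_xy: np.ndarray) -> np.ndarray:
    """Continuous fin adduction angle (deg) at the fin-base vertex.

    The oriented x-y plane angle from the base->nose ray to the base->tip
    ray, unwrapped over frames so that a fin sweeping past the body axis
    continues beyond 180 deg (more adducted = larger angle) instead of
    reflecting back.
    """
    v1 = np.asarray(nose_xy, dtype=float) - np.asarray(base_xy, dtype=float)
    v2 = np.asarray(tip_xy, dtype=float) - np.asarray(base_xy, dtype=float)
    n1 = np.hypot(v1[:, 0], v1[:, 1])
    n2 = np.hypot(v2[:, 0], v2[:, 1])
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        bad = int(np.argmax((n1 < 1e-12) | (n2 < 1e-12)))
        raise ValueError(f"undefined angle: coincident landmarks at frame {bad}")
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = v1[:, 0] * v2[:, 0] + v1[:, 1] * v2[:, 1]
    ang = np.unwrap(np.arctan2(cross, dot))
    ang = np.rad2deg(ang)
    # Orient so adduction (fin swept toward/past the body axis) increases
    # the angle: flip the sign if the series sits in the negative half.
    if np.median(ang) < 0:
        ang = -ang
    return ang


def angular_velocity_summary(angle_deg: np.ndarray, fs: float,
                             top_max: float = 0.05,
                             top_routine: float = 0.20) -> dict:
    """Signed angular-velocity summaries for one cycle.

    Central-difference velocity (deg/s); negative samples are abduction,
    positive adduction.  Within each sign class, the mean of the top 5% of
    magnitudes is the maximum and the mean of the top 20% the routine
    value, reported with the class's sign.  An empty class gives nan.
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    if angle_deg.size < 21:
        raise ValueError("need >= 21 angle samples for velocity summaries")
    vel = np.gradient(angle_deg) * fs
    out = {}
    for name, sel in (("abd", vel[vel < 0]), ("add", vel[vel > 0])):
        if sel.size == 0:
            out[f"{name}_vel_max"] = float("nan")
            out[f"{name}_vel_routine"] = float("nan")
            continue
        mag = np.sort(np.abs(sel))[::-1]
        for key, frac in ((f"{name}_vel_max", top_max),
                          (f"{name}_vel_routine", top_routine)):
            k = max(1, int(np.ceil(frac * mag.size)))
            m = float(mag[:k].mean())
            out[key] = -m if name == "abd" else m
    return out


def cycle_kinematics(
    trajectories: dict[str, LandmarkTrajectory],
    cycle: StrokeCycle,
    polar_mode: str = "phase",
    speed_3d: bool = True,
) -> CycleKinematics:
    """All per-cycle kinematic variables for one annotated stroke cycle."""
    nose = trajectories["nose_tip"]
    caudal = trajectories["caudal_tip"]
    tip = trajectories["pect_tip"]
    base = trajectories["pect_base"]

    elev = elevation_stats(tip, cycle, mode=polar_mode)

    wn = nose.window(cycle.t_start, cycle.t_end)
    wb = base.window(cycle.t_start, cycle.t_end)
    wt = tip.window(cycle.t_start, cycle.t_end)
    ang = adduction_angle(wn.xyz[:, :2], wb.xyz[:, :2], wt.xyz[:, :2])
    amax, t_amax = _extreme_with_timing(wt.t, ang, cycle, polar_mode, "max")
    amin, t_amin = _extreme_with_timing(wt.t, ang, cycle, polar_mode, "min")
    vel = angular_velocity_summary(ang, fs=tip.fs)

    walking = cycle.behaviour == "walking"
    ck = CycleKinematics(
        behaviour=cycle.behaviour,
        speed_over_ground=speed_over_ground(nose, cycle.t_start, cycle.t_end,
                                            use_3d=speed_3d),
        caudal_swing=swing_distance(caudal, cycle),
        pect_swing=swing_distance(tip, cycle),
        nose_swing=swing_distance(nose, cycle) if walking else float("nan"),
        elev_max=elev["elev_max"],
        elev_min=elev["elev_min"],
        elev_range=elev["elev_range"],
        add_max=amax,
        add_min=amin,
        add_range=amax - amin,
        abd_vel_max=vel["abd_vel_max"],
        abd_vel_routine=vel["abd_vel_routine"],
        add_vel_max=vel["add_vel_max"],
        add_vel_routine=vel["add_vel_routine"],
        t_elev_max_deg=elev["t_max_deg"],
        t_elev_min_deg=elev["t_min_deg"],
        t_add_max_deg=t_amax,
        t_add_min_deg=t_amin,
    )
    if walking:
        ne = elevation_stats(nose, cycle, mode=polar_mode)
        ck.t_nose_max_deg = ne["t_max_deg"]
        ck.t_nose_min_deg = ne["t_min_deg"]
    return ck
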