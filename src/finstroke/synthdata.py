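"""Synthetic gait, EMG, timing and fluorescence data with known ground truth.

The generator emulates the structure of a two-behaviour (swimming vs
walking) fin-locomotion study: a handful of fish each contribute a series
of stroke cycles; each cycle has a propulsive and a recovery phase; four
pectoral fin muscles (Abd, Add, Cmt, Zpt) fire scheduled bursts whose
timing jitters on the cycle circle by a von Mises draw; 3D landmark
trajectories follow analytic sinusoids in stroke phase so every kinematic
extreme has a closed form; and a nested study design adds fixed
behaviour/muscle effects, a Normal random fish intercept and residual
noise.  Everything returned is accompanied by its ground truth, so every
downstream stage can be tested without external data.

EMG bursts are carried by Gaussian noise band-passed to 40-4000 Hz with a
trapezoidal amplitude envelope (5 ms rise/fall), matching the
interference-pattern character of real recordings and the analysis band.
Carriers are synthesized inside the burst support only, so a noiseless
configuration is exactly zero outside scheduled bursts.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import signal as sig
from scipy import stats as sps

from .emg import EMGChannel, MUSCLES
from .kinematics import LandmarkTrajectory, StrokeCycle

__all__ = [
    "GaitSimConfig",
    "GroundTruth",
    "generate_emg",
    "generate_kinematics",
    "generate_study",
    "generate_fluorescence",
    "default_burst_schedule",
]

BEHAVIOURS = ("swimming", "walking")


def default_burst_schedule() -> dict:
    """Scheduled bursts per muscle x behaviour: (onset, offset, amplitude).

    Onset/offset are cycle-time fractions in [0, 1); amplitude scales the
    burst carrier RMS.  The layout follows the qualitative activation
    pattern of the four fin muscle groups: the adductor powers propulsion
    and the abductor recovery during swimming, with the two fin-shaping
    muscles (Cmt, Zpt) bridging the phase transitions; walking adds the
    characteristic extra adductor activity through recovery.
    """
    return {
        ("Abd", "swimming"): [(0.50, 0.85, 0.6)],
        ("Add", "swimming"): [(0.02, 0.45, 1.0)],
        ("Cmt", "swimming"): [(0.05, 0.30, 0.5)],
        ("Zpt", "swimming"): [(0.30, 0.60, 0.5)],
        ("Abd", "walking"): [(0.05, 0.35, 1.0), (0.55, 0.75, 0.5)],
        ("Add", "walking"): [(0.02, 0.40, 1.0), (0.55, 0.95, 0.9)],
        ("Cmt", "walking"): [(0.05, 0.40, 0.8)],
        ("Zpt", "walking"): [(0.45, 0.90, 0.9)],
    }


@dataclass
class GaitSimConfig:
    """Study-level simulation parameters.

    Defaults follow the target study design: 4 fish, at least 10 strokes
    per fish and behaviour, EMG at 10 kHz, video at 500 frames/s, swimming
    fin-beat cycles of ~0.2 s and walking steps of ~0.6 s.
    """

    n_fish: int = 4
    cycles_per_fish: int = 10
    behaviours: tuple = BEHAVIOURS
    # per-behaviour (mean, sd) cycle duration in seconds
    cycle_duration_s: dict = field(default_factory=lambda: {
        "swimming": (0.20, 0.02), "walking": (0.60, 0.06)})
    propulsion_fraction: dict = field(default_factory=lambda: {
        "swimming": 0.50, "walking": 0.55})
    # per-behaviour kinematic parameters (amplitudes about a shared centre)
    kinematic_params: dict = field(default_factory=lambda: {
        "swimming": {"add_center": 187.0, "add_amp": 11.0,
                     "elev_center": -0.0485, "elev_amp": 0.0065,
                     "speed": 0.53, "caudal_amp": 0.05, "nose_elev_amp": 0.0},
        "walking": {"add_center": 178.0, "add_amp": 32.0,
                    "elev_center": -0.0485, "elev_amp": 0.0125,
                    "speed": 0.56, "caudal_amp": 0.12,
                    "nose_elev_amp": 0.01},
    })
    burst_schedule: dict = field(default_factory=default_burst_schedule)
    timing_kappa: float = 50.0
    noise_sd: float = 0.1
    burst_amplitude: float = 1.0
    artifact_rate: float = 0.2
    fs_emg: float = 10_000.0
    fs_video: float = 500.0
    random_fish_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        for b, f in self.propulsion_fraction.items():
            if not 0 < f < 1:
                raise ValueError(f"propulsion_fraction[{b}] must be in (0, 1)")
        if self.fs_emg <= 0 or self.fs_video <= 0:
            raise ValueError("sampling rates must be positive")
        for key, sched in self.burst_schedule.items():
            for on, off, _amp in sched:
                if not (0 <= on < 1 and 0 < off <= 1.2 and on < off):
                    raise ValueError(f"bad burst phases {on}, {off} for {key}")


@dataclass
class GroundTruth:
    true_bursts: dict = field(default_factory=dict)      # muscle -> [(on, off)]
    true_cycles: list = field(default_factory=list)      # [(t0, tmid, t1)]
    true_fixed_effects: dict = field(default_factory=dict)
    true_angular_means: dict = field(default_factory=dict)  # (muscle) -> deg
    true_treatment_d: float = float("nan")
    true_kinematics: dict = field(default_factory=dict)
    merged_bursts: list = field(default_factory=list)


def _trial_rng(config: GaitSimConfig, trial: str, stream: str) -> np.random.Generator:
    digest = hashlib.blake2s(f"{trial}|{stream}".encode(), digest_size=4).digest()
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, int.from_bytes(digest, "big")]))


def _make_cycles(config: GaitSimConfig, behaviour: str, rng: np.random.Generator,
                 n_cycles: int, lead_in: float) -> list[StrokeCycle]:
    mean, sd = config.cycle_duration_s[behaviour]
    frac = config.propulsion_fraction[behaviour]
    t = lead_in
    cycles = []
    for _ in range(n_cycles):
        dur = max(float(rng.normal(mean, sd)), 0.25 * mean)
        cycles.append(StrokeCycle(t, t + frac * dur, t + dur, behaviour))
        t += dur
    return cycles


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float = 40.0, high: float = 4000.0) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise of length n."""
    x = rng.standard_normal(n)
    if n >= 32:
        sos = sig.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        x = sig.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _trapezoid_env(n: int, fs: float, ramp_s: float = 0.005) -> np.ndarray:
    r = min(int(round(ramp_s * fs)), n // 2)
    env = np.ones(n)
    if r > 0:
        env[:r] = np.linspace(0, 1, r, endpoint=False)
        env[-r:] = np.linspace(1, 0, r, endpoint=False)
    return env


def generate_emg(config: GaitSimConfig, trial: str,
                 behaviour: str = "swimming",
                 n_cycles: int | None = None) -> tuple[dict, GroundTruth]:
    """Simulate one trial's four-channel EMG record with known bursts.

    Returns ``{muscle: EMGChannel}`` and the ground truth holding the cycle
    annotations and the scheduled (jittered, possibly merged) burst
    intervals per muscle.  A 0.5 s quiet lead-in provides the inactive
    window used for centring.
    """
    if n_cycles is None:
        n_cycles = config.cycles_per_fish
    lead_in = 0.5
    rng_cyc = _trial_rng(config, trial, f"cycles-{behaviour}")
    cycles = _make_cycles(config, behaviour, rng_cyc, n_cycles, lead_in)
    total = cycles[-1].t_end + 0.1
    n = int(round(total * config.fs_emg))
    fs = config.fs_emg

    gt = GroundTruth(true_cycles=[(c.t_start, c.t_mid, c.t_end) for c in cycles])
    channels: dict[str, EMGChannel] = {}
    for muscle in MUSCLES:
        rng = _trial_rng(config, trial, f"emg-{behaviour}-{muscle}")
        x = rng.standard_normal(n) * config.noise_sd if config.noise_sd > 0 \
            else np.zeros(n)
        sched = config.burst_schedule.get((muscle, behaviour), [])
        intervals: list[tuple[float, float, float]] = []
        for c in cycles:
            for on, off, amp in sched:
                jit = float(sps.vonmises.rvs(config.timing_kappa,
                                             random_state=rng)) / (2 * np.pi)
                t_on = c.t_start + (on + jit) * c.duration
                t_off = c.t_start + (off + jit) * c.duration
                intervals.append((t_on, t_off, amp))
        intervals.sort()
        merged: list[list[float]] = []
        for t_on, t_off, amp in intervals:
            if merged and t_on < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], t_off)
                merged[-1][2] = max(merged[-1][2], amp)
                gt.merged_bursts.append((muscle, t_on))
                warnings.warn(f"overlapping scheduled bursts merged ({muscle})")
            else:
                merged.append([t_on, t_off, amp])
        truth = []
        for t_on, t_off, amp in merged:
            i0, i1 = int(round(t_on * fs)), int(round(t_off * fs))
            i0, i1 = max(i0, 0), min(i1, n)
            if i1 - i0 < 4:
                continue
            carrier = _band_noise(rng, i1 - i0, fs)
            x[i0:i1] += (config.burst_amplitude * amp
                         * _trapezoid_env(i1 - i0, fs) * carrier)
            truth.append((i0 / fs, i1 / fs))
        if config.artifact_rate > 0:
            n_art = rng.poisson(config.artifact_rate * total)
            for _ in range(n_art):
                t_c = rng.uniform(0.0, total)
                f_a = rng.uniform(2.0, 15.0)
                dur = rng.uniform(0.05, 0.2)
                i0 = max(int((t_c - dur / 2) * fs), 0)
                i1 = min(int((t_c + dur / 2) * fs), n)
                tt = np.arange(i1 - i0) / fs
                x[i0:i1] += (3 * config.noise_sd * np.sin(2 * np.pi * f_a * tt)
                             * np.hanning(i1 - i0))
        gt.true_bursts[muscle] = truth
        channels[muscle] = EMGChannel(
            fish=trial, muscle=muscle, fs=fs, samples=x,
            quiet_window=(0.05, lead_in - 0.05))
    return channels, gt


# --- kinematics --------------------------------------------------------------


def _phase_angle(t: np.ndarray, cycles: list[StrokeCycle]) -> np.ndarray:
    """Stroke-phase polar angle (rad) of each time over its containing cycle."""
    out = np.zeros_like(t)
    for c in cycles:
        m = (t >= c.t_start) & (t < c.t_end)
        tm = t[m]
        prop = tm < c.t_mid
        th = np.where(
            prop,
            np.pi * (tm - c.t_start) / (c.t_mid - c.t_start),
            np.pi + np.pi * (tm - c.t_mid) / (c.t_end - c.t_mid),
        )
        out[m] = th
    return out


def generate_kinematics(config: GaitSimConfig, trial: str,
                        behaviour: str = "swimming",
                        n_cycles: int | None = None,
                        ) -> tuple[dict, list[StrokeCycle], GroundTruth]:
    """Simulate analytic landmark trajectories for one trial.

    The fish advances at constant speed along +x; fin elevation and
    adduction angle are sinusoids in stroke-phase angle, so their per-cycle
    extrema, ranges and extreme timings have exact closed forms, stored in
    the ground truth together with swing-path lengths obtained by adaptive
    quadrature of the analytic path derivative.
    """
    if n_cycles is None:
        n_cycles = config.cycles_per_fish
    rng_cyc = _trial_rng(config, trial, f"cycles-{behaviour}")
    lead_in = 0.5
    cycles = _make_cycles(config, behaviour, rng_cyc, n_cycles, lead_in)
    p = config.kinematic_params[behaviour]
    fs = config.fs_video
    t0, t1 = cycles[0].t_start, cycles[-1].t_end
    n = int(np.floor((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    theta = _phase_angle(t, cycles)

    v = p["speed"]
    # peak phases (deg) of each sinusoid on the stroke circle
    PEAK_ELEV, PEAK_ADD, PEAK_NOSE = 200.0, 250.0, 40.0
    x_n = v * (t - t0)
    z_n = p["nose_elev_amp"] * np.cos(theta - np.deg2rad(PEAK_NOSE))
    nose = LandmarkTrajectory("nose_tip", t, np.column_stack(
        [x_n, np.zeros(n), z_n]))

    # caudal tip trails one body length behind, oscillating laterally at
    # the cycle frequency (phase angle doubles as oscillation phase)
    y_c = p["caudal_amp"] * np.sin(theta)
    caudal = LandmarkTrajectory("caudal_tip", t, np.column_stack(
        [x_n - 1.0, y_c, np.zeros(n)]))

    # fin base trails the nose; the tip swings about the base in the x-y
    # plane at the adduction angle, and rides the elevation sinusoid in z
    d_base, r_fin = 0.3, 0.15
    alpha = np.deg2rad(p["add_center"]
                       + p["add_amp"] * np.cos(theta - np.deg2rad(PEAK_ADD)))
    x_b = x_n - d_base
    base = LandmarkTrajectory("pect_base", t, np.column_stack(
        [x_b, np.zeros(n), np.full(n, p["elev_center"])]))
    z_tip = (p["elev_center"]
             + p["elev_amp"] * np.cos(theta - np.deg2rad(PEAK_ELEV)))
    tip = LandmarkTrajectory("pect_tip", t, np.column_stack(
        [x_b + r_fin * np.cos(alpha), r_fin * np.sin(alpha), z_tip]))

    # closed-form ground truth (exact for the analytic trajectories)
    gt = GroundTruth(true_cycles=[(c.t_start, c.t_mid, c.t_end) for c in cycles])
    swing = {}
    for name, c in (("pect", cycles[0]),):
        # analytic x-y speed of the fin tip over one cycle, integrated
        def tip_speed(tt, c=c):
            th = _phase_angle(np.atleast_1d(tt), [c])
            dth = np.where(np.atleast_1d(tt) < c.t_mid,
                           np.pi / (c.t_mid - c.t_start),
                           np.pi / (c.t_end - c.t_mid))
            a = np.deg2rad(p["add_center"]
                           + p["add_amp"] * np.cos(th - np.deg2rad(PEAK_ADD)))
            da = -np.deg2rad(p["add_amp"]) * np.sin(th - np.deg2rad(PEAK_ADD)) * dth
            dx = v - r_fin * np.sin(a) * da
            dy = r_fin * np.cos(a) * da
            return np.sqrt(dx**2 + dy**2)[0]
        swing[name], _ = integrate.quad(
            tip_speed, c.t_start, c.t_end,
            points=[c.t_mid], limit=200)
    gt.true_kinematics = {
        "add_max": p["add_center"] + p["add_amp"],
        "add_min": p["add_center"] - p["add_amp"],
        "add_range": 2 * p["add_amp"],
        "elev_max": p["elev_center"] + p["elev_amp"],
        "elev_min": p["elev_center"] - p["elev_amp"],
        "elev_range": 2 * p["elev_amp"],
        "speed": v,
        "t_add_max_deg": PEAK_ADD,
        "t_elev_max_deg": PEAK_ELEV,
        "t_nose_max_deg": PEAK_NOSE,
        "pect_swing_first_cycle": swing["pect"],
    }
    traj = {"nose_tip": nose, "caudal_tip": caudal,
            "pect_tip": tip, "pect_base": base}
    return traj, cycles, gt


# --- study design ------------------------------------------------------------


def generate_study(
    config: GaitSimConfig,
    grand_mean: float = 60.0,
    behaviour_effect: float = 8.0,
    muscle_effects: dict | None = None,
    interaction: dict | None = None,
    residual_sd: float = 10.0,
    with_muscle: bool = True,
) -> tuple["pd.DataFrame", GroundTruth]:
    """Tidy nested study table with known fixed effects.

    response = grand mean + behaviour effect (walking) + muscle effect
    + interaction + fish intercept (Normal, sd = random_fish_sd) + residual.
    The default magnitudes resemble a duty-factor-like percentage response.
    """
    import pandas as pd

    if muscle_effects is None:
        muscle_effects = {"Abd": 0.0, "Add": 4.0, "Cmt": -2.0, "Zpt": 2.0} \
            if with_muscle else {}
    interaction = interaction or {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9111]))
    fish_int = rng.normal(0.0, config.random_fish_sd, size=config.n_fish)
    rows = []
    muscles = list(muscle_effects) if with_muscle else [None]
    for i in range(config.n_fish):
        for beh in config.behaviours:
            b_eff = behaviour_effect if beh == "walking" else 0.0
            for _ in range(config.cycles_per_fish):
                for m in muscles:
                    mu = grand_mean + b_eff + fish_int[i]
                    if m is not None:
                        mu += muscle_effects[m] + interaction.get((beh, m), 0.0)
                    val = mu + (rng.normal(0.0, residual_sd)
                                if residual_sd > 0 else 0.0)
                    rows.append({"fish": f"fish{i + 1}", "behaviour": beh,
                                 "muscle": m, "value": val})
    gt = GroundTruth(true_fixed_effects={
        "grand_mean": grand_mean,
        "behaviour_effect": behaviour_effect,
        "muscle_effects": muscle_effects,
        "interaction": dict(interaction),
        "fish_intercepts": fish_int.tolist(),
        "residual_sd": residual_sd,
    })
    return pd.DataFrame(rows), gt


def generate_fluorescence(effect_d: float, gradient_slope: float,
                          n_cells: int, seed: int,
                          baseline: float = 50.0, noise_sd: float = 10.0,
                          background: float = 5.0,
                          size_class: str = "small") -> "pd.DataFrame":
    """Cell-level fluorescence table with a treatment effect and gradient.

    Walked-fish cell intensities are shifted by ``effect_d`` pooled standard
    deviations above control; intensity rises by ``gradient_slope`` per
    percent fin length; the constant per-section background is added to
    every cell so that background subtraction is exercised downstream.
    """
    import pandas as pd

    if n_cells < 2:
        raise ValueError("need at least 2 cells per group")
    rng = np.random.default_rng(seed)
    rows = []
    for treatment in ("control", "walked"):
        shift = effect_d * noise_sd if treatment == "walked" else 0.0
        for muscle in MUSCLES:
            pct = rng.uniform(0, 100, size=n_cells)
            inten = (baseline + shift + gradient_slope * pct
                     + rng.normal(0, noise_sd, size=n_cells) + background)
            for k in range(n_cells):
                rows.append({
                    "fish": f"{treatment}_fish{k % 2 + 1}",
                    "size_class": size_class,
                    "treatment": treatment,
                    "muscle": muscle,
                    "pct_fin_length": pct[k],
                    "cell_intensity": inten[k],
                    "background": background,
                })
    return pd.DataFrame(rows)
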