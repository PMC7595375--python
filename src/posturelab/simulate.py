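"""Synthetic stander: closed-loop sway simulator for the four visual and
three platform conditions.

The balance model is a single-link inverted pendulum for the COM angle,
stabilized by a delayed PD controller acting on a weighted sum of sensory
error signals (proprioceptive ankle angle, visual and vestibular space
references), each carrying its own low-pass-filtered noise.  Closing the
eyes removes the (low-noise) visual channel and shifts its weight onto the
noisier vestibular channel, which is what makes sway grow across the
EO -> LAB -> ABS -> EC presets.  A kinematic two-segment readout (plus a
small COM-neutral hip wobble that keeps the hip and shoulder channels
linearly independent) produces the sway-rod translations; the controller
torque is the torque channel.  This is a stand-in plant for exercising the
analysis chain, not a validated physiological model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .io import SwayRecording
from .prts import TiltStimulus, default_stimulus

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


__all__ = [
    "SimulationConfig",
    "Study",
    "FallError",
    "VISUAL_CONDITIONS",
    "PLATFORM_MODES",
    "simulate_trial",
    "sway_reference_servo",
    "simulate_calibration_motion",
    "generate_study",
]

VISUAL_CONDITIONS = ("EO", "LAB", "ABS", "EC")
PLATFORM_MODES = ("fixed", "swayref", "fixed_swayref", "tilt")

#: visual weight presets; remaining weight (1 - w_prop - w_vis) is vestibular
DEFAULT_W_VIS = {"EO": 0.35, "LAB": 0.33, "ABS": 0.15, "EC": 0.0}


class FallError(RuntimeError):
    """Simulated stander exceeded the fall threshold."""

    def __init__(self, message: str, time_s: float):
        super().__init__(message)
        self.time_s = time_s


@dataclass(frozen=True)
class SimulationConfig:
    """Plant, controller, noise and protocol parameters for one stander.

    ``kp``/``kd``/``h_com``/segment lengths default to values derived from
    mass and height when left as None.
    """

    body_mass: float = 70.0  # kg
    body_height: float = 1.71  # m
    h_com: Optional[float] = None  # m above ankle axis; default 0.55 * height
    leg_length: Optional[float] = None  # ankle-hip, default 0.515 * height
    trunk_length: Optional[float] = None  # hip-shoulder, default 0.305 * height
    leg_mass_fraction: float = 0.35
    leg_com_fraction: float = 0.59  # leg COM height as fraction of leg length
    ankle_motion_ratio: float = 0.8  # share of COM excursion carried by the leg

    kp: Optional[float] = None  # N*m/rad; default 2.25 * m*g*h_com
    kd: Optional[float] = None  # N*m*s/rad; default 0.29 * kp
    delay: float = 0.1  # s feedback delay

    w_prop: float = 0.25
    w_vis: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_W_VIS))

    torque_noise_sd: float = 1.5  # N*m
    torque_noise_cutoff: float = 0.5  # Hz
    vis_noise_sd: float = 0.0006  # rad
    prop_noise_sd: float = 0.0012  # rad
    vest_noise_sd: float = 0.0040  # rad
    sensory_noise_cutoff: float = 0.4  # Hz
    wobble_sd: float = 0.002  # m, COM-neutral hip mode (channel independence)
    wobble_cutoff: float = 0.3  # Hz

    servo_time_constant: float = 0.0  # s; 0 = exact sway referencing
    sample_rate: float = 1000.0  # Hz
    spont_duration: float = 45.0  # s per spontaneous-sway segment
    calib_duration: float = 120.0  # s
    fall_threshold_deg: float = 10.0
    jitter: float = 0.10  # inter-subject multiplicative jitter
    g: float = 9.81

    # --- derived quantities -------------------------------------------------
    def resolved(self) -> "SimulationConfig":
        """Fill in all None defaults so every parameter is explicit."""
        h = self.h_com if self.h_com is not None else 0.55 * self.body_height
        leg = self.leg_length if self.leg_length is not None else 0.515 * self.body_height
        trunk = (
            self.trunk_length
            if self.trunk_length is not None
            else 0.305 * self.body_height
        )
        kp = self.kp if self.kp is not None else 2.25 * self.body_mass * self.g * h
        kd = self.kd if self.kd is not None else 0.29 * kp
        return replace(self, h_com=h, leg_length=leg, trunk_length=trunk, kp=kp, kd=kd)

    def segment_gains(self) -> Tuple[float, float]:
        """(P, Q): COM displacement per unit sin(leg angle) / sin(trunk angle)."""
        c = self.resolved()
        f_leg = c.leg_mass_fraction
        f_tr = 1.0 - f_leg
        p = f_leg * c.leg_com_fraction * c.leg_length + f_tr * c.leg_length
        q = c.h_com - p
        if q <= 0:
            raise ValueError(
                f"h_com={c.h_com:.3g} m is below the leg-only COM height "
                f"{p:.3g} m; inconsistent anthropometrics"
            )
        return p, q

    def true_calibration(self) -> Tuple[float, float, float]:
        """Ground-truth (a, b, c) of x_com = a + b*x_hip + c*x_sho."""
        c = self.resolved()
        p, q = self.segment_gains()
        b = p / c.leg_length - q / c.trunk_length
        cc = q / c.trunk_length
        return 0.0, b, cc

    def weights_for(self, visual: str) -> Tuple[float, float, float]:
        """(w_prop, w_vis, w_vest) for a visual condition; sums to 1."""
        if visual not in self.w_vis:
            raise ValueError(f"unknown visual condition {visual!r}")
        w_vis = self.w_vis[visual]
        w_vest = 1.0 - self.w_prop - w_vis
        if w_vest < 0:
            raise ValueError(
                f"w_prop + w_vis = {self.w_prop + w_vis} > 1 for {visual!r}"
            )
        return self.w_prop, w_vis, w_vest


@njit(cache=True)
def _closed_loop(
    n,
    dt,
    mgh,
    inertia,
    kp,
    kd,
    delay_steps,
    w_prop,
    w_rest,
    e_noise,
    t_noise,
    wobble,
    stim_rad,
    servo_on,
    servo_coef,
    r_ankle,
    h_com,
    p_gain,
    fall_rad,
):  # pragma: no cover - numba-compiled hot loop, covered via callers
    theta = np.empty(n)
    torque = np.empty(n)
    plat = np.empty(n)
    s_leg = np.empty(n)
    e_hist = np.empty(n)
    th = 0.0
    om = 0.0
    th_plat = 0.0
    for k in range(n):
        x_com = h_com * math.sin(th)
        s_l = r_ankle * x_com / p_gain + wobble[k]
        th_leg = math.asin(s_l)
        if servo_on[k] == 1:
            th_plat = th_plat + servo_coef * (th_leg - th_plat)
        else:
            th_plat = stim_rad[k]
        e = w_prop * (th_leg - th_plat) + w_rest * th + e_noise[k]
        e_hist[k] = e
        if k - delay_steps >= 1:
            e_del = e_hist[k - delay_steps]
            de = (e_del - e_hist[k - delay_steps - 1]) / dt
            t_k = kp * e_del + kd * de + t_noise[k]
        elif k - delay_steps == 0:
            t_k = kp * e_hist[0] + t_noise[k]
        else:
            t_k = t_noise[k]
        theta[k] = th
        torque[k] = t_k
        plat[k] = th_plat
        s_leg[k] = s_l
        # RK4 step, torque held constant over the step
        k1t = om
        k1o = (mgh * math.sin(th) - t_k) / inertia
        k2t = om + 0.5 * dt * k1o
        k2o = (mgh * math.sin(th + 0.5 * dt * k1t) - t_k) / inertia
        k3t = om + 0.5 * dt * k2o
        k3o = (mgh * math.sin(th + 0.5 * dt * k2t) - t_k) / inertia
        k4t = om + dt * k3o
        k4o = (mgh * math.sin(th + dt * k3t) - t_k) / inertia
        th = th + dt * (k1t + 2.0 * k2t + 2.0 * k3t + k4t) / 6.0
        om = om + dt * (k1o + 2.0 * k2o + 2.0 * k3o + k4o) / 6.0
        if abs(th) > fall_rad:
            return theta, torque, plat, s_leg, k
    return theta, torque, plat, s_leg, -1


def _filtered_noise(
    rng: np.random.Generator, n: int, sd: float, cutoff: float, rate: float
) -> np.ndarray:
    """White noise low-passed (2nd-order Butterworth) and rescaled to ``sd``."""
    white = rng.standard_normal(n)
    if sd == 0.0:
        return np.zeros(n)
    if cutoff < rate / 2:
        sos = signal.butter(2, cutoff, btype="low", fs=rate, output="sos")
        white = signal.sosfilt(sos, white)
    s = white.std()
    return white * (sd / s) if s > 0 else white


def sway_reference_servo(
    theta_leg: np.ndarray, time_constant: float, sample_rate: float
) -> np.ndarray:
    """First-order lag tracking of the leg-segment tilt (platform tilt, deg in
    -> deg out).  At ``time_constant = 0`` the platform tracks exactly, so the
    ankle angle never changes."""
    if time_constant < 0:
        raise ValueError(f"time_constant must be >= 0, got {time_constant}")
    x = np.asarray(theta_leg, dtype=float)
    if time_constant == 0:
        return x.copy()
    coef = 1.0 - math.exp(-1.0 / (time_constant * sample_rate))
    y = np.empty_like(x)
    prev = 0.0
    for k in range(len(x)):
        prev = prev + coef * (x[k] - prev)
        y[k] = prev
    return y


def _run_closed_loop(
    config: SimulationConfig,
    visual: str,
    n: int,
    stim_rad: np.ndarray,
    servo_on: np.ndarray,
    seed,
) -> dict:
    c = config.resolved()
    rate = c.sample_rate
    dt = 1.0 / rate
    p_gain, q_gain = c.segment_gains()
    w_prop, w_vis, w_vest = c.weights_for(visual)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    r_prop, r_vis, r_vest, r_torque, r_wobble = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    e_noise = (
        w_prop * _filtered_noise(r_prop, n, c.prop_noise_sd, c.sensory_noise_cutoff, rate)
        + w_vis * _filtered_noise(r_vis, n, c.vis_noise_sd, c.sensory_noise_cutoff, rate)
        + w_vest * _filtered_noise(r_vest, n, c.vest_noise_sd, c.sensory_noise_cutoff, rate)
    )
    t_noise = _filtered_noise(r_torque, n, c.torque_noise_sd, c.torque_noise_cutoff, rate)
    wobble = _filtered_noise(r_wobble, n, c.wobble_sd, c.wobble_cutoff, rate)

    tau = c.servo_time_constant
    servo_coef = 1.0 if tau <= 0 else 1.0 - math.exp(-dt / tau)
    mgh = c.body_mass * c.g * c.h_com
    inertia = c.body_mass * c.h_com**2
    theta, torque, plat, s_leg, fall = _closed_loop(
        n,
        dt,
        mgh,
        inertia,
        c.kp,
        c.kd,
        int(round(c.delay * rate)),
        w_prop,
        w_vis + w_vest,
        e_noise,
        t_noise,
        wobble,
        stim_rad,
        servo_on,
        servo_coef,
        c.ankle_motion_ratio,
        c.h_com,
        p_gain,
        math.radians(c.fall_threshold_deg),
    )
    if fall >= 0:
        raise FallError(
            f"simulated stander fell at t = {fall * dt:.3f} s "
            f"(|theta| > {c.fall_threshold_deg} deg; visual={visual!r})",
            time_s=fall * dt,
        )
    x_com = c.h_com * np.sin(theta)
    s_tr = (1.0 - c.ankle_motion_ratio) * x_com / q_gain - (p_gain / q_gain) * wobble
    x_hip = c.leg_length * s_leg
    x_sho = x_hip + c.trunk_length * s_tr
    return {
        "theta_deg": np.degrees(theta),
        "x_com": x_com,
        "x_hip": x_hip,
        "x_sho": x_sho,
        "torque": torque,
        "platform_deg": np.degrees(plat),
        "weights": (w_prop, w_vis, w_vest),
        "config": c,
    }


def simulate_trial(
    config: SimulationConfig,
    visual: str,
    platform: str,
    stimulus: Optional[TiltStimulus] = None,
    seed=0,
    subject_id: Optional[str] = None,
) -> SwayRecording:
    """Simulate one trial of a given visual x platform condition.

    ``platform`` is one of ``fixed``, ``swayref``, ``fixed_swayref`` (one
    recording holding a fixed segment followed by a sway-referenced segment)
    or ``tilt`` (requires ``stimulus``).  Deterministic given (config, seed).
    """
    if platform not in PLATFORM_MODES:
        raise ValueError(f"unknown platform mode {platform!r}; use one of {PLATFORM_MODES}")
    if (stimulus is None) == (platform == "tilt"):
        raise ValueError("a TiltStimulus is required iff platform == 'tilt'")
    c = config.resolved()
    rate = c.sample_rate
    n_spont = int(round(c.spont_duration * rate))
    if platform == "tilt":
        if abs(stimulus.sample_rate - rate) > 1e-9:
            raise ValueError(
                f"stimulus sample rate {stimulus.sample_rate} != config rate {rate}"
            )
        stim_rad = np.radians(stimulus.tilt_full)
        n = len(stim_rad)
        servo_on = np.zeros(n, dtype=np.uint8)
    elif platform == "fixed":
        n = n_spont
        stim_rad = np.zeros(n)
        servo_on = np.zeros(n, dtype=np.uint8)
    elif platform == "swayref":
        n = n_spont
        stim_rad = np.zeros(n)
        servo_on = np.ones(n, dtype=np.uint8)
    else:  # fixed_swayref
        n = 2 * n_spont
        stim_rad = np.zeros(n)
        servo_on = np.zeros(n, dtype=np.uint8)
        servo_on[n_spont:] = 1

    out = _run_closed_loop(c, visual, n, stim_rad, servo_on, seed)
    w_prop, w_vis, w_vest = out["weights"]
    meta = {
        "body_mass_kg": c.body_mass,
        "h_com_m": c.h_com,
        "kp": c.kp,
        "kd": c.kd,
        "delay_s": c.delay,
        "w_prop": w_prop,
        "w_vis": w_vis,
        "w_vest": w_vest,
        "seed": str(seed),
        "model": "single-link pendulum, delayed PD, two-segment readout",
    }
    if platform == "tilt":
        meta["stimulus"] = {k: v for k, v in stimulus.metadata.items()}
    if platform == "fixed_swayref":
        meta["swayref_start_s"] = c.spont_duration
    return SwayRecording(
        t=np.arange(n) / rate,
        x_hip=out["x_hip"],
        x_sho=out["x_sho"],
        torque=out["torque"],
        platform_tilt=out["platform_deg"],
        sample_rate=rate,
        visual=visual,
        platform=platform,
        subject_id=subject_id,
        meta=meta,
        extras={"theta_com_deg": out["theta_deg"], "x_com_m": out["x_com"]},
    )


def simulate_calibration_motion(
    config: SimulationConfig,
    duration: Optional[float] = None,
    seed=0,
    f_leg: float = 0.02,
    f_trunk: float = 0.035,
    amp_leg: float = 0.025,
    amp_trunk: float = 0.05,
    measurement_noise_sd: float = 0.0,
    subject_id: Optional[str] = None,
) -> SwayRecording:
    """Quasi-static calibration motion: prescribed slow sinusoidal ankle and
    hip oscillations at two incommensurate frequencies (default <= 0.035 Hz).

    The torque channel is built from the COP of the lumped pendulum,
    ``x_cop = x_com - (h_com / g) * x_com''``, whose deviation from the COM
    scales with frequency squared and is negligible at these rates.
    """
    c = config.resolved()
    if duration is None:
        duration = c.calib_duration
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    rate = c.sample_rate
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    p_gain, q_gain = c.segment_gains()

    w1, w2 = 2 * math.pi * f_leg, 2 * math.pi * f_trunk
    phase = math.pi / 3
    s_leg = amp_leg * np.sin(w1 * t)
    s_tr = amp_trunk * np.sin(w2 * t + phase)
    x_com = p_gain * s_leg + q_gain * s_tr
    acc = -p_gain * amp_leg * w1**2 * np.sin(w1 * t) - q_gain * amp_trunk * w2**2 * np.sin(
        w2 * t + phase
    )
    x_cop = x_com - (c.h_com / c.g) * acc
    torque = c.body_mass * c.g * x_cop
    x_hip = c.leg_length * s_leg
    x_sho = x_hip + c.trunk_length * s_tr
    if measurement_noise_sd > 0:
        rng = np.random.default_rng(
            seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        )
        x_hip = x_hip + rng.normal(0, measurement_noise_sd, n)
        x_sho = x_sho + rng.normal(0, measurement_noise_sd, n)
    return SwayRecording(
        t=t,
        x_hip=x_hip,
        x_sho=x_sho,
        torque=torque,
        platform_tilt=np.zeros(n),
        sample_rate=rate,
        visual=None,
        platform="calibration",
        subject_id=subject_id,
        meta={
            "body_mass_kg": c.body_mass,
            "h_com_m": c.h_com,
            "seed": str(seed),
            "frequencies_hz": [f_leg, f_trunk],
        },
        extras={"x_com_m": x_com, "x_cop_m": x_cop},
    )


@dataclass
class Study:
    """A full synthetic study: recordings plus the ground-truth table."""

    recordings: List[SwayRecording]
    ground_truth: pd.DataFrame
    config: SimulationConfig
    stimulus: TiltStimulus
    seed: int

    def subjects(self) -> List[str]:
        return list(self.ground_truth["subject"])

    def get(self, subject_id: str, platform: str, visual: Optional[str] = None) -> SwayRecording:
        for rec in self.recordings:
            if (
                rec.subject_id == subject_id
                and rec.platform == platform
                and (visual is None or rec.visual == visual)
            ):
                return rec
        raise KeyError(f"no recording ({subject_id!r}, {platform!r}, {visual!r})")


def generate_study(
    config: SimulationConfig,
    n_subjects: int,
    seed: int,
    stimulus: Optional[TiltStimulus] = None,
) -> Study:
    """Simulate a full study: per subject one calibration recording plus, for
    each of the 4 visual conditions, one combined fixed/sway-referenced trial
    and one tilt trial.  Anthropometrics and gains are jittered per subject
    (multiplicative, +/- ``config.jitter``); everything is deterministic
    given (config, seed)."""
    if n_subjects < 2:
        raise ValueError(f"n_subjects must be >= 2, got {n_subjects}")
    base = config.resolved()
    if stimulus is None:
        stimulus = default_stimulus(sample_rate=base.sample_rate)
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)

    recordings: List[SwayRecording] = []
    truth_rows = []
    for i, sseq in enumerate(subject_seeds):
        sid = f"S{i + 1:02d}"
        rng = np.random.default_rng(sseq)
        j = base.jitter

        def jit(value, r=rng, lo_hi=j):
            return value * (1.0 + r.uniform(-lo_hi, lo_hi))

        mass = jit(base.body_mass)
        height = jit(base.body_height)
        h_com = 0.55 * height
        kp = jit(2.25 * mass * base.g * h_com)
        kd = jit(0.29 * kp)
        w_prop = float(np.clip(jit(base.w_prop), 0.05, 0.6))
        cfg_s = replace(
            base,
            body_mass=mass,
            body_height=height,
            h_com=h_com,
            leg_length=0.515 * height,
            trunk_length=0.305 * height,
            kp=kp,
            kd=kd,
            w_prop=w_prop,
        )
        _, b_true, c_true = cfg_s.true_calibration()
        trial_seeds = sseq.spawn(1 + 2 * len(VISUAL_CONDITIONS))
        recordings.append(
            simulate_calibration_motion(cfg_s, seed=trial_seeds[0], subject_id=sid)
        )
        for k, visual in enumerate(VISUAL_CONDITIONS):
            recordings.append(
                simulate_trial(
                    cfg_s,
                    visual,
                    "fixed_swayref",
                    seed=trial_seeds[1 + 2 * k],
                    subject_id=sid,
                )
            )
            recordings.append(
                simulate_trial(
                    cfg_s,
                    visual,
                    "tilt",
                    stimulus=stimulus,
                    seed=trial_seeds[2 + 2 * k],
                    subject_id=sid,
                )
            )
        row = {
            "subject": sid,
            "body_mass_kg": mass,
            "body_height_m": height,
            "h_com_m": h_com,
            "kp": kp,
            "kd": kd,
            "w_prop": w_prop,
            "b_true": b_true,
            "c_true": c_true,
        }
        for visual in VISUAL_CONDITIONS:
            wp, wv, wve = cfg_s.weights_for(visual)
            row[f"w_vis_{visual}"] = wv
            row[f"w_vest_{visual}"] = wve
        truth_rows.append(row)

    return Study(
        recordings=recordings,
        ground_truth=pd.DataFrame(truth_rows),
        config=base,
        stimulus=stimulus,
        seed=seed,
    )
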