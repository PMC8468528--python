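"""Synthetic gait sessions with known ground truth.

Emulates what a pylon-embedded 6-axis load cell records while a person
wearing a variable-stiffness prosthetic foot walks a circuit of level
ground, +/-5 degree ramps, and stairs at three forefoot stiffness settings
(low/medium/high, coded 0/1/2).

Each stride draws a target DMAMA from a linear model with a per-subject
intercept, a stiffness slope, an incline slope, and a negative
stiffness-by-incline interaction, plus stride-to-stride noise.  Stance
waveforms are then built in the shank frame — a two-peak axial loading
profile, an S-shaped anterior-posterior shear, and an ankle-moment waveform
scaled so the ratio of ankle-moment impulse to sagittal-force-impulse
magnitude equals the drawn target exactly (trapezoid rule on the stride's
own jittered sample times).  The load-cell wrench is obtained by inverting
the quasi-static moment transfer (sensor Mz = ankle moment - (r x F)_z),
rotating into the load-cell frame with the inverse of the true mounting
rotation, and adding sensor noise.  Sample times carry the load cell's
nonuniform rate (truncated normal, mean 149.9 Hz, SD 38.5 Hz, floored).

Stairs take no incline value: they enter the target model with a zero
incline term and participate in mode labels and stiffness analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.spatial.transform import Rotation

from .series import LOAD_CELL_FRAME, SubjectGeometry, WrenchSeries

MODES = ("down_ramp", "level", "up_ramp", "down_stairs", "up_stairs")
STIFFNESS_LEVELS = ("low", "medium", "high")

#: circuit order walked within each stiffness trial
CIRCUIT = ("level", "up_ramp", "down_ramp", "up_stairs", "down_stairs")

# Per-mode waveform shaping.  amp: axial peak (x body weight); notch: depth of
# the mid-stance valley (negative = single central peak, used for stairs);
# shear/skew: anterior-posterior shear amplitude and propulsive bias; mx/my:
# accessory frontal/transverse sensor-moment amplitudes (N*m); fz: mediolateral
# force (x body weight); stance_scale: relative stance duration.  The impulse
# ratio is the only constrained quantity; these shapes exist to make modes
# qualitatively distinct and hence classifiable.
MODE_SHAPES = {
    "level": dict(amp=1.05, notch=0.25, shear=0.18, skew=0.00, mx=2.0, my=1.0, fz=0.05, stance_scale=1.00),
    "up_ramp": dict(amp=1.00, notch=0.15, shear=0.25, skew=0.35, mx=3.0, my=1.6, fz=0.06, stance_scale=1.06),
    "down_ramp": dict(amp=1.12, notch=0.33, shear=0.27, skew=-0.35, mx=1.2, my=2.4, fz=0.07, stance_scale=0.95),
    "up_stairs": dict(amp=0.95, notch=-0.20, shear=0.10, skew=0.50, mx=4.5, my=3.4, fz=0.09, stance_scale=1.12),
    "down_stairs": dict(amp=1.22, notch=-0.33, shear=0.12, skew=-0.50, mx=0.6, my=4.2, fz=0.10, stance_scale=0.90),
}

_EDGE_FRACTION = 0.01   # loading edge rise/fall, fraction of stance
_AXIAL_PEDESTAL = 0.18  # axial pedestal (x body weight) inside stance


def _default_strides() -> dict:
    # circuit yield per stiffness trial: many level strides, ~11 of each other mode
    return {"level": 50, "up_ramp": 11, "down_ramp": 11, "up_stairs": 11, "down_stairs": 11}


@dataclass
class SessionConfig:
    """Generative configuration; defaults mirror the study conditions.

    DMAMA coefficients are in percent foot length: per stiffness increment
    (``beta_stiffness``), per degree incline (``beta_incline``), and per
    increment-degree (``beta_interaction``).  ``stride_noise_sd`` is the
    stride-to-stride DMAMA SD; sensor noise is additive white noise on the
    load-cell channels.
    """

    subjects: int = 4
    strides_per_condition: dict = field(default_factory=_default_strides)
    modes: tuple = MODES
    stiffness_levels: tuple = STIFFNESS_LEVELS
    incline_deg: dict = field(
        default_factory=lambda: {"down_ramp": -5.0, "level": 0.0, "up_ramp": 5.0}
    )
    beta0_subject: tuple = (10.0, 14.0, 8.0, 12.0)
    beta_stiffness: float = 3.01
    beta_incline: float = 0.413
    beta_interaction: float = -0.145
    stride_noise_sd: float = 3.0
    sample_rate_mean_hz: float = 149.9
    sample_rate_sd_hz: float = 38.5
    sample_rate_floor_hz: float = 50.0
    sensor_noise_force_sd: float = 1.0
    sensor_noise_moment_sd: float = 0.1
    stance_duration_s: float = 0.65
    swing_duration_s: float = 0.45
    foot_length_m: float = 0.24
    body_weight_n: tuple = (883.0, 1030.0, 736.0, 883.0)
    seed: int = 0

    def validate(self) -> "SessionConfig":
        if self.subjects < 1:
            raise ValueError("subjects must be >= 1")
        if len(self.beta0_subject) < self.subjects:
            raise ValueError("beta0_subject must provide one intercept per subject")
        if len(self.body_weight_n) < self.subjects:
            raise ValueError("body_weight_n must provide one weight per subject")
        for mode in self.modes:
            if mode not in MODE_SHAPES:
                raise ValueError(f"unknown mode {mode!r}")
            if self.stride_count(mode, 0) < 1:
                raise ValueError("all stride counts must be >= 1")
        for name in ("stride_noise_sd", "sensor_noise_force_sd", "sensor_noise_moment_sd",
                     "sample_rate_sd_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("stance_duration_s", "swing_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.foot_length_m <= 0:
            raise ValueError("foot length must be positive")
        if min(self.body_weight_n[: self.subjects]) <= 0:
            raise ValueError("body weight must be positive")
        if self.sample_rate_floor_hz <= 0 or self.sample_rate_mean_hz <= self.sample_rate_floor_hz:
            raise ValueError("mean sample rate must exceed the positive floor rate")
        return self

    def stride_count(self, mode: str, stiffness_code: int) -> int:
        """Stride count for a condition; keys may be mode or (mode, stiffness)."""
        spc = self.strides_per_condition
        if (mode, stiffness_code) in spc:
            return int(spc[(mode, stiffness_code)])
        return int(spc[mode])

    def incline_for(self, mode: str) -> float:
        """Incline in degrees; stairs carry no incline and contribute 0."""
        return float(self.incline_deg.get(mode, 0.0))

    def target_dmama(self, subject: int, mode: str, stiffness_code: int) -> float:
        """Noise-free target DMAMA (% foot length) for one condition."""
        inc = self.incline_for(mode)
        return (
            self.beta0_subject[subject]
            + self.beta_stiffness * stiffness_code
            + self.beta_incline * inc
            + self.beta_interaction * stiffness_code * inc
        )


@dataclass(frozen=True)
class SubjectRecording:
    """One subject's session with its generating ground truth.

    ``geometry`` holds the *true* sensor-to-shank rotation and offsets;
    ``stride_truth`` the drawn per-stride target DMAMA with true stance
    boundaries; ``sample_labels`` the per-sample mode/stiffness annotation
    with transition flags.
    """

    subject: int
    wrench_lc: WrenchSeries
    geometry: SubjectGeometry
    sample_labels: pd.DataFrame
    stride_truth: pd.DataFrame


@dataclass(frozen=True)
class SyntheticSession:
    config: SessionConfig
    subjects: list

    def stride_truth(self) -> pd.DataFrame:
        return pd.concat([s.stride_truth for s in self.subjects], ignore_index=True)


def _truncnorm_rates(rng: np.random.Generator, n: int, cfg: SessionConfig) -> np.ndarray:
    """Per-sample rates from a normal truncated below at the floor rate."""
    lo = ndtr((cfg.sample_rate_floor_hz - cfg.sample_rate_mean_hz) / cfg.sample_rate_sd_hz)
    u = lo + (1.0 - lo) * rng.random(n)
    return cfg.sample_rate_mean_hz + cfg.sample_rate_sd_hz * ndtri(u)


def _edge_window(phi: np.ndarray, r: float = _EDGE_FRACTION) -> np.ndarray:
    """Smoothstep loading/unloading edges so force leaves zero quickly."""
    up = np.clip(phi / r, 0.0, 1.0)
    dn = np.clip((1.0 - phi) / r, 0.0, 1.0)
    return up * up * (3 - 2 * up) * dn * dn * (3 - 2 * dn)


def _stance_waveforms(phi: np.ndarray, mode: str, body_weight: float):
    """Shank-frame force channels and the unit ankle-moment shape."""
    p = MODE_SHAPES[mode]
    w = _edge_window(phi)
    fy = body_weight * w * (
        _AXIAL_PEDESTAL + p["amp"] * (np.sin(np.pi * phi) + p["notch"] * np.sin(3 * np.pi * phi))
    )
    fx = body_weight * w * p["shear"] * (-np.sin(2 * np.pi * phi) + p["skew"] * np.sin(np.pi * phi))
    fz = body_weight * w * p["fz"] * np.sin(np.pi * phi)
    moment_shape = np.sin(np.pi * phi) ** 2 * (0.25 + 0.75 * phi)
    return fx, fy, fz, moment_shape, w


def _subject_geometry(rng: np.random.Generator, cfg: SessionConfig, subject: int) -> SubjectGeometry:
    """True mounting geometry: a small random sensor misalignment plus
    joint-to-sensor lever arms (load cell sits above the prosthetic ankle,
    below the knee)."""
    rotvec = np.radians(rng.normal(0.0, 3.0, size=3))
    R = Rotation.from_rotvec(rotvec).as_matrix()
    r_ankle = np.array([0.01, 0.12, 0.005]) + rng.normal(0.0, 0.005, size=3)
    r_knee = np.array([0.01, -0.30, 0.005]) + rng.normal(0.0, 0.005, size=3)
    return SubjectGeometry(
        rotation_lc_to_shank=R,
        r_ankle_to_lc=r_ankle,
        r_knee_to_lc=r_knee,
        foot_length=cfg.foot_length_m,
        body_weight=float(cfg.body_weight_n[subject]),
    )


def draw_stride_table(config: SessionConfig, rng=None) -> pd.DataFrame:
    """Draw the per-stride target DMAMA table without waveform synthesis.

    The statistical structure (subject intercepts, condition slopes, stride
    noise) is identical to what :func:`generate_session` embeds in its
    waveforms; this path serves sensitivity analyses and parameter-recovery
    studies where only the stride-level table matters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for subject in range(config.subjects):
        for code in range(len(config.stiffness_levels)):
            for mode in [m for m in CIRCUIT if m in config.modes]:
                n = config.stride_count(mode, code)
                mu = config.target_dmama(subject, mode, code)
                draws = mu + config.stride_noise_sd * rng.standard_normal(n)
                for d in draws:
                    rows.append(
                        {
                            "subject": subject,
                            "mode": mode,
                            "stiffness_code": code,
                            "incline_deg": config.incline_for(mode),
                            "dmama_pct_foot": float(d),
                            "transition": False,
                        }
                    )
    return pd.DataFrame(rows)


def _synth_stride(rng, cfg, geometry, t0, mode, target_pct):
    """Build one stride (stance + following swing) at jittered sample times.

    Returns (times, F_shank, M_shank, phi, stance_mask, t_heel_strike,
    t_toe_off).  The ankle-moment waveform is scaled so the trapezoidal
    impulse ratio over the stance samples equals ``target_pct``.
    """
    p = MODE_SHAPES[mode]
    t_stance = cfg.stance_duration_s * p["stance_scale"] * (1.0 + 0.03 * rng.standard_normal())
    t_stance = max(t_stance, 0.3)
    total = t_stance + cfg.swing_duration_s
    max_rate = cfg.sample_rate_mean_hz + 6 * cfg.sample_rate_sd_hz
    n_draw = int(total * max_rate) + 8
    dt = 1.0 / _truncnorm_rates(rng, n_draw, cfg)
    jitter = t0 + np.cumsum(dt)
    # explicit samples at the exact stance boundaries (waveform zeros there)
    # keep the sampled piecewise-linear signal consistent with the target
    # impulse ratio under exact-window integration downstream
    times = np.concatenate(
        [
            [t0],
            jitter[jitter < t0 + t_stance - 1e-9],
            [t0 + t_stance],
            jitter[(jitter > t0 + t_stance + 1e-9) & (jitter < t0 + total)],
        ]
    )

    stance = times <= t0 + t_stance
    phi = np.zeros_like(times)
    phi[stance] = (times[stance] - t0) / t_stance

    force = np.zeros((len(times), 3))
    moment = np.zeros((len(times), 3))
    fx, fy, fz, mshape, w = _stance_waveforms(phi[stance], mode, geometry.body_weight)
    ts = times[stance]

    impulse_x = np.trapezoid(fx, ts)
    impulse_y = np.trapezoid(fy, ts)
    impulse_mag = np.hypot(impulse_x, impulse_y)
    shape_integral = np.trapezoid(mshape, ts)
    target_m = target_pct / 100.0 * geometry.foot_length
    m_ankle = (target_m * impulse_mag / shape_integral) * mshape

    # invert the quasi-static transfer: sensor Mz = M_ankle - (r x F_sag)_z
    ra = geometry.r_ankle_to_lc
    mz = m_ankle - (ra[0] * fy - ra[1] * fx)
    force[stance] = np.column_stack([fx, fy, fz])
    moment[stance] = np.column_stack(
        [p["mx"] * np.sin(np.pi * phi[stance]) * w, p["my"] * np.sin(2 * np.pi * phi[stance]) * w, mz]
    )
    return times, force, moment, stance, float(t0), float(t0 + t_stance)


def generate_session(config: SessionConfig, geometry_overrides: dict | None = None) -> SyntheticSession:
    """Generate a full multi-subject session in the load-cell frame.

    For each subject and stiffness trial, strides are laid out in circuit
    order with one flagged transition stride at every mode boundary.  The
    returned streams are in the *load-cell* frame (rotated by the inverse
    of each subject's true mounting rotation, with sensor noise added);
    running calibrate -> segment -> DMAMA downstream should recover each
    stride's target.

    ``geometry_overrides`` maps subject index to a fixed
    :class:`SubjectGeometry`, replacing the randomly drawn true mounting
    geometry for that subject (useful for controlled checks, e.g. an
    identity rotation).
    """
    config.validate()
    geometry_overrides = geometry_overrides or {}
    rng = np.random.default_rng(config.seed)
    subjects = []
    for subject in range(config.subjects):
        drawn = _subject_geometry(rng, config, subject)
        geometry = geometry_overrides.get(subject, drawn)
        times_l, force_l, moment_l = [], [], []
        lab_mode, lab_stiff, lab_trans = [], [], []
        truth_rows = []
        t_cursor = 0.5
        stride_id = 0
        for code in range(len(config.stiffness_levels)):
            circuit = [m for m in CIRCUIT if m in config.modes]
            for bi, mode in enumerate(circuit):
                block = [("transition", mode)] if bi else []
                block += [("stride", mode)] * config.stride_count(mode, code)
                for kind, m in block:
                    mu = config.target_dmama(subject, m, code)
                    target = mu + config.stride_noise_sd * rng.standard_normal()
                    t, f, mm, stance, hs, to = _synth_stride(
                        rng, config, geometry, t_cursor, m, target
                    )
                    is_trans = kind == "transition"
                    modes = np.full(len(t), m, dtype=object)
                    if is_trans:  # mode boundary falls mid-stance
                        modes[t < (hs + to) / 2] = circuit[bi - 1]
                    times_l.append(t)
                    force_l.append(f)
                    moment_l.append(mm)
                    lab_mode.append(modes)
                    lab_stiff.append(np.full(len(t), code))
                    lab_trans.append(stance & is_trans)
                    truth_rows.append(
                        {
                            "stride_id": stride_id,
                            "subject": subject,
                            "mode": m,
                            "stiffness_code": code,
                            "incline_deg": config.incline_for(m),
                            "hs_time_s": hs,
                            "to_time_s": to,
                            "target_dmama_pct": target,
                            "transition": is_trans,
                        }
                    )
                    stride_id += 1
                    t_cursor = t[-1] + 1.0 / config.sample_rate_mean_hz
            t_cursor += 1.0  # pause between stiffness trials

        time = np.concatenate(times_l)
        force = np.concatenate(force_l)
        moment = np.concatenate(moment_l)
        # rotate into the load-cell frame with the inverse of the true rotation
        Rt = geometry.rotation_lc_to_shank.T
        force = force @ Rt.T
        moment = moment @ Rt.T
        force = force + config.sensor_noise_force_sd * rng.standard_normal(force.shape)
        moment = moment + config.sensor_noise_moment_sd * rng.standard_normal(moment.shape)

        subjects.append(
            SubjectRecording(
                subject=subject,
                wrench_lc=WrenchSeries(time=time, force=force, moment=moment, frame=LOAD_CELL_FRAME),
                geometry=geometry,
                sample_labels=pd.DataFrame(
                    {
                        "time_s": time,
                        "mode": np.concatenate(lab_mode),
                        "stiffness_code": np.concatenate(lab_stiff).astype(int),
                        "transition_flag": np.concatenate(lab_trans),
                    }
                ),
                stride_truth=pd.DataFrame(truth_rows),
            )
        )
    return SyntheticSession(config=config, subjects=subjects)


def generate_calibration_trial(
    geometry: SubjectGeometry,
    n_samples: int,
    orientation_noise_deg: float = 1.0,
    offset_noise_m: float = 0.002,
    seed: int = 0,
):
    """Noisy paired observations of the true rotation and offset vectors.

    Each rotation sample is the true rotation composed with a small random
    rotation whose rotation-vector components have SD
    ``orientation_noise_deg``; offsets get isotropic Gaussian noise.

    Returns ``(rotations (n,3,3), ankle_offsets (n,3), knee_offsets (n,3))``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if orientation_noise_deg < 0 or offset_noise_m < 0:
        raise ValueError("noise magnitudes must be >= 0")
    rng = np.random.default_rng(seed)
    rotvecs = np.radians(orientation_noise_deg) * rng.standard_normal((n_samples, 3))
    perturb = Rotation.from_rotvec(rotvecs).as_matrix().reshape(n_samples, 3, 3)
    rotations = geometry.rotation_lc_to_shank[None] @ perturb
    ankle = geometry.r_ankle_to_lc[None] + offset_noise_m * rng.standard_normal((n_samples, 3))
    knee = geometry.r_knee_to_lc[None] + offset_noise_m * rng.standard_normal((n_samples, 3))
    return rotations, ankle, knee
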