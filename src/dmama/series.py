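"""Core data containers for pylon load-cell gait analysis.

Shank-frame axis convention used throughout the package: X anterior,
Y proximal (up the pylon), Z to the subject's right.  The sagittal plane is
X–Y and the sagittal moment is the Z component, with plantarflexion
(ground reaction force anterior to the ankle) positive.  A positive DMAMA
therefore reads as a mean moment-arm anterior to the ankle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

LOAD_CELL_FRAME = "load_cell"
SHANK_FRAME = "shank"

#: determinant / orthonormality tolerance for calibrated rotation matrices
ROTATION_TOL = 1e-9


def _as_float_array(x, name: str, shape_tail: tuple[int, ...]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 + len(shape_tail) or arr.shape[1:] != shape_tail:
        raise ValueError(f"{name} must have shape (n, {', '.join(map(str, shape_tail))})"
                         if shape_tail else f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class WrenchSeries:
    """Time-stamped 3-axis force + 3-axis moment samples in a named frame.

    Parameters
    ----------
    time : (n,) array, seconds — strictly increasing, possibly nonuniform.
    force : (n, 3) array, newtons.
    moment : (n, 3) array, newton-metres.
    frame : ``"load_cell"`` or ``"shank"``.
    """

    time: np.ndarray
    force: np.ndarray
    moment: np.ndarray
    frame: str = LOAD_CELL_FRAME

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = _as_float_array(self.force, "force", (3,))
        m = _as_float_array(self.moment, "moment", (3,))
        if t.ndim != 1:
            raise ValueError("time must be one-dimensional")
        if not (len(t) == len(f) == len(m)):
            raise ValueError("time, force and moment must have equal sample counts")
        if len(t) and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"timestamps must be strictly increasing (violated at sample {bad})")
        for name, arr in (("time", t), ("force", f), ("moment", m)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.frame not in (LOAD_CELL_FRAME, SHANK_FRAME):
            raise ValueError(f"unknown frame {self.frame!r}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "moment", m)

    def __len__(self) -> int:
        return len(self.time)

    def with_frame(self, frame: str) -> "WrenchSeries":
        return replace(self, frame=frame)


def _check_rotation(R: np.ndarray, tol: float = ROTATION_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if abs(np.linalg.det(R) - 1.0) > tol or np.max(np.abs(R.T @ R - np.eye(3))) > tol:
        raise ValueError("rotation must be orthonormal with determinant +1")
    return R


@dataclass(frozen=True)
class SubjectGeometry:
    """Per-subject geometric calibration of the pylon-embedded load cell.

    ``rotation_lc_to_shank`` rotates load-cell-frame vectors into the shank
    frame.  ``r_ankle_to_lc`` / ``r_knee_to_lc`` point from the joint centre
    to the load-cell origin (metres); they are the lever arms of the
    quasi-static moment transfer.
    """

    rotation_lc_to_shank: np.ndarray
    r_ankle_to_lc: np.ndarray
    r_knee_to_lc: np.ndarray
    foot_length: float
    body_weight: float

    def __post_init__(self):
        R = _check_rotation(self.rotation_lc_to_shank)
        ra = np.asarray(self.r_ankle_to_lc, dtype=float).reshape(3)
        rk = np.asarray(self.r_knee_to_lc, dtype=float).reshape(3)
        if not self.foot_length > 0:
            raise ValueError("foot_length must be positive")
        if not self.body_weight > 0:
            raise ValueError("body_weight must be positive")
        object.__setattr__(self, "rotation_lc_to_shank", R)
        object.__setattr__(self, "r_ankle_to_lc", ra)
        object.__setattr__(self, "r_knee_to_lc", rk)

    def offset(self, joint: str) -> np.ndarray:
        try:
            return {"ankle": self.r_ankle_to_lc, "knee": self.r_knee_to_lc}[joint]
        except KeyError:
            raise KeyError(f"no offset vector for joint {joint!r}") from None


@dataclass(frozen=True)
class StrideSegment:
    """One stance phase, heel strike to toe-off, with condition labels."""

    stride_id: int
    heel_strike: float
    toe_off: float
    mode: str = ""
    stiffness_code: int = -1
    transition_excluded: bool = False

    def __post_init__(self):
        if not self.heel_strike < self.toe_off:
            raise ValueError("heel_strike must precede toe_off")

    @property
    def duration(self) -> float:
        return self.toe_off - self.heel_strike


@dataclass(frozen=True)
class JointMomentSeries:
    """Sagittal quasi-static joint moments derived from a shank-frame wrench.

    ``ankle_moment`` and ``knee_moment`` are scalar sagittal (Z) moments,
    extensor positive; ``sagittal_force`` keeps the (Fx, Fy) components used
    in the moment transfer and in the DMAMA denominator.
    """

    time: np.ndarray
    ankle_moment: np.ndarray
    knee_moment: np.ndarray
    sagittal_force: np.ndarray  # (n, 2): anterior, proximal

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class DmamaResult:
    """Per-stride DMAMA: moment impulse over GRF impulse, as a length."""

    stride_id: int
    moment_impulse: float        # N·m·s, ∫ M_ankle dt over stance
    force_impulse_magnitude: float  # N·s, ‖∫ (Fx, Fy) dt‖
    mean_ankle_moment: float     # N·m
    mean_sagittal_force: float   # N
    dmama_m: float
    dmama_pct_foot: float
    mode: str = ""
    stiffness_code: int = -1
    valid: bool = True
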