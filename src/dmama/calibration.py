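"""Load-cell-to-shank frame calibration.

A pylon-mounted load cell is never perfectly aligned with the shank.  The
definitive alignment is estimated from repeated noisy observations of the
load-cell-to-shank rotation: each 3x3 sample is converted to its rotation
vector (axis scaled by angle, the Rodrigues parametrisation), the vectors are
averaged element-wise, and the mean vector is mapped back through the
exponential map.  Joint-to-sensor offset vectors are averaged arithmetically.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .series import (
    LOAD_CELL_FRAME,
    SHANK_FRAME,
    SubjectGeometry,
    WrenchSeries,
)

#: orthonormality tolerance accepted on *input* rotation samples
SAMPLE_TOL = 1e-6
#: rotation angles this close to pi are rejected (axis sign ambiguity)
PI_GUARD = 1e-6


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    """Polar projection onto SO(3), absorbing floating-point drift."""
    U, _, Vt = np.linalg.svd(R)
    out = U @ Vt
    if np.linalg.det(out) < 0:  # reflection guard; unreachable for near-rotations
        U[:, -1] *= -1
        out = U @ Vt
    return out


def average_rotation(samples) -> np.ndarray:
    """Average rotation matrices via element-wise rotation-vector averaging.

    Parameters
    ----------
    samples : sequence of (3, 3) arrays or (n, 3, 3) array
        Rotation-matrix observations; each must be orthonormal with
        determinant +1 within ``SAMPLE_TOL``.

    Returns
    -------
    (3, 3) ndarray — a valid rotation (orthonormal, det +1).

    Raises
    ------
    ValueError
        On an empty sample set, a non-orthonormal sample, or a sample whose
        rotation angle lies within ``PI_GUARD`` of pi, where the rotation
        vector's sign is ambiguous and element-wise averaging breaks down.
    """
    mats = np.asarray(samples, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.ndim != 3 or mats.shape[1:] != (3, 3) or len(mats) == 0:
        raise ValueError("samples must be a non-empty set of 3x3 matrices")
    dets = np.linalg.det(mats)
    if np.any(np.abs(dets - 1.0) > SAMPLE_TOL):
        raise ValueError("rotation sample with |det - 1| beyond tolerance")
    err = np.abs(np.einsum("nij,nik->njk", mats, mats) - np.eye(3)).max()
    if err > SAMPLE_TOL:
        raise ValueError("rotation sample not orthonormal within tolerance")

    rotvecs = Rotation.from_matrix(mats).as_rotvec()
    angles = np.linalg.norm(np.atleast_2d(rotvecs), axis=1)
    if np.any(np.abs(angles - np.pi) < PI_GUARD):
        raise ValueError("rotation angle at pi: axis sign ambiguous, cannot average")
    mean_vec = np.atleast_2d(rotvecs).mean(axis=0)
    return _orthonormalize(Rotation.from_rotvec(mean_vec).as_matrix())


def average_offset(samples) -> np.ndarray:
    """Element-wise arithmetic mean of 3-vector offset observations."""
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None]
    if arr.ndim != 2 or arr.shape[1] != 3 or len(arr) == 0:
        raise ValueError("samples must be a non-empty set of 3-vectors")
    return arr.mean(axis=0)


def to_shank_frame(series: WrenchSeries, geometry: SubjectGeometry) -> WrenchSeries:
    """Re-express a load-cell-frame wrench stream in the shank frame.

    Rotates every force and moment sample by ``rotation_lc_to_shank``;
    timestamps are untouched.  Refuses a series already tagged as shank
    frame so a stream can never be rotated twice.
    """
    if series.frame == SHANK_FRAME:
        raise ValueError("series is already in the shank frame")
    if series.frame != LOAD_CELL_FRAME:
        raise ValueError(f"cannot rotate series in frame {series.frame!r}")
    R = geometry.rotation_lc_to_shank
    return WrenchSeries(
        time=series.time,
        force=series.force @ R.T,
        moment=series.moment @ R.T,
        frame=SHANK_FRAME,
    )


class FrameCalibrator:
    """Estimator for the definitive sensor-to-shank alignment.

    ``fit`` consumes paired calibration observations (rotation matrices and
    joint-to-sensor offset vectors); ``transform`` applies the fitted
    rotation to a load-cell-frame wrench stream.

    Attributes (after ``fit``)
    --------------------------
    rotation_ : (3, 3) ndarray — averaged load-cell-to-shank rotation.
    r_ankle_to_lc_, r_knee_to_lc_ : (3,) ndarray or None — averaged offsets.
    n_samples_ : int
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "FrameCalibrator":
        if params:
            raise ValueError(f"unknown parameters: {sorted(params)}")
        return self

    def fit(self, rotations, ankle_offsets=None, knee_offsets=None) -> "FrameCalibrator":
        self.rotation_ = average_rotation(rotations)
        self.r_ankle_to_lc_ = None if ankle_offsets is None else average_offset(ankle_offsets)
        self.r_knee_to_lc_ = None if knee_offsets is None else average_offset(knee_offsets)
        self.n_samples_ = len(np.asarray(rotations).reshape(-1, 3, 3))
        return self

    def geometry(self, foot_length: float, body_weight: float) -> SubjectGeometry:
        """Bundle the fitted alignment into a :class:`SubjectGeometry`."""
        self._check_fitted()
        if self.r_ankle_to_lc_ is None or self.r_knee_to_lc_ is None:
            raise ValueError("offset samples were not provided to fit()")
        return SubjectGeometry(
            rotation_lc_to_shank=self.rotation_,
            r_ankle_to_lc=self.r_ankle_to_lc_,
            r_knee_to_lc=self.r_knee_to_lc_,
            foot_length=foot_length,
            body_weight=body_weight,
        )

    def transform(self, series: WrenchSeries) -> WrenchSeries:
        self._check_fitted()
        if series.frame == SHANK_FRAME:
            raise ValueError("series is already in the shank frame")
        return WrenchSeries(
            time=series.time,
            force=series.force @ self.rotation_.T,
            moment=series.moment @ self.rotation_.T,
            frame=SHANK_FRAME,
        )

    def fit_transform(self, rotations, series: WrenchSeries, **kw) -> WrenchSeries:
        return self.fit(rotations, **kw).transform(series)

    def _check_fitted(self):
        if not hasattr(self, "rotation_"):
            raise AttributeError("FrameCalibrator is not fitted; call fit() first")


def geodesic_angle_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic distance between two rotations, in degrees."""
    rel = Rotation.from_matrix(np.asarray(R1) @ np.asarray(R2).T)
    return float(np.degrees(rel.magnitude()))
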