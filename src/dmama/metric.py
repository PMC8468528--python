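"""Quasi-static joint moments and the dynamic mean ankle moment arm (DMAMA).

The sagittal joint moment at the ankle (or knee) is transported from the
load-cell origin using quasi-static vector mechanics,

    M_joint = (r_joint_to_lc x F_sagittal)_z + M_z ,

neglecting inertial terms, which are small during stance.  DMAMA for one
stance phase is the ratio of the sagittal ankle-moment impulse to the
magnitude of the vector impulse of the sagittal ground reaction force,

    DMAMA = (integral of M_ankle dt) / || integral of (Fx, Fy) dt || ,

a length: the mean anterior moment arm of the ground reaction impulse about
the ankle.  It is reported both in metres and as a percentage of the
prosthetic foot length.  All integrals are trapezoidal on the measured
(nonuniform) sample times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import (
    SHANK_FRAME,
    DmamaResult,
    JointMomentSeries,
    StrideSegment,
    SubjectGeometry,
    WrenchSeries,
)

#: strides whose sagittal force impulse falls below this (N·s) are flagged invalid
MIN_FORCE_IMPULSE_NS = 1.0


def joint_moments(series: WrenchSeries, geometry: SubjectGeometry) -> JointMomentSeries:
    """Sagittal ankle and knee moments via quasi-static moment transport.

    For each sample the joint moment is the Z component of
    ``r_joint_to_lc x F_sagittal`` plus the sensed Z moment, with the force
    restricted to the sagittal (X–Y) plane.  Extensor positive.
    """
    if series.frame != SHANK_FRAME:
        raise ValueError("joint moments require a shank-frame series")
    fx, fy = series.force[:, 0], series.force[:, 1]
    mz = series.moment[:, 2]

    def transport(joint: str) -> np.ndarray:
        r = geometry.offset(joint)
        # (r x F_sag)_z with F_sag = (Fx, Fy, 0)
        return r[0] * fy - r[1] * fx + mz

    return JointMomentSeries(
        time=series.time,
        ankle_moment=transport("ankle"),
        knee_moment=transport("knee"),
        sagittal_force=np.column_stack([fx, fy]),
    )


def compute_dmama(
    moments: JointMomentSeries,
    segment: StrideSegment,
    geometry: SubjectGeometry,
) -> DmamaResult:
    """DMAMA for one stance phase, on the raw measured sample times.

    Integration runs over exactly [heel_strike, toe_off]: interior samples
    at their measured times, with channel values linearly interpolated at
    the two (possibly sub-sample) event times.  A stride whose sagittal
    force-impulse magnitude falls below ``MIN_FORCE_IMPULSE_NS`` is
    returned flagged ``valid=False`` rather than raising, so degenerate
    stances never crash a batch run.
    """
    t = moments.time
    hs, to = segment.heel_strike, segment.toe_off
    if hs < t[0] or to > t[-1]:
        raise ValueError("stride segment lies outside the series time range")
    inner = (t > hs) & (t < to)
    if inner.sum() < 1:
        raise ValueError("stride segment contains no interior samples")
    ts = np.concatenate([[hs], t[inner], [to]])
    duration = to - hs

    def integrate(channel: np.ndarray) -> float:
        vals = np.concatenate(
            [[np.interp(hs, t, channel)], channel[inner], [np.interp(to, t, channel)]]
        )
        return float(np.trapezoid(vals, ts))

    moment_impulse = integrate(moments.ankle_moment)
    fvec = np.array(
        [integrate(moments.sagittal_force[:, 0]), integrate(moments.sagittal_force[:, 1])]
    )
    force_impulse = float(np.hypot(*fvec))

    valid = force_impulse >= MIN_FORCE_IMPULSE_NS
    dmama_m = moment_impulse / force_impulse if valid else np.nan
    return DmamaResult(
        stride_id=segment.stride_id,
        moment_impulse=moment_impulse,
        force_impulse_magnitude=force_impulse,
        mean_ankle_moment=moment_impulse / duration,
        mean_sagittal_force=force_impulse / duration,
        dmama_m=dmama_m,
        dmama_pct_foot=100.0 * dmama_m / geometry.foot_length,
        mode=segment.mode,
        stiffness_code=segment.stiffness_code,
        valid=valid,
    )


def compute_dmama_table(
    series: WrenchSeries,
    segments: list[StrideSegment],
    geometry: SubjectGeometry,
) -> pd.DataFrame:
    """Per-stride DMAMA for a whole session (one row per stance).

    Columns: stride_id, mode, stiffness_code, excluded, dmama_mm,
    dmama_pct_foot, moment_impulse_nms, force_impulse_ns, valid.
    """
    moments = joint_moments(series, geometry)
    rows = []
    for seg in segments:
        r = compute_dmama(moments, seg, geometry)
        rows.append(
            {
                "stride_id": r.stride_id,
                "mode": r.mode,
                "stiffness_code": r.stiffness_code,
                "excluded": seg.transition_excluded,
                "dmama_mm": 1000.0 * r.dmama_m,
                "dmama_pct_foot": r.dmama_pct_foot,
                "moment_impulse_nms": r.moment_impulse,
                "force_impulse_ns": r.force_impulse_magnitude,
                "valid": r.valid,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stride_id",
            "mode",
            "stiffness_code",
            "excluded",
            "dmama_mm",
            "dmama_pct_foot",
            "moment_impulse_nms",
            "force_impulse_ns",
            "valid",
        ],
    )


def moving_average_dmama(values, window: int, excluded=None) -> np.ndarray:
    """Trailing mean of DMAMA over the last ``window`` non-excluded strides.

    A slow-adapting smoother for closed-loop stiffness control: stride-to-
    stride DMAMA fluctuates too much to drive per-step adjustments, so a
    controller should track the running average over several strides.

    Parameters
    ----------
    values : per-stride DMAMA values (%, ordered in time).
    window : number of trailing strides averaged (>= 1).
    excluded : optional boolean mask; excluded strides are skipped entirely
        (they neither produce nor enter an average).

    Returns
    -------
    Array of trailing means aligned with the non-excluded strides; entry i
    averages the last ``min(i + 1, window)`` included values.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = np.asarray(values, dtype=float)
    if excluded is not None:
        vals = vals[~np.asarray(excluded, dtype=bool)]
    return (
        pd.Series(vals).rolling(window, min_periods=1).mean().to_numpy()
        if len(vals)
        else vals
    )
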