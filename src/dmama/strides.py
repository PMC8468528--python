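"""Stance-phase detection and stride segmentation.

Gait events are read off the sagittal-plane force magnitude of the
shank-frame wrench: the foot is on the ground while ``hypot(Fx, Fy)``
exceeds 8% of body weight.  An upward crossing is a heel strike, a downward
crossing a toe-off.  Short threshold chatter is suppressed by a debounce
rule: below-threshold gaps shorter than the minimum swing time are merged
into the surrounding stance, and stances shorter than the minimum stance
time are discarded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import SHANK_FRAME, StrideSegment, WrenchSeries

#: stance threshold as a fraction of body weight
FORCE_THRESHOLD_FRACTION = 0.08
#: debounce: minimum accepted stance and swing durations, seconds
MIN_STANCE_S = 0.2
MIN_SWING_S = 0.1


def resample_uniform(series: WrenchSeries, rate: float) -> WrenchSeries:
    """Linearly interpolate every channel onto a uniform grid.

    Compensates for the load cell's nonuniform sampling before feature
    extraction for the locomotion-mode classifier.  (DMAMA itself is
    integrated on the raw measured sample times and never passes through
    here.)

    Parameters
    ----------
    series : WrenchSeries with at least 2 samples.
    rate : target sampling rate, Hz (> 0).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(series) < 2:
        raise ValueError("need at least 2 samples to resample")
    t = series.time
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * rate)) + 1) / rate
    force = np.column_stack([np.interp(grid, t, series.force[:, i]) for i in range(3)])
    moment = np.column_stack([np.interp(grid, t, series.moment[:, i]) for i in range(3)])
    return WrenchSeries(time=grid, force=force, moment=moment, frame=series.frame)


def sagittal_force_magnitude(series: WrenchSeries) -> np.ndarray:
    """``hypot(Fx, Fy)`` — the sagittal-plane force magnitude, N."""
    return np.hypot(series.force[:, 0], series.force[:, 1])


def detect_events(
    series: WrenchSeries,
    body_weight: float,
    threshold_fraction: float = FORCE_THRESHOLD_FRACTION,
    min_stance_s: float = MIN_STANCE_S,
    min_swing_s: float = MIN_SWING_S,
) -> list[tuple[float, float]]:
    """Detect (heel-strike, toe-off) time pairs from the sagittal force.

    Returns an empty list (not an error) when the signal never crosses the
    threshold.  Event times are refined to sub-sample precision by linear
    interpolation of the threshold crossing between the last below- and
    first above-threshold samples (and vice versa at toe-off), so on clean
    square pulses they land within one sample of the true edges.
    """
    if series.frame != SHANK_FRAME:
        raise ValueError("event detection expects a shank-frame series")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    threshold = threshold_fraction * body_weight
    sag = sagittal_force_magnitude(series)
    above = sag >= threshold
    if not above.any():
        return []
    t = series.time

    def crossing(i_out: int, i_in: int) -> float:
        """Interpolated threshold-crossing time between adjacent samples.

        Refinement is skipped across recording gaps (neighbour farther
        than the minimum swing time), where interpolation would invent a
        long sub-threshold ramp that never existed.
        """
        f0, f1 = sag[i_out], sag[i_in]
        if f1 == f0 or abs(t[i_in] - t[i_out]) > min_swing_s:
            return float(t[i_in])
        frac = np.clip((threshold - f0) / (f1 - f0), 0.0, 1.0)
        return float(t[i_out] + frac * (t[i_in] - t[i_out]))

    # contiguous above-threshold runs as [start_idx, end_idx] inclusive
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    runs = list(zip(starts, ends))

    # debounce 1: merge runs separated by a sub-minimum swing gap (chatter dip)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and t[s] - t[merged[-1][1]] < min_swing_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # debounce 2: drop stances shorter than the minimum stance duration,
    # refining accepted edges to the interpolated crossing times
    events = []
    for s, e in merged:
        if t[e] - t[s] < min_stance_s:
            continue
        hs = crossing(s - 1, s) if s > 0 else float(t[s])
        to = crossing(e + 1, e) if e < len(t) - 1 else float(t[e])
        events.append((hs, to))
    return events


def segment_strides(
    events: list[tuple[float, float]],
    labels: pd.DataFrame,
) -> list[StrideSegment]:
    """Attach condition labels to detected stances and flag transitions.

    Parameters
    ----------
    events : ordered (heel_strike, toe_off) pairs.
    labels : per-sample annotation frame with columns ``time_s``, ``mode``,
        ``stiffness_code`` and ``transition_flag``, covering the full time
        span of the events.

    Returns
    -------
    One :class:`StrideSegment` per stance, in time order.  The mode is the
    majority per-sample label over the stance; a stance whose samples span
    more than one mode, or any flagged transition sample, is marked
    ``transition_excluded``.
    """
    required = {"time_s", "mode", "stiffness_code", "transition_flag"}
    missing = required - set(labels.columns)
    if missing:
        raise ValueError(f"labels frame is missing columns: {sorted(missing)}")
    if not events:
        return []
    hs_all = min(hs for hs, _ in events)
    to_all = max(to for _, to in events)
    lt = labels["time_s"].to_numpy()
    if len(lt) == 0 or lt[0] > hs_all or lt[-1] < to_all:
        raise ValueError("labels do not cover the time range of the detected events")

    segments = []
    prev_to = -np.inf
    for i, (hs, to) in enumerate(events):
        if hs <= prev_to:
            raise ValueError("events must be ordered and non-overlapping")
        prev_to = to
        mask = (lt >= hs) & (lt <= to)
        stance = labels.loc[mask]
        if stance.empty:  # no annotation sample inside the stance window
            raise ValueError(f"no label samples inside stance [{hs:.3f}, {to:.3f}] s")
        modes = stance["mode"]
        mode = modes.mode().iloc[0]
        stiffness = int(stance["stiffness_code"].mode().iloc[0])
        excluded = bool(modes.nunique() > 1 or stance["transition_flag"].any())
        segments.append(
            StrideSegment(
                stride_id=i,
                heel_strike=hs,
                toe_off=to,
                mode=str(mode),
                stiffness_code=stiffness,
                transition_excluded=excluded,
            )
        )
    return segments


def segments_to_frame(segments: list[StrideSegment]) -> pd.DataFrame:
    """Tabulate stride segments (one row per stance)."""
    return pd.DataFrame(
        {
            "stride_id": [s.stride_id for s in segments],
            "hs_time_s": [s.heel_strike for s in segments],
            "to_time_s": [s.toe_off for s in segments],
            "mode": [s.mode for s in segments],
            "stiffness_code": [s.stiffness_code for s in segments],
            "excluded": [s.transition_excluded for s in segments],
        }
    )
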