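"""End-to-end orchestration: simulate -> calibrate -> segment -> DMAMA ->
classify -> sensitivity -> report.

Every stage draws its randomness from child seeds spawned from the single
run seed, so a rerun with the same configuration is byte-identical.  A
stage failure aborts the run naming the failing stage; artifacts written
by earlier stages are retained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .calibration import FrameCalibrator
from .classify import (
    DEFAULT_WINDOW_MS,
    LocomotionModeClassifier,
    SubjectStreams,
)
from .metric import compute_dmama_table, moving_average_dmama
from .sensitivity import fit_interaction, sensitivity_by_stratum
from .strides import detect_events, segment_strides, segments_to_frame
from .synthetic import (
    SessionConfig,
    SubjectRecording,
    generate_calibration_trial,
    generate_session,
)

log = logging.getLogger("dmama")

#: calibration-trial defaults: sample count and noise magnitudes
CALIBRATION_SAMPLES = 300
CALIBRATION_ROT_NOISE_DEG = 1.0
CALIBRATION_OFFSET_NOISE_M = 0.002


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    session: SessionConfig = field(default_factory=SessionConfig)
    out_dir: Path | str = "dmama_run"
    seed: int = 0
    run_classifier: bool = True
    run_sensitivity: bool = True
    classifier_feature_selection: bool = False
    classifier_window_optimization: bool = False
    classifier_folds: int = 10
    smoothing_window: int = 5
    log_level: str = "INFO"


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 for portability
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def calibrate_subject(rec: SubjectRecording, seed: int) -> "FrameCalibrator":
    """Run a synthetic calibration trial against the subject's true geometry
    and fit the definitive rotation/offsets from its noisy samples."""
    rot, ankle, knee = generate_calibration_trial(
        rec.geometry,
        CALIBRATION_SAMPLES,
        orientation_noise_deg=CALIBRATION_ROT_NOISE_DEG,
        offset_noise_m=CALIBRATION_OFFSET_NOISE_M,
        seed=seed,
    )
    return FrameCalibrator().fit(rot, ankle_offsets=ankle, knee_offsets=knee)


def process_subject(rec: SubjectRecording, calib_seed: int):
    """Calibrate, rotate, segment and score DMAMA for one subject.

    Returns ``(streams, strides_frame, dmama_frame)`` where ``streams`` is
    the classifier-ready shank-frame bundle.
    """
    calib = calibrate_subject(rec, calib_seed)
    geometry = calib.geometry(rec.geometry.foot_length, rec.geometry.body_weight)
    shank = calib.transform(rec.wrench_lc)
    events = detect_events(shank, geometry.body_weight)
    segments = segment_strides(events, rec.sample_labels)
    dmama = compute_dmama_table(shank, segments, geometry)
    dmama.insert(0, "subject", rec.subject)
    incline_by_mode = (
        rec.stride_truth.groupby("mode")["incline_deg"].first().to_dict()
    )
    dmama["incline_deg"] = dmama["mode"].map(lambda m: incline_by_mode.get(m, 0.0))
    streams = SubjectStreams(
        subject=rec.subject, series=shank, segments=segments, geometry=geometry
    )
    return streams, segments_to_frame(segments), dmama


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write per-stage artifacts.

    Returns the summary report (also written as ``report.json``).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session_cfg = dataclasses.replace(config.session, seed=config.seed)
    cfg_sha = io.config_hash(session_cfg)
    seeds = _child_seeds(config.seed, 2 + session_cfg.subjects)

    report = {"meta": {"seed": config.seed, "config_sha": cfg_sha}}

    try:
        session = generate_session(session_cfg)
    except Exception as e:
        raise StageError("simulate", e) from e
    for rec in session.subjects:
        tag = f"subject{rec.subject:02d}"
        io.write_session_csv(out / f"{tag}_session.csv", rec.wrench_lc, config.seed, cfg_sha)
        io.write_csv(out / f"{tag}_samples.csv", rec.sample_labels, config.seed, cfg_sha)
        io.write_csv(out / f"{tag}_truth.csv", rec.stride_truth, config.seed, cfg_sha)
        io.write_geometry_json(out / f"{tag}_geometry.json", rec.geometry, config.seed, cfg_sha)

    all_streams, dmama_frames = [], []
    for i, rec in enumerate(session.subjects):
        try:
            streams, strides, dmama = process_subject(rec, seeds[2 + i])
        except Exception as e:
            raise StageError("segment/dmama", e) from e
        tag = f"subject{rec.subject:02d}"
        io.write_csv(out / f"{tag}_strides.csv", strides, config.seed, cfg_sha)
        all_streams.append(streams)
        dmama_frames.append(dmama)

    dmama_all = pd.concat(dmama_frames, ignore_index=True)
    io.write_csv(out / "dmama.csv", dmama_all, config.seed, cfg_sha)
    ok = dmama_all[~dmama_all["excluded"] & dmama_all["valid"]]
    report["dmama"] = {
        "n_strides": int(len(dmama_all)),
        "n_included": int(len(ok)),
        "mean_pct_foot": float(ok["dmama_pct_foot"].mean()),
        "sd_pct_foot": float(ok["dmama_pct_foot"].std(ddof=1)),
        "smoothed_tail_pct_foot": float(
            moving_average_dmama(
                ok["dmama_pct_foot"].to_numpy(), config.smoothing_window
            )[-1]
        ),
    }

    if config.run_sensitivity:
        try:
            report["sensitivity"] = {
                "stiffness_by_mode": sensitivity_by_stratum(ok, "stiffness_code", "mode"),
                "incline_by_stiffness": sensitivity_by_stratum(
                    ok, "incline_deg", "stiffness_code"
                ),
                "interaction": fit_interaction(ok).to_dict(),
            }
        except Exception as e:
            raise StageError("sensitivity", e) from e

    if config.run_classifier:
        try:
            clf = LocomotionModeClassifier(
                folds=config.classifier_folds,
                seed=seeds[0],
                select_features=config.classifier_feature_selection,
                optimize_window_size=config.classifier_window_optimization,
                selection_window_ms=DEFAULT_WINDOW_MS,
            ).fit(all_streams)
            report["classifier"] = clf.report_.to_dict()
        except Exception as e:
            raise StageError("classify", e) from e

    io.write_json(out / "report.json", report)
    return report
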