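import numpy as np
import pytest

from dmama import (
    MODES,
    SessionConfig,
    compute_dmama_table,
    detect_events,
    generate_session,
    segment_strides,
    to_shank_frame,
)
from dmama.classify import SubjectStreams


@pytest.fixture(scope="session")
def clean_session():
    """Small noise-free session: 2 subjects, 3 strides per condition."""
    cfg = SessionConfig(
        subjects=2,
        strides_per_condition={m: 3 for m in MODES},
        stride_noise_sd=0.0,
        sensor_noise_force_sd=0.0,
        sensor_noise_moment_sd=0.0,
        seed=11,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def default_session():
    """Default study conditions: 4 subjects, imbalanced stride counts."""
    return generate_session(SessionConfig(seed=7))


def run_subject(rec, geometry=None):
    """Segment and score one subject using its true (or given) geometry."""
    geometry = geometry or rec.geometry
    shank = to_shank_frame(rec.wrench_lc, geometry)
    events = detect_events(shank, geometry.body_weight)
    segments = segment_strides(events, rec.sample_labels)
    table = compute_dmama_table(shank, segments, geometry)
    return shank, segments, table


def streams_for(session):
    """Classifier-ready shank-frame streams using true geometry."""
    out = []
    for rec in session.subjects:
        shank, segments, _ = run_subject(rec)
        out.append(
            SubjectStreams(
                subject=rec.subject,
                series=shank,
                segments=segments,
                geometry=rec.geometry,
            )
        )
    return out


@pytest.fixture(scope="session")
def default_streams(default_session):
    return streams_for(default_session)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
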