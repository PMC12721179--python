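"""Shared fixtures: generated sessions reused across test modules."""

from __future__ import annotations

import pytest

from gaitcode.kinematics import segment_session
from gaitcode.session import Session
from gaitcode.synth import GaitParams, generate_kinematics


@pytest.fixture(scope="session")
def trot_kin():
    """Default trot kinematics, 120 s: (table, ground truth)."""
    return generate_kinematics(GaitParams(), duration=120.0, seed=11)


@pytest.fixture(scope="session")
def trot_session(trot_kin):
    kin, _ = trot_kin
    return Session("trot", kin, [], frame_rate=80.0, duration=120.0)


@pytest.fixture(scope="session")
def trot_seg(trot_session):
    return segment_session(trot_session)


@pytest.fixture(scope="session")
def long_walk():
    """Walk-heavy kinematics (~85% walking, ~2000 strides) for tuning
    recovery tests: (table, ground truth, duration)."""
    gait = GaitParams(bout_duration=10.0, inter_bout_gap=1.2)
    duration = 1000.0
    kin, truth = generate_kinematics(gait, duration=duration, seed=7)
    return kin, truth, duration


@pytest.fixture(scope="session")
def long_walk_seg(long_walk):
    kin, _, duration = long_walk
    sess = Session("walkalot", kin, [], frame_rate=80.0, duration=duration)
    return segment_session(sess)
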