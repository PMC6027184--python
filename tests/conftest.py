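"""Shared fixtures: the synthetic subject, its calibration, and one full
muscle-driven forward-dynamics run of the 60 deg/s trial (expensive, so
session-scoped and reused by the tracking, normalization and EMG tests)."""

from __future__ import annotations

import numpy as np
import pytest

import elbowsim as es


@pytest.fixture(scope="session")
def subject() -> es.SyntheticSubject:
    return es.generate_subject()


@pytest.fixture(scope="session")
def calibrated_subject() -> es.SyntheticSubject:
    subj = es.generate_subject()
    laxity = es.generate_trial(subj, es.TrialSpec(label="laxity", seed=11))
    calibrated, _ = es.estimate_zero_load_lengths(subj.model.ligaments, laxity)
    subj.model.ligaments = calibrated
    return subj


@pytest.fixture(scope="session")
def trial_60(calibrated_subject) -> es.MotionTrial:
    return es.generate_trial(calibrated_subject,
                             es.TrialSpec(label="60deg_s", seed=12))


@pytest.fixture(scope="session")
def ik_60(calibrated_subject, trial_60) -> es.IKResult:
    return es.run_inverse_kinematics(calibrated_subject.model, trial_60)


@pytest.fixture(scope="session")
def fd_60(calibrated_subject, ik_60) -> es.SimulationResult:
    """Full forward-dynamics run of the synthetic 60 deg/s trial."""
    return es.run_forward_dynamics(calibrated_subject.model, ik_60,
                                   dt=1e-4, dt_output=0.01)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
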