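"""Shared fixtures: small simulated subjects reused across test modules.

All fixtures are generated programmatically at session scope so expensive
simulations run once.
"""

from __future__ import annotations

import numpy as np
import pytest

import nirseeg as ns


@pytest.fixture(scope="session")
def montage() -> ns.MontageSpec:
    return ns.default_montage()


@pytest.fixture(scope="session")
def small_paradigm() -> ns.ParadigmSpec:
    """Two-task, one-session paradigm: 16 trials, ~10 min of signal."""
    return ns.ParadigmSpec(
        tasks=("ROT", "FACE"), reps_per_subsession=4, n_subsessions=2, n_sessions=1
    )


@pytest.fixture(scope="session")
def small_subject(small_paradigm, montage):
    """One simulated subject (default effects, fixed heart rate)."""
    config = ns.SimulationConfig(seed=7, cardiac_bpm=66.0)
    schedule, sessions = ns.generate_subject(small_paradigm, montage, config, 0)
    return {"schedule": schedule, "sessions": sessions, "config": config}


@pytest.fixture(scope="session")
def small_features(small_subject, montage):
    """EEG (16 x 25 x 620) and NIRS (16 x 25 x 219) feature matrices."""
    eeg, nirs = ns.subject_feature_sets(
        small_subject["schedule"], small_subject["sessions"], montage
    )
    return eeg, nirs


@pytest.fixture(scope="session")
def erd_sim(montage):
    """40 mental-rotation trials in one subsession, preprocessed and epoched.

    Dense trial count makes intertrial-variance and band-power estimates
    stable enough for quantitative recovery checks.
    """
    paradigm = ns.ParadigmSpec(
        tasks=("ROT",), reps_per_subsession=40, n_subsessions=1, n_sessions=1
    )
    config = ns.SimulationConfig(seed=3, cardiac_bpm=66.0)
    schedule = ns.generate_schedule(paradigm, 11)
    raw = ns.simulate_eeg(schedule, montage, config, session=0)
    clean, rate = ns.preprocess_eeg(raw, config.eeg_rate, montage.eeg_channels)
    epochs = ns.epoch_session(clean, rate, schedule, 0, montage.eeg_channels)
    return {"schedule": schedule, "raw": raw, "epochs": epochs, "config": config}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
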