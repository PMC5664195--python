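"""Native plain-text fixture format for simulated sessions and result tables.

One directory per (subject, session):

    subject-01/session-00/
        schedule.tsv       session, subsession, onset_s, task (subsession-relative)
        spans.tsv          session, subsession, start_s, duration_s
        eeg.tsv            time x channels; header = channel labels
        nirs.tsv           time x channel-wavelength columns 'S<i>-D<j>@760' / '@850'
        montage.json       channel lists, hemisphere tags, region maps
        ground_truth.json  full simulation configuration + resolved cardiac BPM

Everything is TSV/JSON so fixtures diff cleanly and regeneration from the
same seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .montage import MontageSpec
from .nirs import MBLLCoefficients, WAVELENGTHS
from .paradigm import TrialSchedule
from .simulate import HRFSpec, MultimodalSession, SimulationConfig

__all__ = ["write_session", "read_session", "write_feature_table"]

_FLOAT_FMT = "%.9g"


def _montage_dict(montage: MontageSpec) -> dict:
    return {
        "eeg_channels": list(montage.eeg_channels),
        "nirs_channels": list(montage.nirs_channels),
        "hemisphere": dict(montage.hemisphere),
        "short_channels": list(montage.short_channels),
        "region_map": {k: list(v) for k, v in montage.region_map.items()},
        "eeg_regions": {k: list(v) for k, v in montage.eeg_regions.items()},
        "distance_cm": montage.distance_cm,
    }


def _montage_from_dict(d: dict) -> MontageSpec:
    return MontageSpec(
        eeg_channels=tuple(d["eeg_channels"]),
        nirs_channels=tuple(d["nirs_channels"]),
        hemisphere=dict(d["hemisphere"]),
        short_channels=tuple(d["short_channels"]),
        region_map={k: tuple(v) for k, v in d["region_map"].items()},
        eeg_regions={k: tuple(v) for k, v in d["eeg_regions"].items()},
        distance_cm=float(d["distance_cm"]),
    )


def _config_dict(config: SimulationConfig) -> dict:
    return {
        "eeg_rate": config.eeg_rate,
        "nirs_rate": config.nirs_rate,
        "effect_table": [[t, r, b, v] for (t, r, b), v in config.effect_table.items()],
        "hrf": {
            "onset_delay_s": config.hrf.onset_delay_s,
            "time_to_peak_s": config.hrf.time_to_peak_s,
            "undershoot": config.hrf.undershoot,
            "shape": config.hrf.shape,
            "amplitudes": [[t, r, c, v] for (t, r, c), v in config.hrf.amplitudes.items()],
        },
        "cardiac_bpm": config.cardiac_bpm,
        "eeg_osc_amplitudes": dict(config.eeg_osc_amplitudes),
        "eeg_noise_sd": config.eeg_noise_sd,
        "ramp_s": config.ramp_s,
        "cardiac_od_amplitude": config.cardiac_od_amplitude,
        "short_channel_cardiac_gain": config.short_channel_cardiac_gain,
        "cardiac_free_channels": list(config.cardiac_free_channels),
        "nirs_noise_sd": config.nirs_noise_sd,
        "nirs_drift_sd": config.nirs_drift_sd,
        "baseline_intensity": {str(k): v for k, v in config.baseline_intensity.items()},
        "mbll": {
            "extinction": {str(w): dict(v) for w, v in config.mbll.extinction.items()},
            "dpf": {str(w): v for w, v in config.mbll.dpf.items()},
            "distance_cm": config.mbll.distance_cm,
        },
        "seed": config.seed,
    }


def _config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(
        eeg_rate=d["eeg_rate"],
        nirs_rate=d["nirs_rate"],
        effect_table={(t, r, b): v for t, r, b, v in d["effect_table"]},
        hrf=HRFSpec(
            onset_delay_s=d["hrf"]["onset_delay_s"],
            time_to_peak_s=d["hrf"]["time_to_peak_s"],
            undershoot=d["hrf"]["undershoot"],
            shape=d["hrf"]["shape"],
            amplitudes={(t, r, c): v for t, r, c, v in d["hrf"]["amplitudes"]},
        ),
        cardiac_bpm=d["cardiac_bpm"],
        eeg_osc_amplitudes=dict(d["eeg_osc_amplitudes"]),
        eeg_noise_sd=d["eeg_noise_sd"],
        ramp_s=d["ramp_s"],
        cardiac_od_amplitude=d["cardiac_od_amplitude"],
        short_channel_cardiac_gain=d["short_channel_cardiac_gain"],
        cardiac_free_channels=tuple(d["cardiac_free_channels"]),
        nirs_noise_sd=d["nirs_noise_sd"],
        nirs_drift_sd=d.get("nirs_drift_sd", 0.0),
        baseline_intensity={int(k): v for k, v in d["baseline_intensity"].items()},
        mbll=MBLLCoefficients(
            extinction={int(w): dict(v) for w, v in d["mbll"]["extinction"].items()},
            dpf={int(w): v for w, v in d["mbll"]["dpf"].items()},
            distance_cm=d["mbll"]["distance_cm"],
        ),
        seed=d["seed"],
    )


def write_session(
    out_dir,
    subject: int,
    session: MultimodalSession,
    montage: MontageSpec,
    schedule: TrialSchedule,
) -> Path:
    """Write one session fixture directory; returns its path."""
    path = Path(out_dir) / f"subject-{subject + 1:02d}" / f"session-{session.session:02d}"
    path.mkdir(parents=True, exist_ok=True)

    sched = schedule.session_view(session.session)
    sched.trials.to_csv(path / "schedule.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    sched.spans.to_csv(path / "spans.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    eeg = pd.DataFrame(session.eeg, columns=list(montage.eeg_channels))
    eeg.to_csv(path / "eeg.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    cols = [f"{ch}@{w}" for ch in montage.nirs_channels for w in WAVELENGTHS]
    flat = session.nirs.reshape(session.nirs.shape[0], -1)
    pd.DataFrame(flat, columns=cols).to_csv(
        path / "nirs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    (path / "montage.json").write_text(json.dumps(_montage_dict(montage), indent=1, sort_keys=True))
    truth = _config_dict(session.ground_truth)
    truth["resolved_cardiac_bpm"] = session.cardiac_bpm
    truth["session"] = session.session
    truth["task_s"] = sched.task_s
    truth["cue_s"] = sched.cue_s
    (path / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return path


def read_session(path) -> tuple[MultimodalSession, MontageSpec]:
    """Read a session fixture directory written by :func:`write_session`."""
    path = Path(path)
    if not (path / "schedule.tsv").exists():
        raise ConfigurationError(f"{path} is not a session fixture directory")
    montage = _montage_from_dict(json.loads((path / "montage.json").read_text()))
    truth = json.loads((path / "ground_truth.json").read_text())
    config = _config_from_dict(truth)

    trials = pd.read_csv(path / "schedule.tsv", sep="\t")
    spans = pd.read_csv(path / "spans.tsv", sep="\t")
    schedule = TrialSchedule(trials, spans, truth.get("task_s", 15.0), truth.get("cue_s", 3.0))

    eeg = pd.read_csv(path / "eeg.tsv", sep="\t").to_numpy()
    nirs_flat = pd.read_csv(path / "nirs.tsv", sep="\t").to_numpy()
    nirs = nirs_flat.reshape(nirs_flat.shape[0], len(montage.nirs_channels), len(WAVELENGTHS))

    session = MultimodalSession(
        session=int(truth["session"]),
        schedule=schedule,
        eeg=eeg,
        eeg_rate=config.eeg_rate,
        nirs=nirs,
        nirs_rate=config.nirs_rate,
        ground_truth=config,
        cardiac_bpm=float(truth["resolved_cardiac_bpm"]),
    )
    return session, montage


def write_feature_table(features, path) -> Path:
    """Write a WindowedFeatureMatrix in the long TSV layout
    (rows = epoch x window, columns = '<channel>|<subtype>')."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    return path
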