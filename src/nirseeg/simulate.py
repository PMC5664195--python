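"""Synthetic multimodal sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes, not
head physics:

* **EEG** (512 Hz, 62 channels): 1/f Gaussian background plus one
  random-phase sinusoidal oscillator per (channel, band).  Task effects are
  event-related (de)synchronization: during each trial of an affected task the
  oscillator amplitude in the affected scalp region is scaled so that
  band-limited variance changes by the configured fraction (negative = ERD),
  with 0.5 s cosine on/off ramps.
* **NIRS** (4.46 Hz, 60 channels x 2 wavelengths): task-locked hemodynamic
  responses — a gamma-kernel Delta[HbO]/Delta[HbR] waveform with configurable
  onset delay and time-to-peak — are pushed through the forward Modified
  Beer-Lambert Law to optical densities, a common cardiac oscillation
  (stronger on the four short channels) and white noise are added, and
  intensities are emitted as baseline * exp(-OD).

Every draw derives from the configuration seed, so identical (config, seed)
pairs produce identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seeding import child_rng, child_seed
from .exceptions import ConfigurationError
from .montage import MontageSpec
from .nirs import MBLLCoefficients, WAVELENGTHS
from .paradigm import ParadigmSpec, TrialSchedule, generate_schedule

__all__ = [
    "HRFSpec",
    "SimulationConfig",
    "MultimodalSession",
    "default_effect_table",
    "default_hemo_amplitudes",
    "hrf_kernel",
    "simulate_eeg",
    "simulate_nirs",
    "simulate_session",
    "generate_subject",
    "generate_dataset",
]

#: Oscillator bands available to the EEG generator (name -> Hz interval).
OSCILLATOR_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha_low": (8.0, 10.0),
    "alpha_high": (10.0, 12.0),
    "beta_low": (12.0, 21.0),
    "beta_high": (21.0, 30.0),
}

#: Composite band keys accepted in effect tables.
_BAND_ALIASES: dict[str, tuple[str, ...]] = {
    **{name: (name,) for name in OSCILLATOR_BANDS},
    "alpha_total": ("alpha_low", "alpha_high"),
    "beta_total": ("beta_low", "beta_high"),
}


def default_effect_table(strength: float = 1.0) -> dict[tuple[str, str, str], float]:
    """Qualitative task -> (EEG region, band) power-change map.

    Encodes the canonical patterns: occipital alpha/beta suppression for
    mental rotation, left-temporal alpha for word generation, left-motor
    mu/beta for motor imagery, frontal theta enhancement for subtraction, and
    weaker imagery-task effects.  ``strength`` scales every fractional change.
    """
    base = {
        ("ROT", "occipital", "alpha_low"): -0.40,
        ("ROT", "occipital", "alpha_high"): -0.50,
        ("ROT", "occipital", "beta_low"): -0.30,
        ("WORD", "left_temporal", "alpha_total"): -0.35,
        ("SUB", "frontal", "theta"): 0.40,
        ("SUB", "occipital", "alpha_total"): -0.25,
        ("MI", "left_motor", "alpha_high"): -0.45,
        ("MI", "left_motor", "beta_low"): -0.30,
        ("SING", "left_temporal", "alpha_low"): -0.25,
        ("NAV", "right_parietal", "alpha_high"): -0.30,
        ("FACE", "right_temporal", "alpha_low"): -0.25,
    }
    return {k: v * strength for k, v in base.items()}


def default_hemo_amplitudes(strength: float = 1.0) -> dict[tuple[str, str, str], float]:
    """Task -> (NIRS region, chromophore) peak amplitudes in micromol/L."""
    base = {
        ("ROT", "centrofrontal_left", "HbO"): 0.8,
        ("ROT", "centrofrontal_right", "HbO"): 0.6,
        ("ROT", "centrofrontal_left", "HbR"): -0.25,
        ("WORD", "lateral_frontal_left", "HbO"): 0.8,
        ("WORD", "lateral_frontal_left", "HbR"): -0.25,
        ("SUB", "centrofrontal_left", "HbO"): 0.7,
        ("SUB", "centrofrontal_right", "HbO"): 0.7,
        ("MI", "central_left", "HbO"): 0.8,
        ("MI", "central_left", "HbR"): -0.25,
        ("SING", "temporoparietal_left", "HbO"): 0.6,
        ("NAV", "parietal_left", "HbO"): 0.5,
        ("NAV", "parietal_right", "HbO"): 0.5,
        ("FACE", "temporoparietal_right", "HbO"): 0.6,
    }
    return {k: v * strength for k, v in base.items()}


@dataclass(frozen=True)
class HRFSpec:
    """Hemodynamic response kernel: gamma wave minus a late undershoot.

    ``time_to_peak_s`` is measured from task onset (so the kernel itself peaks
    ``time_to_peak_s - onset_delay_s`` after the delayed response start).
    Amplitudes map (task, NIRS region, chromophore) to peak concentration
    changes in micromol/L (HbO positive, HbR negative by convention).
    """

    onset_delay_s: float = 2.0
    time_to_peak_s: float = 11.0
    undershoot: float = 0.15
    shape: float = 6.0
    amplitudes: dict[tuple[str, str, str], float] = field(default_factory=default_hemo_amplitudes)

    def __post_init__(self) -> None:
        if self.time_to_peak_s <= self.onset_delay_s:
            raise ConfigurationError("time_to_peak_s must exceed onset_delay_s")


def hrf_kernel(t: np.ndarray, spec: HRFSpec) -> np.ndarray:
    """Unit-peak hemodynamic kernel evaluated at times ``t`` (s since onset).

    Gamma densities are evaluated in log space (each normalized to a unit
    peak), so arbitrarily late times underflow to zero instead of overflowing.
    """
    tt = np.asarray(t, dtype=float) - spec.onset_delay_s
    peak = spec.time_to_peak_s - spec.onset_delay_s
    theta = peak / (spec.shape - 1.0)
    h = np.zeros_like(tt)
    pos = tt > 0
    x = tt[pos]
    a1 = spec.shape
    g1 = np.exp(np.clip((a1 - 1) * np.log(x / peak) + (peak - x) / theta, -745, 0))
    a2 = 2 * spec.shape
    peak2 = (a2 - 1.0) * theta
    g2 = np.exp(np.clip((a2 - 1) * np.log(x / peak2) + (peak2 - x) / theta, -745, 0))
    h[pos] = g1 - spec.undershoot * g2
    m = h.max()
    return h / m if m > 0 else h


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable parameters of the multimodal generator."""

    eeg_rate: float = 512.0
    nirs_rate: float = 4.46
    effect_table: dict[tuple[str, str, str], float] = field(default_factory=default_effect_table)
    hrf: HRFSpec = field(default_factory=HRFSpec)
    cardiac_bpm: float | None = None  # None: drawn per subject from [45, 100]
    eeg_osc_amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "theta": 2.0, "alpha_low": 2.5, "alpha_high": 2.5,
            "beta_low": 1.2, "beta_high": 0.8,
        }
    )
    eeg_noise_sd: float = 1.0
    ramp_s: float = 0.5
    cardiac_od_amplitude: float = 0.005
    short_channel_cardiac_gain: float = 3.0
    cardiac_free_channels: tuple[str, ...] = ()
    nirs_noise_sd: float = 0.003
    nirs_drift_sd: float = 0.01  # 1/f baseline wander (OD units), dominates at low f
    baseline_intensity: dict[int, float] = field(default_factory=lambda: {760: 1.0, 850: 1.2})
    mbll: MBLLCoefficients = field(default_factory=MBLLCoefficients)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eeg_rate <= 0 or self.nirs_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        for key, effect in self.effect_table.items():
            if effect <= -1.0:
                raise ConfigurationError(f"effect {key} must be > -1 (got {effect})")
            if key[2] not in _BAND_ALIASES:
                raise ConfigurationError(f"unknown band {key[2]!r} in effect table")
        for w, b in self.baseline_intensity.items():
            if b <= 0:
                raise ConfigurationError(f"baseline intensity at {w} nm must be positive")
        if self.cardiac_bpm is not None and not (45 <= self.cardiac_bpm <= 100):
            raise ConfigurationError("cardiac_bpm must lie in [45, 100]")

    def resolve_cardiac_bpm(self, subject: int = 0) -> float:
        if self.cardiac_bpm is not None:
            return float(self.cardiac_bpm)
        return float(child_rng(self.seed, "cardiac", subject).uniform(45.0, 100.0))


@dataclass
class MultimodalSession:
    """One session's simulated recordings plus their generating truth."""

    session: int
    schedule: TrialSchedule      # view restricted to this session
    eeg: np.ndarray              # (n_samples, 62)
    eeg_rate: float
    nirs: np.ndarray             # (n_samples, 60, 2) intensities
    nirs_rate: float
    ground_truth: SimulationConfig
    cardiac_bpm: float
    true_concentration: np.ndarray | None = None  # (n_samples, 60, 2): HbO, HbR


def _ramp_profile(n: int, ramp_n: int) -> np.ndarray:
    r = np.ones(n)
    if ramp_n > 0 and n >= 2 * ramp_n:
        x = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        r[:ramp_n] = x
        r[-ramp_n:] = x[::-1]
    return r


def _pink_noise(rng: np.random.Generator, n: int, n_ch: int, sd: float) -> np.ndarray:
    white = rng.standard_normal((n, n_ch))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale[:, None], n=n, axis=0)
    pink *= sd / pink.std(axis=0, keepdims=True)
    return pink


def simulate_eeg(
    schedule: TrialSchedule,
    montage: MontageSpec,
    config: SimulationConfig,
    *,
    session: int | None = None,
    subject: int = 0,
) -> np.ndarray:
    """One session's EEG recording, (ceil(duration * rate), 62 channels).

    Band-limited oscillation variance in an affected (region, band) is scaled
    by (1 + effect) during task execution; elsewhere baseline statistics hold.
    """
    if session is None:
        sessions = schedule.sessions
        if len(sessions) != 1:
            raise ConfigurationError("pass session= for multi-session schedules")
        session = sessions[0]
    sched = schedule.session_view(session)
    rng = child_rng(config.seed, "eeg", subject, session)
    fs = config.eeg_rate
    n = int(math.ceil(sched.session_duration(session) * fs))
    t = np.arange(n) / fs
    out = _pink_noise(rng, n, len(montage.eeg_channels), config.eeg_noise_sd)

    trials = sched.absolute_trials(session)
    ch_index = {c: i for i, c in enumerate(montage.eeg_channels)}
    ramp_n = int(round(config.ramp_s * fs))
    task_n = int(round(sched.task_s * fs))

    for band, (lo, hi) in OSCILLATOR_BANDS.items():
        amp = config.eeg_osc_amplitudes.get(band, 0.0)
        if amp <= 0:
            continue
        bw = hi - lo
        freqs = rng.uniform(lo + 0.15 * bw, hi - 0.15 * bw, size=len(montage.eeg_channels))
        phases = rng.uniform(0, 2 * np.pi, size=len(montage.eeg_channels))
        gain = np.ones((n, len(montage.eeg_channels)), dtype=np.float32)
        for _, trial in trials.iterrows():
            for (task, region, key), effect in config.effect_table.items():
                if task != trial["task"] or band not in _BAND_ALIASES[key]:
                    continue
                idx = [ch_index[c] for c in montage.eeg_regions[region]]
                start = int(round(trial["onset_abs_s"] * fs))
                stop = min(n, start + task_n)
                profile = _ramp_profile(stop - start, ramp_n)
                factor = 1.0 + (math.sqrt(1.0 + effect) - 1.0) * profile
                gain[start:stop, idx] *= factor[:, None].astype(np.float32)
        out += gain * (amp * np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :]))
    return out


def _nirs_true_concentration(
    sched: TrialSchedule,
    montage: MontageSpec,
    config: SimulationConfig,
    session: int,
    t: np.ndarray,
) -> np.ndarray:
    """(n, 60 channels, 2): true Delta[HbO], Delta[HbR] in micromol/L."""
    conc = np.zeros((t.size, len(montage.nirs_channels), 2))
    ch_index = {c: i for i, c in enumerate(montage.nirs_channels)}
    chromo_index = {"HbO": 0, "HbR": 1}
    trials = sched.absolute_trials(session)
    for _, trial in trials.iterrows():
        h = None
        for (task, region, chromo), amp in config.hrf.amplitudes.items():
            if task != trial["task"]:
                continue
            if h is None:
                h = hrf_kernel(t - trial["onset_abs_s"], config.hrf)
            idx = [
                ch_index[c]
                for c in montage.region_map[region]
                if c not in montage.short_channels  # shorts see scalp, not cortex
            ]
            conc[:, idx, chromo_index[chromo]] += amp * h[:, None]
    return conc


def simulate_nirs(
    schedule: TrialSchedule,
    montage: MontageSpec,
    config: SimulationConfig,
    *,
    session: int | None = None,
    subject: int = 0,
    return_truth: bool = False,
):
    """One session's dual-wavelength NIRS intensities.

    Intensities are ``baseline * exp(-(forward-MBLL OD + cardiac + noise))``;
    concentration responses are task-locked with the configured onset delay
    and time-to-peak.  With ``return_truth`` the (intensities, true
    concentrations, cardiac bpm) triple is returned.
    """
    if session is None:
        sessions = schedule.sessions
        if len(sessions) != 1:
            raise ConfigurationError("pass session= for multi-session schedules")
        session = sessions[0]
    sched = schedule.session_view(session)
    rng = child_rng(config.seed, "nirs", subject, session)
    fs = config.nirs_rate
    n = int(math.ceil(sched.session_duration(session) * fs))
    t = np.arange(n) / fs

    conc = _nirs_true_concentration(sched, montage, config, session, t)
    m = config.mbll.matrix(WAVELENGTHS)
    od = conc @ m.T  # (n, channels, wavelengths)

    bpm = config.resolve_cardiac_bpm(subject)
    wave = np.sin(2 * np.pi * (bpm / 60.0) * t + rng.uniform(0, 2 * np.pi))
    amp = np.full(len(montage.nirs_channels), config.cardiac_od_amplitude)
    amp *= rng.uniform(0.9, 1.1, size=amp.size)
    for i, ch in enumerate(montage.nirs_channels):
        if ch in montage.short_channels:
            amp[i] *= config.short_channel_cardiac_gain
        if ch in config.cardiac_free_channels:
            amp[i] = 0.0
    od = od + wave[:, None, None] * amp[None, :, None]
    if config.nirs_drift_sd > 0:
        # slow instrumental/physiological baseline wander per channel-wavelength
        drift = _pink_noise(rng, n, od.shape[1] * od.shape[2], config.nirs_drift_sd)
        od = od + drift.reshape(od.shape)
    if config.nirs_noise_sd > 0:
        od = od + config.nirs_noise_sd * rng.standard_normal(od.shape)

    baseline = np.array([config.baseline_intensity[w] for w in WAVELENGTHS])
    intensities = baseline[None, None, :] * np.exp(-od)
    if return_truth:
        return intensities, conc, bpm
    return intensities


def simulate_session(
    schedule: TrialSchedule,
    montage: MontageSpec,
    config: SimulationConfig,
    session: int,
    *,
    subject: int = 0,
    keep_truth: bool = True,
) -> MultimodalSession:
    """Simulate both modalities for one session of a subject."""
    eeg = simulate_eeg(schedule, montage, config, session=session, subject=subject)
    nirs, conc, bpm = simulate_nirs(
        schedule, montage, config, session=session, subject=subject, return_truth=True
    )
    return MultimodalSession(
        session=session,
        schedule=schedule.session_view(session),
        eeg=eeg,
        eeg_rate=config.eeg_rate,
        nirs=nirs,
        nirs_rate=config.nirs_rate,
        ground_truth=config,
        cardiac_bpm=bpm,
        true_concentration=conc if keep_truth else None,
    )


def generate_subject(
    paradigm: ParadigmSpec,
    montage: MontageSpec,
    config: SimulationConfig,
    subject: int = 0,
) -> tuple[TrialSchedule, list[MultimodalSession]]:
    """Schedule plus simulated sessions for one subject (seeded per subject)."""
    schedule = generate_schedule(paradigm, child_seed(config.seed, "schedule", subject))
    sessions = [
        simulate_session(schedule, montage, config, s, subject=subject, keep_truth=False)
        for s in schedule.sessions
    ]
    return schedule, sessions


def generate_dataset(
    paradigm: ParadigmSpec,
    montage: MontageSpec,
    config: SimulationConfig,
    n_subjects: int,
    out_dir,
) -> list:
    """Write ``n_subjects`` simulated subject directories in the native
    fixture format (one directory per session).  Regeneration with the same
    configuration and seed is byte-identical."""
    from . import io as _io  # deferred: io imports this module's types

    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    paths = []
    for subject in range(n_subjects):
        schedule, sessions = generate_subject(paradigm, montage, config, subject)
        for sess in sessions:
            path = _io.write_session(
                out_dir, subject, sess, montage, schedule
            )
            paths.append(path)
            sess.eeg = None  # free memory as we go
            sess.nirs = None
    return paths
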