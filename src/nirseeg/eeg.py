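"""EEG pipeline: preprocessing, epoching, ERD/ERS maps, band-power features.

Preprocessing references to Cz, downsamples to 256 Hz, band-passes 0.5-100 Hz,
notches the 60 Hz line, and re-references to the channel average.  Epochs span
-5..+20 s around task onset with a -300..0 ms baseline correction.  ERD/ERS is
estimated with the intertrial-variance method: band-pass, subtract the
trial-averaged evoked component, take the across-trial variance IV(t), and
express the analysis-window variance as a percent change from a pre-onset
reference.  Features are log band powers (and two band-power ratios) per
channel in non-overlapping 1 s windows: 62 channels x 10 subtypes = 620
features per window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigurationError
from .features import WindowedFeatureMatrix
from .paradigm import TrialSchedule

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "DEFAULT_RATIOS",
    "BETA_TOTAL",
    "EpochSet",
    "preprocess_eeg",
    "epoch_eeg",
    "epoch_session",
    "compute_erd_ers",
    "erd_map",
    "extract_eeg_features",
]

log = logging.getLogger(__name__)

LOG_POWER_FLOOR = 1e-12  # floor for degenerate (all-zero) window powers


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ConfigurationError(f"band {self.name}: need 0 <= lo < hi")


#: The emitted per-channel bands (8) — theta through total spectrum.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha_low", 8.0, 10.0),
    BandDefinition("alpha_high", 10.0, 12.0),
    BandDefinition("alpha_total", 8.0, 12.0),
    BandDefinition("beta_low", 12.0, 21.0),
    BandDefinition("beta_high", 21.0, 30.0),
    BandDefinition("broad", 4.0, 30.0),
    BandDefinition("total", 0.1, 100.0),
)

BETA_TOTAL = BandDefinition("beta_total", 12.0, 30.0)

#: Ratio features computed on linear powers: (name, numerator, denominator).
DEFAULT_RATIOS: tuple[tuple[str, str, str], ...] = (
    ("alpha_total/beta_total", "alpha_total", "beta_total"),
    ("theta/beta_total", "theta", "beta_total"),
)


@dataclass
class EpochSet:
    """Epoch x channel x time array with task labels and a shared time axis."""

    data: np.ndarray          # (n_epochs, n_channels, n_times)
    times: np.ndarray         # seconds relative to task onset
    labels: np.ndarray        # task per epoch
    rate: float
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.shape[0] != len(self.labels):
            raise ConfigurationError("one label per epoch required")
        if self.data.shape[1] != len(self.channels):
            raise ConfigurationError("channel axis does not match channel labels")
        if self.data.shape[2] != len(self.times):
            raise ConfigurationError("time axis does not match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def task_epochs(self, task: str) -> np.ndarray:
        return self.data[self.labels.astype(str) == task]

    @classmethod
    def concatenate(cls, parts: list["EpochSet"]) -> "EpochSet":
        first = parts[0]
        for p in parts[1:]:
            if p.channels != first.channels or p.rate != first.rate or len(p.times) != len(first.times):
                raise ConfigurationError("epoch sets are not concatenable")
        return cls(
            np.concatenate([p.data for p in parts], axis=0),
            first.times.copy(),
            np.concatenate([p.labels for p in parts]),
            first.rate,
            first.channels,
        )


def _bandpass_sos(lo: float, hi: float, rate: float, order: int = 4) -> np.ndarray:
    nyq = rate / 2.0
    return signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def preprocess_eeg(
    data: np.ndarray,
    rate: float,
    channels: tuple[str, ...],
    *,
    target_rate: float = 256.0,
    band: tuple[float, float] = (0.5, 100.0),
    notch: tuple[float, float] = (58.0, 62.0),
    reference: str | None = "Cz",
) -> tuple[np.ndarray, float]:
    """Reference, downsample to 256 Hz, band-pass, notch, average-reference.

    ``data`` is (n_samples, n_channels).  Returns the cleaned signal and its
    new sampling rate.  Filters are zero-phase (forward-backward) IIR.
    """
    data = np.asarray(data, dtype=float)
    if rate < target_rate:
        raise ConfigurationError(f"input rate {rate} Hz below target {target_rate} Hz")
    if data.ndim != 2 or data.shape[1] != len(channels):
        raise ConfigurationError("data must be (n_samples, n_channels)")
    if reference is not None:
        if reference not in channels:
            raise ConfigurationError(f"reference channel {reference!r} not in montage")
        data = data - data[:, [channels.index(reference)]]
    frac = Fraction(target_rate / rate).limit_denominator(1000)
    if frac != 1:
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=0)
    sos = _bandpass_sos(band[0], band[1], target_rate)
    data = signal.sosfiltfilt(sos, data, axis=0)
    if notch is not None:
        nyq = target_rate / 2.0
        sos_n = signal.butter(4, [notch[0] / nyq, notch[1] / nyq], btype="bandstop", output="sos")
        data = signal.sosfiltfilt(sos_n, data, axis=0)
    # common-average re-reference
    data = data - data.mean(axis=1, keepdims=True)
    return np.ascontiguousarray(data), float(target_rate)


def epoch_eeg(
    data: np.ndarray,
    rate: float,
    onsets_s: np.ndarray,
    labels: np.ndarray,
    channels: tuple[str, ...],
    *,
    tmin: float = -5.0,
    tmax: float = 20.0,
    baseline: tuple[float, float] | None = (-0.3, 0.0),
) -> EpochSet:
    """Cut epochs around task onsets and apply baseline correction.

    Each epoch covers [tmin, tmax) s around its onset; the per-channel mean
    over the baseline interval is subtracted.  Trials whose epoch extends past
    either end of the signal are dropped with a logged warning.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    n_times = int(round((tmax - tmin) * rate))
    times = tmin + np.arange(n_times) / rate
    epochs, kept_labels = [], []
    for onset, label in zip(np.asarray(onsets_s, dtype=float), labels):
        start = int(round((onset + tmin) * rate))
        stop = start + n_times
        if start < 0 or stop > n:
            log.warning("dropping trial at %.1f s: epoch exceeds signal bounds", onset)
            continue
        epochs.append(data[start:stop].T)  # (channels, times)
        kept_labels.append(label)
    if not epochs:
        raise ConfigurationError("no trial fits within the signal span")
    arr = np.stack(epochs)
    if baseline is not None:
        mask = (times >= baseline[0]) & (times < baseline[1])
        arr = arr - arr[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(arr, times, np.asarray(kept_labels, dtype=object), rate, tuple(channels))


def epoch_session(
    data: np.ndarray,
    rate: float,
    schedule: TrialSchedule,
    session: int,
    channels: tuple[str, ...],
    **kwargs,
) -> EpochSet:
    """Epoch one session's recording using the schedule's absolute onsets."""
    trials = schedule.absolute_trials(session)
    return epoch_eeg(
        data, rate, trials["onset_abs_s"].to_numpy(), trials["task"].to_numpy(),
        channels, **kwargs,
    )


def _intertrial_variance(band_data: np.ndarray) -> np.ndarray:
    """IV(t) per channel: across-trial variance after removing the evoked mean."""
    resid = band_data - band_data.mean(axis=0, keepdims=True)
    return (resid**2).sum(axis=0) / (band_data.shape[0] - 1)


def erd_from_iv(
    iv: np.ndarray,
    times: np.ndarray,
    ref: tuple[float, float],
    analysis: tuple[float, float],
) -> np.ndarray:
    """ERD/ERS percent from an intertrial-variance time course.

    ERD% = 100 * (mean IV over the analysis window - mean IV over the
    reference window) / (mean IV over the reference window).  Negative values
    are desynchronization (power loss), positive synchronization.
    """
    ref_mask = (times >= ref[0]) & (times < ref[1])
    ana_mask = (times >= analysis[0]) & (times < analysis[1])
    iv_ref = iv[..., ref_mask].mean(axis=-1)
    iv_ana = iv[..., ana_mask].mean(axis=-1)
    return 100.0 * (iv_ana - iv_ref) / iv_ref


def compute_erd_ers(
    epochs: EpochSet,
    band: BandDefinition,
    task: str,
    *,
    ref: tuple[float, float] = (-2.0, 0.0),
    analysis: tuple[float, float] = (0.5, 2.0),
) -> pd.Series:
    """Per-channel ERD/ERS percent for one task and band.

    Requires at least two epochs of the task (the across-trial variance is
    undefined otherwise).  The reference window must precede task onset.
    """
    sel = epochs.task_epochs(task)
    if sel.shape[0] < 2:
        raise ConfigurationError(f"need >= 2 epochs of task {task!r} for ERD")
    if ref[1] > 0:
        raise ConfigurationError("reference window must precede task onset")
    sos = _bandpass_sos(band.lo, max(band.lo + 1e-9, band.hi), epochs.rate)
    band_data = signal.sosfiltfilt(sos, sel, axis=2)
    iv = _intertrial_variance(band_data)
    values = erd_from_iv(iv, epochs.times, ref, analysis)
    return pd.Series(values, index=list(epochs.channels), name=f"{task}:{band.name}")


def erd_map(
    epochs: EpochSet,
    task: str,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS[:6],
    **kwargs,
) -> pd.DataFrame:
    """Channel x band ERD/ERS map for one task."""
    cols = {b.name: compute_erd_ers(epochs, b, task, **kwargs) for b in bands}
    return pd.DataFrame(cols)


def _band_power_matrix(
    seg: np.ndarray, rate: float, bands: tuple[BandDefinition, ...]
) -> np.ndarray:
    """Periodogram band powers for (epochs, channels, n) windows.

    A single unwindowed DFT per window; power = squared magnitude summed over
    the bins whose centre frequency falls in [lo, hi).
    """
    n = seg.shape[-1]
    spec = np.fft.rfft(seg, axis=-1)
    power = (spec.real**2 + spec.imag**2) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    out = np.empty(seg.shape[:-1] + (len(bands),))
    for i, b in enumerate(bands):
        mask = (freqs >= b.lo) & (freqs < b.hi)
        out[..., i] = power[..., mask].sum(axis=-1)
    return out


def extract_eeg_features(
    epochs: EpochSet,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    ratios: tuple[tuple[str, str, str], ...] = DEFAULT_RATIOS,
) -> WindowedFeatureMatrix:
    """Log band-power features in non-overlapping 1 s windows.

    Per channel and window: the powers of each band in ``bands`` plus the
    ratio features (computed on linear powers), all natural-log transformed.
    With the default 8 bands and 2 ratios on 62 channels this yields 620
    features per window.
    """
    if epochs.rate < 200:
        raise ConfigurationError("epoch rate must be >= 200 Hz for the 100 Hz band edge")
    n_per_win = int(round(epochs.rate))
    n_windows = int(np.floor(epochs.data.shape[2] / n_per_win))
    window_starts = epochs.times[0] + np.arange(n_windows)
    seg = epochs.data[:, :, : n_windows * n_per_win]
    seg = seg.reshape(epochs.n_epochs, len(epochs.channels), n_windows, n_per_win)

    all_bands = tuple(bands) + (BETA_TOTAL,)
    powers = _band_power_matrix(seg, epochs.rate, all_bands)
    name_to_idx = {b.name: i for i, b in enumerate(all_bands)}

    n_emit = len(bands) + len(ratios)
    feats = np.empty((epochs.n_epochs, len(epochs.channels), n_windows, n_emit))
    feats[..., : len(bands)] = powers[..., : len(bands)]
    for j, (_, num, den) in enumerate(ratios):
        with np.errstate(divide="ignore", invalid="ignore"):
            feats[..., len(bands) + j] = (
                powers[..., name_to_idx[num]] / powers[..., name_to_idx[den]]
            )
    feats = np.log(np.maximum(feats, LOG_POWER_FLOOR))

    # (epochs, channels, windows, subtype) -> (epochs, windows, channel-major features)
    feats = feats.transpose(0, 2, 1, 3).reshape(epochs.n_epochs, n_windows, -1)
    subtypes = [b.name for b in bands] + [name for name, _, _ in ratios]
    meta = pd.DataFrame(
        [("EEG", ch, st) for ch in epochs.channels for st in subtypes],
        columns=["modality", "channel", "subtype"],
    )
    return WindowedFeatureMatrix(feats, window_starts, meta, epochs.labels.copy())
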