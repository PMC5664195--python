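"""fNIRS pipeline: optical density, cardiac channel QC, MBLL, regional
channels, windowed concentration features.

Raw dual-wavelength (760/850 nm) intensities are converted to optical density
OD(t) = -ln(I(t)/mean I).  Channel quality control exploits the cardiac pulse:
the OD of each long channel, band-passed 0.8-1.2 Hz, is correlated per epoch
with the same-side short channels (small source-detector separation, scalp
dominated, hence a clean heartbeat); per-epoch Pearson p-values are aggregated
with Fisher's method and channels whose aggregate p is not significant are
rejected for the session.  Retained OD is band-passed 0.01-0.30 Hz and
inverted through the Modified Beer-Lambert Law,

    dOD(lambda) = [eps_HbO(lambda) d[HbO] + eps_HbR(lambda) d[HbR]] * d * DPF(lambda),

to oxy/deoxy-hemoglobin concentration changes (micromol/L); total hemoglobin
is their sum.  Thirteen regional channels (averages over retained neighbours)
extend 60 channels to 73; mean concentrations per 1 s window give
73 x 3 = 219 features, with rejected channels' features set to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import ConfigurationError
from .features import WindowedFeatureMatrix
from .montage import MontageSpec

__all__ = [
    "WAVELENGTHS",
    "CHROMOPHORES",
    "ODSeries",
    "ChannelQCReport",
    "MBLLCoefficients",
    "HemoSeries",
    "intensities_to_od",
    "qc_cardiac_channels",
    "od_to_hemoglobin",
    "add_regional_channels",
    "extract_nirs_features",
    "average_response_map",
]

WAVELENGTHS: tuple[int, int] = (760, 850)
CHROMOPHORES: tuple[str, str, str] = ("HbO", "HbR", "HbT")


@dataclass
class ODSeries:
    """Optical densities: (n_samples, n_channels, n_wavelengths) at ``rate`` Hz."""

    data: np.ndarray
    channels: tuple[str, ...]
    rate: float
    wavelengths: tuple[int, int] = WAVELENGTHS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != len(self.channels) \
                or self.data.shape[2] != len(self.wavelengths):
            raise ConfigurationError("OD data must be (samples, channels, wavelengths)")


@dataclass
class ChannelQCReport:
    """Per-channel aggregate cardiac-correlation p-values and retention flags."""

    table: pd.DataFrame  # columns: channel, aggregate_p, retained, is_short
    alpha: float = 0.05
    band: tuple[float, float] = (0.8, 1.2)

    def retained_mask(self, channels: tuple[str, ...]) -> np.ndarray:
        flags = self.table.set_index("channel")["retained"]
        return np.asarray([bool(flags.get(c, True)) for c in channels])


# Hemoglobin extinction coefficients in L / (micromol cm), natural-log
# convention, scaled from a standard published table at 760/850 nm.
DEFAULT_EXTINCTION: dict[int, dict[str, float]] = {
    760: {"HbO": 5.86e-4, "HbR": 1.5485e-3},
    850: {"HbO": 1.058e-3, "HbR": 6.9132e-4},
}


@dataclass(frozen=True)
class MBLLCoefficients:
    """Extinction coefficients, pathlength factors and optode separation."""

    extinction: dict[int, dict[str, float]] = field(
        default_factory=lambda: {w: dict(v) for w, v in DEFAULT_EXTINCTION.items()}
    )
    dpf: dict[int, float] = field(default_factory=lambda: {760: 6.0, 850: 6.0})
    distance_cm: float = 3.0

    def matrix(self, wavelengths: tuple[int, int] = WAVELENGTHS) -> np.ndarray:
        """The 2x2 system mapping (dHbO, dHbR) to (dOD_760, dOD_850)."""
        m = np.array(
            [
                [
                    self.extinction[w]["HbO"] * self.distance_cm * self.dpf[w],
                    self.extinction[w]["HbR"] * self.distance_cm * self.dpf[w],
                ]
                for w in wavelengths
            ]
        )
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
            raise ConfigurationError("MBLL coefficient matrix is singular")
        return m


@dataclass
class HemoSeries:
    """Concentration changes: (n_samples, n_channels, 3 chromophores), micromol/L."""

    data: np.ndarray
    channels: tuple[str, ...]
    rate: float
    retained: np.ndarray  # QC mask per channel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[2] != len(CHROMOPHORES):
            raise ConfigurationError("hemo data must be (samples, channels, 3)")
        if self.data.shape[1] != len(self.channels) or len(self.retained) != len(self.channels):
            raise ConfigurationError("channel axis mismatch")


def intensities_to_od(
    intensities: np.ndarray, channels: tuple[str, ...], rate: float
) -> ODSeries:
    """OD(t) = -ln(I(t) / mean I) per channel and wavelength.

    Raises on any non-positive intensity sample, naming the offending channel.
    """
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities <= 0):
        idx = np.argwhere(intensities <= 0)[0]
        raise ConfigurationError(
            f"non-positive intensity at sample {idx[0]}, channel {channels[idx[1]]}"
        )
    mean = intensities.mean(axis=0, keepdims=True)
    return ODSeries(-np.log(intensities / mean), tuple(channels), rate)


def _bandpass(data: np.ndarray, rate: float, lo: float, hi: float, order: int = 3) -> np.ndarray:
    nyq = rate / 2.0
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, data, axis=0)


def _autocorrelations(x: np.ndarray, n_lags: int) -> np.ndarray:
    x = x - x.mean()
    v = float(x @ x)
    if v == 0:
        return np.zeros(n_lags)
    return np.array([float(x[:-k] @ x[k:]) / v for k in range(1, n_lags + 1)])


def _corr_pvalue_autocorrected(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed Pearson-correlation p-value with an effective-sample-size
    correction for serial dependence.

    Narrow band-pass filtering makes samples strongly autocorrelated, so the
    naive i.i.d. p-value is wildly anticonservative.  The Bartlett-type
    correction replaces n with n_eff = n / (1 + 2 sum_k (1 - k/n) rho_x(k)
    rho_y(k)), keeping the null test approximately calibrated.
    """
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    n_lags = max(1, min(n - 3, n // 3))
    rho = _autocorrelations(x, n_lags) * _autocorrelations(y, n_lags)
    k = np.arange(1, n_lags + 1)
    denom = 1.0 + 2.0 * float(np.sum((1.0 - k / n) * rho))
    n_eff = float(np.clip(n / max(denom, 1e-12), 5.0, n))
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n_eff - 2.0) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n_eff - 2.0))


def qc_cardiac_channels(
    od: ODSeries,
    montage: MontageSpec,
    onsets_s: np.ndarray,
    *,
    band: tuple[float, float] = (0.8, 1.2),
    alpha: float = 0.05,
    epoch_span: tuple[float, float] = (-5.0, 20.0),
    wavelength: int = 760,
) -> ChannelQCReport:
    """Cardiac-correlation channel rejection.

    For every trial epoch, each channel's QC-band OD is Pearson-correlated
    with each same-side short channel's; the smaller of the two p-values is
    kept, and the per-epoch p-values are aggregated across epochs with
    Fisher's method.  A channel is retained iff its aggregate p < ``alpha``.
    Short channels are always retained.  Midline channels are tested against
    all four short channels.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    if onsets.size < 1:
        raise ConfigurationError("QC needs at least one epoch")
    w_idx = od.wavelengths.index(wavelength)
    filt = _bandpass(od.data[:, :, w_idx], od.rate, band[0], band[1])
    ch_index = {c: i for i, c in enumerate(od.channels)}
    n = filt.shape[0]

    rows = []
    for ch in od.channels:
        is_short = ch in montage.short_channels
        if is_short:
            rows.append((ch, 0.0, True, True))
            continue
        refs = [ch_index[r] for r in montage.side_short_channels(ch)]
        p_values = []
        for onset in onsets:
            start = max(0, int(round((onset + epoch_span[0]) * od.rate)))
            stop = min(n, int(round((onset + epoch_span[1]) * od.rate)))
            x = filt[start:stop, ch_index[ch]]
            if x.size < 3 or np.ptp(x) == 0:
                continue  # zero-variance segment: skip this epoch
            best = None
            for r in refs:
                y = filt[start:stop, r]
                if np.ptp(y) == 0:
                    continue
                p = _corr_pvalue_autocorrected(x, y)
                best = p if best is None else min(best, p)
            if best is not None:
                p_values.append(best)
        if not p_values:
            rows.append((ch, 1.0, False, False))
            continue
        agg = stats.combine_pvalues(np.clip(p_values, 1e-300, 1.0), method="fisher").pvalue
        rows.append((ch, float(agg), bool(agg < alpha), False))

    table = pd.DataFrame(rows, columns=["channel", "aggregate_p", "retained", "is_short"])
    return ChannelQCReport(table, alpha=alpha, band=band)


def od_to_hemoglobin(
    od: ODSeries,
    coeffs: MBLLCoefficients | None = None,
    *,
    hp_lp: tuple[float, float] | None = (0.01, 0.30),
    retained: np.ndarray | None = None,
) -> HemoSeries:
    """Band-pass the OD and invert the MBLL to chromophore concentrations.

    ``hp_lp=None`` disables the hemodynamic band-pass (used for exact
    forward/inverse checks).  The returned series has 3 chromophores per
    channel with HbT = HbO + HbR at every sample.
    """
    coeffs = coeffs or MBLLCoefficients()
    m = coeffs.matrix(od.wavelengths)
    data = od.data
    if hp_lp is not None:
        data = _bandpass(data.reshape(data.shape[0], -1), od.rate, hp_lp[0], hp_lp[1], order=3)
        data = data.reshape(od.data.shape)
    # solve the 2x2 system for every (sample, channel)
    conc = np.linalg.solve(m[None, None, :, :], data[..., None])[..., 0]
    out = np.empty(conc.shape[:2] + (3,))
    out[..., 0] = conc[..., 0]
    out[..., 1] = conc[..., 1]
    out[..., 2] = conc[..., 0] + conc[..., 1]
    if retained is None:
        retained = np.ones(len(od.channels), dtype=bool)
    return HemoSeries(out, od.channels, od.rate, retained)


def add_regional_channels(
    hemo: HemoSeries, region_map: dict[str, tuple[str, ...]]
) -> HemoSeries:
    """Append one averaged channel per region (13 regions -> 73 channels).

    Regional amplitudes are the mean over the region's *retained* member
    channels per chromophore; a region whose members are all rejected yields a
    zero regional series marked rejected.
    """
    ch_index = {c: i for i, c in enumerate(hemo.channels)}
    extra, names, flags = [], [], []
    for region, members in region_map.items():
        idx = []
        for mch in members:
            if mch not in ch_index:
                raise ConfigurationError(f"region {region!r}: unknown channel {mch!r}")
            if hemo.retained[ch_index[mch]]:
                idx.append(ch_index[mch])
        if idx:
            extra.append(hemo.data[:, idx, :].mean(axis=1))
            flags.append(True)
        else:
            extra.append(np.zeros((hemo.data.shape[0], 3)))
            flags.append(False)
        names.append(region)
    data = np.concatenate([hemo.data, np.stack(extra, axis=1)], axis=1)
    retained = np.concatenate([hemo.retained, np.asarray(flags)])
    return HemoSeries(data, tuple(hemo.channels) + tuple(names), hemo.rate, retained)


def _epoch_hemo(
    hemo: HemoSeries, onsets_s: np.ndarray, span: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Sample times (relative to onset) and per-epoch index slabs.

    Returns (rel_times, index array (n_epochs, n_times)); epochs extending
    past the recording are dropped.
    """
    n = hemo.data.shape[0]
    t = np.arange(n) / hemo.rate
    rows = []
    for onset in np.asarray(onsets_s, dtype=float):
        mask = (t >= onset + span[0]) & (t < onset + span[1])
        rows.append(np.flatnonzero(mask))
    lengths = {len(r) for r in rows}
    n_keep = min(lengths)
    idx = np.stack([r[:n_keep] for r in rows])
    rel = t[idx[0]] - float(onsets_s[0])
    return rel, idx


def extract_nirs_features(
    hemo: HemoSeries,
    onsets_s: np.ndarray,
    labels: np.ndarray,
    *,
    span: tuple[float, float] = (-5.0, 20.0),
) -> WindowedFeatureMatrix:
    """Mean concentration per (channel, chromophore) in 1 s epoch windows.

    Windows are the same non-overlapping 1 s grid as the EEG features.  All
    features of QC-rejected channels are set to 0, preserving the fixed
    channel x chromophore feature layout (73 x 3 = 219 on the default
    montage with regional channels).
    """
    rel, idx = _epoch_hemo(hemo, onsets_s, span)
    n_windows = int(np.floor(span[1] - span[0]))
    window_starts = span[0] + np.arange(n_windows)
    epoch_data = hemo.data[idx]  # (n_epochs, n_times, n_channels, 3)
    win_of_sample = np.floor(rel - span[0]).astype(int)

    n_ep, _, n_ch, _ = epoch_data.shape
    values = np.empty((n_ep, n_windows, n_ch, 3))
    for w in range(n_windows):
        mask = win_of_sample == w
        if not mask.any():
            raise ConfigurationError(f"window starting {window_starts[w]} s holds no sample")
        values[:, w] = epoch_data[:, mask].mean(axis=1)
    values[:, :, ~hemo.retained, :] = 0.0
    values = values.reshape(n_ep, n_windows, n_ch * 3)

    meta = pd.DataFrame(
        [("NIRS", ch, chromo) for ch in hemo.channels for chromo in CHROMOPHORES],
        columns=["modality", "channel", "subtype"],
    )
    return WindowedFeatureMatrix(values, window_starts, meta, np.asarray(labels, dtype=object))


def average_response_map(
    hemo: HemoSeries,
    onsets_s: np.ndarray,
    labels: np.ndarray,
    task: str,
    *,
    window: tuple[float, float] = (10.0, 15.0),
    baseline: tuple[float, float] = (-5.0, 0.0),
    span: tuple[float, float] = (-5.0, 20.0),
) -> pd.DataFrame:
    """Grand-mean response per (channel, chromophore) for one task.

    Each epoch is baseline-normalized (mean over the pre-onset baseline
    subtracted), then averaged over trials and over the response window
    (default 10-15 s after onset).
    """
    labels = np.asarray(labels, dtype=object)
    sel = labels.astype(str) == task
    if not sel.any():
        raise ConfigurationError(f"no epochs of task {task!r}")
    rel, idx = _epoch_hemo(hemo, np.asarray(onsets_s, dtype=float)[sel], span)
    epoch_data = hemo.data[idx]
    base_mask = (rel >= baseline[0]) & (rel < baseline[1])
    win_mask = (rel >= window[0]) & (rel < window[1])
    normalized = epoch_data - epoch_data[:, base_mask].mean(axis=1, keepdims=True)
    grand = normalized[:, win_mask].mean(axis=(0, 1))  # (channels, 3)
    return pd.DataFrame(grand, index=list(hemo.channels), columns=list(CHROMOPHORES))
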