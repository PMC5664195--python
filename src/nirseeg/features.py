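"""Windowed feature matrices and modality fusion.

Every feature pipeline (EEG band powers, NIRS mean concentrations) emits a
:class:`WindowedFeatureMatrix`: an epoch x window x feature array over the
shared grid of non-overlapping 1 s windows spanning the -5..+20 s epoch,
with per-feature metadata (modality, channel, subtype) and per-epoch task
labels.  Fusion is concatenation along the feature axis over identical epoch
and window axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError

__all__ = ["WindowedFeatureMatrix", "fuse_feature_sets"]

META_COLUMNS = ("modality", "channel", "subtype")


@dataclass
class WindowedFeatureMatrix:
    """Features per (epoch, 1 s window, feature) with metadata and labels."""

    values: np.ndarray            # (n_epochs, n_windows, n_features)
    window_starts: np.ndarray     # window start seconds relative to task onset
    meta: pd.DataFrame            # columns: modality, channel, subtype
    labels: np.ndarray            # task label per epoch

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 3:
            raise AlignmentError("values must be (epochs, windows, features)")
        n_ep, n_win, n_feat = self.values.shape
        if len(self.window_starts) != n_win:
            raise AlignmentError("window axis and window_starts length differ")
        if len(self.meta) != n_feat:
            raise AlignmentError("feature metadata length must equal feature count")
        if len(self.labels) != n_ep:
            raise AlignmentError("one label per epoch required")
        if not all(c in self.meta.columns for c in META_COLUMNS):
            raise AlignmentError(f"metadata must have columns {META_COLUMNS}")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    @property
    def feature_names(self) -> list[str]:
        return [f"{c}|{s}" for c, s in zip(self.meta["channel"], self.meta["subtype"])]

    def window_index(self, start_s: float) -> int:
        hits = np.flatnonzero(np.isclose(self.window_starts, start_s))
        if hits.size != 1:
            raise AlignmentError(f"no unique window starting at {start_s} s")
        return int(hits[0])

    def select_epochs(self, mask: np.ndarray) -> "WindowedFeatureMatrix":
        mask = np.asarray(mask)
        return WindowedFeatureMatrix(
            self.values[mask], self.window_starts.copy(), self.meta.copy(), self.labels[mask]
        )

    def select_pair(self, pair: tuple[str, str]) -> "WindowedFeatureMatrix":
        """Epochs belonging to either task of a pair."""
        mask = np.isin(self.labels.astype(str), list(pair))
        return self.select_epochs(mask)

    @classmethod
    def concatenate(cls, parts: list["WindowedFeatureMatrix"]) -> "WindowedFeatureMatrix":
        """Stack feature sets along the epoch axis (e.g. across sessions)."""
        first = parts[0]
        for p in parts[1:]:
            if not np.allclose(p.window_starts, first.window_starts):
                raise AlignmentError("window grids differ")
            if p.n_features != first.n_features:
                raise AlignmentError("feature spaces differ")
        return cls(
            np.concatenate([p.values for p in parts], axis=0),
            first.window_starts.copy(),
            first.meta.copy(),
            np.concatenate([p.labels for p in parts]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long layout: rows = epoch x window, columns = '<channel>|<subtype>'."""
        n_ep, n_win, n_feat = self.values.shape
        idx = pd.MultiIndex.from_product(
            [range(n_ep), self.window_starts], names=["epoch", "window_start_s"]
        )
        return pd.DataFrame(self.values.reshape(n_ep * n_win, n_feat), index=idx,
                            columns=self.feature_names)


def fuse_feature_sets(
    eeg: WindowedFeatureMatrix, nirs: WindowedFeatureMatrix
) -> WindowedFeatureMatrix:
    """Concatenate two modality feature sets along the feature axis.

    Requires identical epoch counts, labels and window grids; metadata is
    preserved so the fused matrix partitions back into its modalities.
    """
    if eeg.n_epochs != nirs.n_epochs:
        raise AlignmentError(
            f"epoch counts differ: {eeg.n_epochs} vs {nirs.n_epochs}"
        )
    if not np.array_equal(eeg.labels.astype(str), nirs.labels.astype(str)):
        raise AlignmentError("epoch labels differ between modalities")
    if eeg.n_windows != nirs.n_windows or not np.allclose(
        eeg.window_starts, nirs.window_starts
    ):
        raise AlignmentError("window grids differ between modalities")
    values = np.concatenate([eeg.values, nirs.values], axis=2)
    meta = pd.concat([eeg.meta, nirs.meta], ignore_index=True)
    return WindowedFeatureMatrix(values, eeg.window_starts.copy(), meta, eeg.labels.copy())
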