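"""Sensor montage: 62 EEG electrodes plus a 60-channel dual-wavelength
fNIRS array with 4 short source-detector pairs and 13 named regions.

The EEG layout is a 64-electrode 10-10 arrangement without AF7/AF8 (their cap
positions hold NIRS optodes).  NIRS channels are (source, detector) pairs at
~3 cm separation; the four frontal short channels (S15-D1, S15-D2 on the left
and S16-D13, S16-D14 on the right) carry a clean cardiac pulse and anchor the
channel quality control.  Thirteen regional channels — averages of
neighbouring long channels — extend the 60 measured channels to 73.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigurationError

__all__ = [
    "EEG_CHANNELS",
    "EEG_REGIONS",
    "SHORT_CHANNELS",
    "MontageSpec",
    "default_montage",
]

# 10-10 layout (64 positions) without AF7/AF8.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3",
    "P5", "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz",
    "CPz", "Fpz", "Fp2", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8",
    "FT8", "FC6", "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8",
    "TP8", "CP6", "CP4", "CP2", "P2", "P4", "P6", "P8", "P10", "PO8",
    "PO4", "O2",
)

# Scalp regions used to place simulated task effects (ERD/ERS) on EEG.
EEG_REGIONS: dict[str, tuple[str, ...]] = {
    "occipital": ("O1", "Oz", "O2", "PO7", "PO3", "POz", "PO4", "PO8", "Iz"),
    "left_motor": ("C1", "C3", "C5", "FC3", "CP3"),
    "right_motor": ("C2", "C4", "C6", "FC4", "CP4"),
    "left_temporal": ("T7", "FT7", "TP7", "CP5"),
    "right_temporal": ("T8", "FT8", "TP8", "CP6"),
    "frontal": ("Fp1", "Fpz", "Fp2", "AF3", "AFz", "AF4", "F1", "Fz", "F2"),
    "left_parietal": ("P1", "P3", "P5", "P7"),
    "right_parietal": ("P2", "P4", "P6", "P8"),
    "central_midline": ("FCz", "Cz", "CPz"),
}

SHORT_CHANNELS: tuple[str, ...] = ("S15-D1", "S15-D2", "S16-D13", "S16-D14")


@dataclass(frozen=True)
class MontageSpec:
    """EEG channel labels plus the NIRS channel/region geometry."""

    eeg_channels: tuple[str, ...]
    nirs_channels: tuple[str, ...]
    hemisphere: dict[str, str]            # nirs channel -> left | right | midline
    short_channels: tuple[str, ...]
    region_map: dict[str, tuple[str, ...]]  # 13 regions -> member nirs channels
    eeg_regions: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(EEG_REGIONS))
    distance_cm: float = 3.0

    def __post_init__(self) -> None:
        if len(set(self.eeg_channels)) != len(self.eeg_channels):
            raise ConfigurationError("duplicate EEG channel labels")
        if len(set(self.nirs_channels)) != len(self.nirs_channels):
            raise ConfigurationError("duplicate NIRS channel labels")
        missing = set(self.short_channels) - set(self.nirs_channels)
        if missing:
            raise ConfigurationError(f"short channels not in montage: {sorted(missing)}")
        for region, members in self.region_map.items():
            if not members:
                raise ConfigurationError(f"region {region!r} is empty")
            unknown = set(members) - set(self.nirs_channels)
            if unknown:
                raise ConfigurationError(f"region {region!r} has unknown members {sorted(unknown)}")
        unknown = set(self.hemisphere) ^ set(self.nirs_channels)
        if unknown:
            raise ConfigurationError("hemisphere map must cover exactly the NIRS channels")
        if self.distance_cm <= 0:
            raise ConfigurationError("source-detector distance must be positive")

    @property
    def long_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.nirs_channels if c not in self.short_channels)

    def side_short_channels(self, channel: str) -> tuple[str, ...]:
        """Reference short channels for a channel's QC: same side, or all four
        for midline channels."""
        side = self.hemisphere[channel]
        if side == "midline":
            return self.short_channels
        return tuple(c for c in self.short_channels if self.hemisphere[c] == side)


def _nirs_layout() -> tuple[list[str], dict[str, str]]:
    """60 source-detector pairs: 28 long per hemisphere + 4 frontal shorts."""
    channels: list[str] = []
    hemi: dict[str, str] = {}
    for side, src0, det0 in (("left", 1, 1), ("right", 8, 13)):
        for i in range(7):  # 7 long-channel sources per side
            src = src0 + i
            for k in range(4):
                det = det0 + (2 * i + k) % 12
                name = f"S{src}-D{det}"
                channels.append(name)
                hemi[name] = side
    for name in SHORT_CHANNELS:
        channels.append(name)
        hemi[name] = "left" if name.startswith("S15") else "right"
    return channels, hemi


def _nirs_regions(channels: list[str], hemi: dict[str, str]) -> dict[str, tuple[str, ...]]:
    """13 named regions: 6 per hemisphere plus one midline frontal region."""
    region_names = (
        "prefrontal", "lateral_frontal", "centrofrontal",
        "central", "temporoparietal", "parietal",
    )
    regions: dict[str, tuple[str, ...]] = {}
    for side in ("left", "right"):
        longs = [c for c in channels if hemi[c] == side and c not in SHORT_CHANNELS]
        shorts = [c for c in channels if hemi[c] == side and c in SHORT_CHANNELS]
        # 28 long channels per side -> chunks of 3,5,5,5,5,5 across the 6 regions;
        # the prefrontal region additionally contains the side's 2 short channels.
        sizes = (3, 5, 5, 5, 5, 5)
        idx = 0
        for name, size in zip(region_names, sizes):
            members = longs[idx:idx + size]
            if name == "prefrontal":
                members = shorts + members
            regions[f"{name}_{side}"] = tuple(members)
            idx += size
    regions["centrofrontal_mid"] = regions["centrofrontal_left"] + regions["centrofrontal_right"]
    return regions


def default_montage() -> MontageSpec:
    """The standard 62-EEG / 60-NIRS montage with 13 regions."""
    channels, hemi = _nirs_layout()
    regions = _nirs_regions(channels, hemi)
    return MontageSpec(
        eeg_channels=EEG_CHANNELS,
        nirs_channels=tuple(channels),
        hemisphere=hemi,
        short_channels=SHORT_CHANNELS,
        region_map=regions,
    )
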