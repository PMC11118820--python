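"""Electrode montage and recording containers.

The default montage is the 19-channel subset of the international 10-20
system used for standing-balance studies, grouped into the three scalp
regions that matter for balance control: the frontal lobe area (information
integration), the central area (proprioception) and the occipital lobe area
(vision).  ``Fz``, ``Cz`` and ``Pz`` are the core nodes of those regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "REGIONS",
    "CORE_NODES",
    "DEFAULT_CORE_PAIRS",
    "ChannelLayout",
    "default_layout",
    "Recording",
]

REGIONS: Tuple[str, ...] = ("frontal", "central", "occipital")

_FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
_CENTRAL = ("T7", "C3", "Cz", "C4", "T8")
_OCCIPITAL = ("P7", "P3", "Pz", "P4", "P8", "O1", "O2")

#: Core node of each region; their pairwise PLVs drive window screening.
CORE_NODES: Mapping[str, str] = MappingProxyType(
    {"frontal": "Fz", "central": "Cz", "occipital": "Pz"}
)

#: Electrode pairs whose PLV is the phase-screening index.
DEFAULT_CORE_PAIRS: Tuple[Tuple[str, str], ...] = (("Fz", "Cz"), ("Fz", "Pz"))


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel labels plus a label -> region map.

    Every label must map to exactly one region.  Channel order is
    significant: it fixes row order in all arrays and matrices downstream.
    """

    labels: Tuple[str, ...]
    region_of: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels in layout")
        missing = [ch for ch in labels if ch not in self.region_of]
        if missing:
            raise ValueError(f"channels without a region: {missing}")
        bad = {ch: r for ch, r in self.region_of.items() if r not in REGIONS}
        if bad:
            raise ValueError(f"unknown regions: {bad}")
        object.__setattr__(self, "region_of", MappingProxyType(dict(self.region_of)))

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Resolve a channel label (case-insensitive) to its row index."""
        try:
            return self.labels.index(label)
        except ValueError:
            pass
        lowered = [ch.lower() for ch in self.labels]
        try:
            return lowered.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in layout") from None

    def region_channels(self, region: str) -> Tuple[str, ...]:
        if region not in REGIONS:
            raise KeyError(f"unknown region {region!r}")
        return tuple(ch for ch in self.labels if self.region_of[ch] == region)

    def region_indices(self, region: str) -> np.ndarray:
        return np.array([self.index(ch) for ch in self.region_channels(region)])


def default_layout() -> ChannelLayout:
    """The 19-channel 10-20 balance montage (7 frontal, 5 central, 7 occipital)."""
    region_of = {}
    for ch in _FRONTAL:
        region_of[ch] = "frontal"
    for ch in _CENTRAL:
        region_of[ch] = "central"
    for ch in _OCCIPITAL:
        region_of[ch] = "occipital"
    return ChannelLayout(labels=_FRONTAL + _CENTRAL + _OCCIPITAL, region_of=region_of)


@dataclass
class Recording:
    """A continuous multichannel EEG-like signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (or arbitrary units for synthetic data).
    fs : float
        Sampling rate in Hz.
    layout : ChannelLayout
        Channel labels and region map; row order matches ``data``.
    """

    data: np.ndarray
    fs: float
    layout: ChannelLayout = field(default_factory=default_layout)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but layout has "
                f"{self.layout.n_channels} channels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.layout.index(label)]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data=data, fs=self.fs, layout=self.layout)


def resolve_pairs(
    layout: ChannelLayout, pairs: Sequence[Tuple[str, str]]
) -> Tuple[Tuple[int, int], ...]:
    """Map label pairs to index pairs, validating against the layout."""
    return tuple((layout.index(a), layout.index(b)) for a, b in pairs)
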