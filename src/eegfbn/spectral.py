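"""Welch power spectral density per channel and per-region band power.

The record is split into tapered, partially overlapping segments; the
modified periodograms of the segments are averaged, with the taper-power
normalization chosen so a white-noise input of variance sigma^2 has mean
density sigma^2 / fs across the one-sided band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import signal

from .montage import REGIONS, ChannelLayout, Recording

__all__ = ["PSDEstimate", "welch_psd", "region_psd_summary"]

DEFAULT_SEGMENT_S = 1.0
DEFAULT_OVERLAP_FRAC = 0.5
DEFAULT_WINDOW_FN = "hamming"


@dataclass
class PSDEstimate:
    """One-sided Welch PSD for every channel (units^2 / Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    segment_len: int
    n_segments: int
    window_fn: str
    overlap_frac: float
    norm_factor: float
    labels: Tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.shape != (len(self.labels), self.freqs.size):
            raise ValueError("power shape does not match labels/freqs")
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def band_power(self, band: Tuple[float, float]) -> np.ndarray:
        """Per-channel PSD integrated over [low, high] Hz (trapezoid rule)."""
        low, high = band
        if not (self.freqs[0] <= low < high <= self.freqs[-1]):
            raise ValueError(f"band {band} outside the frequency grid")
        mask = (self.freqs >= low) & (self.freqs <= high)
        if mask.sum() < 2:
            raise ValueError("band too narrow for the frequency grid")
        return np.trapezoid(self.power[:, mask], self.freqs[mask], axis=1)


def welch_psd(
    rec: Recording,
    segment_len: int | None = None,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
    window_fn: str = DEFAULT_WINDOW_FN,
) -> PSDEstimate:
    """Welch PSD of every channel (one-sided, density scaling).

    ``segment_len`` defaults to one second of samples.  The taper's power
    normalization U = sum(c^2)/M makes the estimate unbiased for white noise.
    """
    if segment_len is None:
        segment_len = int(round(DEFAULT_SEGMENT_S * rec.fs))
    if segment_len > rec.n_samples:
        raise ValueError(
            f"segment_len {segment_len} longer than recording ({rec.n_samples})"
        )
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    noverlap = int(round(overlap_frac * segment_len))
    taper = signal.get_window(window_fn, segment_len)
    freqs, power = signal.welch(
        rec.data,
        fs=rec.fs,
        window=taper,
        nperseg=segment_len,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=1,
    )
    step = segment_len - noverlap
    n_segments = 1 + (rec.n_samples - segment_len) // step
    norm_factor = float(np.sum(taper**2) / segment_len)
    return PSDEstimate(
        freqs=freqs,
        power=power,
        segment_len=segment_len,
        n_segments=n_segments,
        window_fn=window_fn,
        overlap_frac=overlap_frac,
        norm_factor=norm_factor,
        labels=rec.layout.labels,
        fs=rec.fs,
    )


def region_psd_summary(
    psd: PSDEstimate, layout: ChannelLayout, band: Tuple[float, float]
) -> Dict[str, float]:
    """Mean band-integrated power of the channels in each scalp region."""
    bp = psd.band_power(band)
    out: Dict[str, float] = {}
    for region in REGIONS:
        idx = [psd.labels.index(ch) for ch in layout.region_channels(region)]
        out[region] = float(np.mean(bp[idx])) if idx else 0.0
    return out
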