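"""Filtering, band extraction and non-overlapping window segmentation.

All filters are zero-phase so the instantaneous-phase estimates downstream
are not biased by group delay.  Band-pass and band extraction use symmetric
(linear-phase) FIR kernels applied with centered FFT convolution, which is
exactly zero-phase; the narrow notch uses a second-order IIR applied
forward-backward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal

from .montage import ChannelLayout, Recording

__all__ = [
    "DEFAULT_BAND_HZ",
    "GAMMA_BAND_HZ",
    "DEFAULT_NOTCH_HZ",
    "DEFAULT_WINDOW_S",
    "bandpass",
    "notch",
    "remove_baseline",
    "gamma_band",
    "segment",
    "WindowSet",
]

#: Broadband pass band applied after the notch.
DEFAULT_BAND_HZ: Tuple[float, float] = (1.0, 50.0)
#: The gamma band used for the balance analysis.
GAMMA_BAND_HZ: Tuple[float, float] = (30.0, 50.0)
#: Mains frequency removed by the notch.
DEFAULT_NOTCH_HZ: float = 50.0
#: Non-overlapping analysis window length.
DEFAULT_WINDOW_S: float = 0.2
#: FIR transition width heuristic (Hz).
DEFAULT_TRANSITION_HZ: float = 2.0


def _fir_numtaps(fs: float, transition_hz: float) -> int:
    """Hamming-window FIR length for a given transition width (odd)."""
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n + 1 if n % 2 == 0 else n


def _apply_fir_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # symmetric kernel + centered convolution == zero phase
    out = signal.oaconvolve(data, taps[None, :], mode="full", axes=1)
    half = (len(taps) - 1) // 2
    return out[:, half : half + data.shape[1]]


def bandpass(
    rec: Recording,
    low_hz: float,
    high_hz: float,
    transition_hz: float = DEFAULT_TRANSITION_HZ,
) -> Recording:
    """Zero-phase FIR band-pass; band edges must lie inside (0, fs/2)."""
    nyq = rec.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < fs/2 = {nyq} Hz"
        )
    numtaps = _fir_numtaps(rec.fs, transition_hz)
    taps = signal.firwin(
        numtaps, [low_hz, high_hz], pass_zero=False, window="hamming", fs=rec.fs
    )
    return rec.copy_with(_apply_fir_zero_phase(rec.data, taps))


def notch(rec: Recording, freq_hz: float, quality: float = 30.0) -> Recording:
    """Zero-phase narrow-band rejection at ``freq_hz`` (second-order IIR notch)."""
    nyq = rec.fs / 2.0
    if not (0.0 < freq_hz < nyq):
        raise ValueError(f"notch frequency {freq_hz} Hz outside (0, {nyq}) Hz")
    b, a = signal.iirnotch(freq_hz, quality, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return rec.copy_with(out)


def remove_baseline(rec: Recording) -> Recording:
    """Subtract each channel's mean (zero-drift / baseline removal)."""
    return rec.copy_with(rec.data - rec.data.mean(axis=1, keepdims=True))


def gamma_band(rec: Recording, transition_hz: float = DEFAULT_TRANSITION_HZ) -> Recording:
    """Extract the 30-50 Hz gamma band."""
    return bandpass(rec, *GAMMA_BAND_HZ, transition_hz=transition_hz)


@dataclass
class WindowSet:
    """Non-overlapping fixed-length segments of a parent recording.

    Keeps a reference to the parent so downstream phase extraction can run
    on the continuous signal and slice afterwards (avoiding Hilbert edge
    artifacts in short windows).  ``source_indices`` are start-sample offsets
    into the parent; they are strictly increasing and windows never overlap.
    """

    parent: Recording
    source_indices: np.ndarray
    window_samples: int
    window_s: float

    def __post_init__(self) -> None:
        self.source_indices = np.asarray(self.source_indices, dtype=np.int64)
        if self.window_samples < 2:
            raise ValueError("windows must hold at least 2 samples")
        idx = self.source_indices
        if idx.size == 0:
            raise ValueError("WindowSet must contain at least one window")
        if np.any(np.diff(idx) < self.window_samples):
            raise ValueError("windows overlap or indices are not increasing")
        if idx[0] < 0 or idx[-1] + self.window_samples > self.parent.n_samples:
            raise ValueError("window extends beyond the parent recording")

    @property
    def n_windows(self) -> int:
        return int(self.source_indices.size)

    @property
    def fs(self) -> float:
        return self.parent.fs

    @property
    def layout(self) -> ChannelLayout:
        return self.parent.layout

    @property
    def windows(self) -> np.ndarray:
        """(n_windows, n_channels, window_samples) view-copy of the segments."""
        cols = self.source_indices[:, None] + np.arange(self.window_samples)[None, :]
        return self.parent.data[:, cols].transpose(1, 0, 2)

    def subset(self, mask: np.ndarray) -> "WindowSet":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_windows,):
            raise ValueError("mask length must match window count")
        if not mask.any():
            raise ValueError("subset would be empty")
        return WindowSet(
            parent=self.parent,
            source_indices=self.source_indices[mask],
            window_samples=self.window_samples,
            window_s=self.window_s,
        )


def segment(rec: Recording, window_s: float = DEFAULT_WINDOW_S) -> WindowSet:
    """Split a recording into non-overlapping windows of ``window_s`` seconds.

    The trailing partial window is discarded.  Raises if the window is longer
    than the recording or holds fewer than 2 samples.
    """
    wlen = int(round(window_s * rec.fs))
    if wlen < 2:
        raise ValueError("window_s * fs must be at least 2 samples")
    if wlen > rec.n_samples:
        raise ValueError(
            f"window of {wlen} samples longer than recording ({rec.n_samples})"
        )
    n_win = rec.n_samples // wlen
    starts = np.arange(n_win, dtype=np.int64) * wlen
    return WindowSet(
        parent=rec, source_indices=starts, window_samples=wlen, window_s=window_s
    )
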