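"""Analytic-signal phase extraction and the PLV / PLI / wPLI metrics.

The analytic signal R(t) = r(t) + j*H[r](t) = A(t) e^{j phi(t)} of each
channel gives its instantaneous amplitude and phase.  For two channels s1,
s2 with phase difference theta(t) = phi_s1(t) - phi_s2(t):

* PLV  = | mean_t e^{j theta(t)} |                       (phase locking)
* PLI  = | mean_t sign(sin theta(t)) |                   (lag asymmetry)
* wPLI = | mean_t Im X(t) | / mean_t | Im X(t) |,        X = R_s1 conj(R_s2)

The PLV is maximal for any consistent phase relation, including zero lag,
so it inflates under volume conduction; PLI and wPLI discard zero-lag
(real-axis) contributions, and wPLI additionally weights each sample by the
magnitude of the imaginary cross-spectrum, which reduces noise sensitivity
around the zero-lag discontinuity.

By default phases are extracted from the continuous filtered record and
then segmented, avoiding Hilbert edge artifacts in 0.2 s windows; a
per-window transform is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import hilbert

from .montage import ChannelLayout
from .preprocess import WindowSet

__all__ = [
    "DegenerateChannelError",
    "AnalyticWindow",
    "PhaseDiffSeries",
    "PairMetric",
    "ConnectivityMatrix",
    "analytic_signal",
    "hilbert_windows",
    "phase_difference",
    "plv",
    "pli",
    "wpli",
    "pairwise_matrix",
    "connectivity_per_window",
]

logger = logging.getLogger("eegfbn")

METRICS = ("PLV", "PLI", "wPLI")

#: diagonal convention per metric: a channel is perfectly locked to itself
#: (PLV), but has no lag asymmetry with itself (PLI/wPLI).
_DIAG = {"PLV": 1.0, "PLI": 0.0, "wPLI": 0.0}

_CHUNK = 4096  # time-chunk for pairwise elementwise accumulations


class DegenerateChannelError(ValueError):
    """A constant (e.g. all-zero) channel has no defined instantaneous phase."""


@dataclass
class AnalyticWindow:
    """Complex analytic signal of a (channels x samples) segment."""

    analytic: np.ndarray
    fs: float
    labels: Tuple[str, ...]
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.analytic = np.asarray(self.analytic, dtype=np.complex128)
        if self.analytic.ndim != 2:
            raise ValueError("analytic must be 2-D (channels x samples)")
        if len(self.labels) != self.analytic.shape[0]:
            raise ValueError("labels/rows mismatch")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.analytic.shape[0], dtype=bool)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.analytic)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.analytic)

    @property
    def n_samples(self) -> int:
        return self.analytic.shape[1]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            lowered = [ch.lower() for ch in self.labels]
            if label.lower() in lowered:
                return lowered.index(label.lower())
            raise KeyError(f"channel {label!r} not present") from None

    def _check_pair(self, pair: Tuple[str, str]) -> Tuple[int, int]:
        i, j = self.index(pair[0]), self.index(pair[1])
        bad = [self.labels[k] for k in (i, j) if self.degenerate[k]]
        if bad:
            raise DegenerateChannelError(
                f"channel(s) {bad} are constant; instantaneous phase undefined"
            )
        return i, j


def analytic_signal(
    window: np.ndarray, fs: float, labels: Optional[Sequence[str]] = None
) -> AnalyticWindow:
    """Analytic signal (Hilbert transform) of each channel of a segment.

    Constant channels (including all-zero) are flagged as degenerate: their
    amplitude is reported but any metric using their phase raises
    :class:`DegenerateChannelError`.
    """
    arr = np.atleast_2d(np.asarray(window, dtype=np.float64))
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    if not np.all(np.isfinite(arr)):
        raise ValueError("window contains non-finite samples")
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(arr.shape[0]))
    degenerate = np.ptp(arr, axis=1) == 0.0
    return AnalyticWindow(
        analytic=hilbert(arr, axis=1),
        fs=fs,
        labels=tuple(labels),
        degenerate=degenerate,
    )


def hilbert_windows(ws: WindowSet, per_window: bool = False) -> List[AnalyticWindow]:
    """Analytic signal of every window of a :class:`WindowSet`.

    By default the Hilbert transform is taken once on the continuous parent
    recording and sliced at the windows' source indices; ``per_window=True``
    transforms each window independently instead.
    """
    labels = ws.layout.labels
    if per_window:
        return [analytic_signal(w, ws.fs, labels) for w in ws.windows]
    full = analytic_signal(ws.parent.data, ws.fs, labels)
    out = []
    for start in ws.source_indices:
        seg = full.analytic[:, start : start + ws.window_samples]
        deg = np.ptp(seg.real, axis=1) == 0.0
        out.append(AnalyticWindow(seg, ws.fs, labels, degenerate=deg | full.degenerate))
    return out


@dataclass
class PhaseDiffSeries:
    """Instantaneous phase difference theta(t) of one channel pair, wrapped to (-pi, pi]."""

    theta: np.ndarray
    pair: Tuple[str, str]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        # wrap into (-pi, pi]
        self.theta = np.angle(np.exp(1j * self.theta))

    @property
    def n_samples(self) -> int:
        return self.theta.size


@dataclass
class PairMetric:
    """A scalar synchronization value for one channel pair."""

    value: float
    metric: str
    pair: Tuple[str, str]
    n_samples: int
    signed: Optional[float] = None  # PLI before taking the absolute value


def phase_difference(a: AnalyticWindow, pair: Tuple[str, str]) -> PhaseDiffSeries:
    """theta(t) = phi_s1(t) - phi_s2(t), wrapped into (-pi, pi]."""
    i, j = a._check_pair(pair)
    return PhaseDiffSeries(theta=a.phase[i] - a.phase[j], pair=tuple(pair))


def _check_theta(theta: PhaseDiffSeries) -> np.ndarray:
    t = theta.theta
    if t.size < 2:
        raise ValueError("need at least 2 phase samples")
    if not np.all(np.isfinite(t)):
        raise DegenerateChannelError("phase difference contains undefined samples")
    return t


def plv(theta: PhaseDiffSeries) -> PairMetric:
    """Phase-locking value: modulus of the time-averaged unit phasor of theta."""
    t = _check_theta(theta)
    value = float(np.abs(np.mean(np.exp(1j * t))))
    return PairMetric(value=value, metric="PLV", pair=theta.pair, n_samples=t.size)


def pli(theta: PhaseDiffSeries) -> PairMetric:
    """Phase lag index: |mean sign(sin theta)|; the signed mean is retained."""
    t = _check_theta(theta)
    signed = float(np.mean(np.sign(np.sin(t))))
    return PairMetric(
        value=abs(signed),
        metric="PLI",
        pair=theta.pair,
        n_samples=t.size,
        signed=signed,
    )


def wpli(a: AnalyticWindow, pair: Tuple[str, str]) -> PairMetric:
    """Weighted phase lag index from the instantaneous cross-spectrum.

    X(t) = R_s1(t) * conj(R_s2(t)); wPLI = |mean Im X| / mean |Im X|, with the
    0/0 case (a purely zero-lag relation, Im X identically 0) defined as 0.
    """
    i, j = a._check_pair(pair)
    x = a.analytic[i] * np.conj(a.analytic[j])
    imx = x.imag
    if imx.size < 2:
        raise ValueError("need at least 2 samples")
    den = np.mean(np.abs(imx))
    # purely zero-lag relations leave only rounding residue in Im X
    tol = 1e-12 * np.mean(np.abs(x))
    value = 0.0 if den <= tol else float(abs(np.mean(imx)) / den)
    return PairMetric(value=value, metric="wPLI", pair=tuple(pair), n_samples=imx.size)


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel synchronization matrix for one metric."""

    values: np.ndarray
    metric: str
    layout: ChannelLayout
    n_windows_averaged: int = 1
    flagged: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.layout.n_channels
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match layout")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-12,
        ):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def labels(self) -> Tuple[str, ...]:
        return self.layout.labels

    def pair_value(self, a: str, b: str) -> float:
        return float(self.values[self.layout.index(a), self.layout.index(b)])

    def offdiag_values(self) -> np.ndarray:
        """The C(n, 2) upper-triangle pair values, row-major order."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def _pair_chunks(z1: np.ndarray, z2: np.ndarray):
    for start in range(0, z1.shape[1], _CHUNK):
        yield z1[:, start : start + _CHUNK], z2[:, start : start + _CHUNK]


def pairwise_matrix(
    a: AnalyticWindow, metric: str = "wPLI", layout: Optional[ChannelLayout] = None
) -> ConnectivityMatrix:
    """All-pairs synchronization matrix (C(n,2) distinct values; symmetric).

    Degenerate channels are not silently zeroed: their rows/columns are NaN
    and their labels are recorded in ``flagged`` (and logged).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    A = a.analytic
    n_ch, n = A.shape
    if metric == "PLV":
        Z = np.exp(1j * np.angle(A))
        M = np.abs(Z @ Z.conj().T) / n
    elif metric == "PLI":
        Z = np.exp(1j * np.angle(A))
        S = np.zeros((n_ch, n_ch))
        for z1, z2 in _pair_chunks(Z, Z):
            cross = z1[:, None, :] * np.conj(z2[None, :, :])
            S += np.sign(cross.imag).sum(axis=2)
        M = np.abs(S) / n
    else:  # wPLI
        num = np.imag(A @ A.conj().T)  # sum_t Im X
        den = np.zeros((n_ch, n_ch))
        mag = np.zeros((n_ch, n_ch))
        for z1, z2 in _pair_chunks(A, A):
            cross = z1[:, None, :] * np.conj(z2[None, :, :])
            den += np.abs(cross.imag).sum(axis=2)
            mag += np.abs(cross).sum(axis=2)
        tol = 1e-12 * mag  # zero-lag pairs leave only rounding residue
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(den > tol, np.abs(num) / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(M, _DIAG[metric])

    flagged: Tuple[str, ...] = ()
    if a.degenerate.any():
        flagged = tuple(np.asarray(a.labels)[a.degenerate])
        M[a.degenerate, :] = np.nan
        M[:, a.degenerate] = np.nan
        logger.warning("degenerate channels flagged in %s matrix: %s", metric, flagged)

    if layout is None:
        from .montage import default_layout

        dl = default_layout()
        if tuple(a.labels) == dl.labels:
            layout = dl
        else:
            # ad-hoc label set: synthesize a one-region layout so the matrix
            # still carries its channel names
            layout = ChannelLayout(
                labels=tuple(a.labels),
                region_of={ch: "frontal" for ch in a.labels},
            )
    return ConnectivityMatrix(values=M, metric=metric, layout=layout, flagged=flagged)


def connectivity_per_window(
    ws: WindowSet, metric: str = "wPLI", per_window_hilbert: bool = False
) -> List[ConnectivityMatrix]:
    """One pairwise matrix per window of a :class:`WindowSet`."""
    return [
        pairwise_matrix(aw, metric, layout=ws.layout)
        for aw in hilbert_windows(ws, per_window=per_window_hilbert)
    ]
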