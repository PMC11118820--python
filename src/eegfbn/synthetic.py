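"""Synthetic multichannel EEG with planted phase-coupling events.

The generator emulates the statistical structure a standing-balance EEG
study needs, without any real data:

* a resting baseline of independent gamma-band (40 Hz carrier) oscillators
  whose phases follow a Wiener (phase-diffusion) process, so pairwise phase
  locking decays to zero over long records;
* randomly timed "balance-adjustment" events during which specified channel
  pairs lock to a common driver with a prescribed mean phase lag; the
  residual pair phase difference is approximately von-Mises distributed with
  concentration kappa(coupling_strength);
* 1/f^alpha background noise at a configurable SNR;
* an optional instantaneous (zero-lag) linear mixing stage with a common
  source, emulating volume conduction.

Events also raise the locked oscillation's amplitude (activation gain), so
regionally graded coupling produces the regional band-power gradients seen
in task EEG, not only a phase pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .montage import CORE_NODES, ChannelLayout, Recording, default_layout

__all__ = [
    "CouplingEvent",
    "GroundTruth",
    "generate_recording",
    "paradigm_preset",
    "kappa_from_strength",
    "PARADIGM_REGION_STRENGTH",
    "PARADIGMS",
]

#: Maximum von-Mises concentration used for fully coupled pairs.
KAPPA_MAX = 50.0


def kappa_from_strength(c: float) -> float:
    """Monotone map coupling_strength -> von-Mises concentration.

    kappa(c) = min(2c / (1 - c^2), KAPPA_MAX).  Chosen so that the circular
    resultant length of the pair phase difference is roughly equal to ``c``
    over the useful range, with kappa(1) = 50 (resultant ~ 0.99).
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("coupling_strength must lie in [0, 1]")
    if c == 0.0:
        return 0.0
    if c >= 1.0:
        return KAPPA_MAX
    return min(2.0 * c / (1.0 - c * c), KAPPA_MAX)


def _wrap_phase(theta) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(theta, dtype=np.float64)))


@dataclass(frozen=True)
class CouplingEvent:
    """A transient phase-coupling episode between channel pairs.

    During [start_s, start_s + duration_s) every listed pair oscillates with
    mean instantaneous phase difference ``phase_lag_rad`` and a concentration
    that grows with ``coupling_strength`` (0 = no coupling, 1 = near-perfect
    locking).
    """

    start_s: float
    duration_s: float
    channel_pairs: Tuple[Tuple[str, str], ...]
    phase_lag_rad: float
    coupling_strength: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "channel_pairs", tuple((a, b) for a, b in self.channel_pairs)
        )
        if self.start_s < 0:
            raise ValueError("start_s must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if not (-math.pi < self.phase_lag_rad <= math.pi):
            raise ValueError("phase_lag_rad must lie in (-pi, pi]")
        if not self.channel_pairs:
            raise ValueError("channel_pairs must not be empty")
        for a, b in self.channel_pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {b})")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def channels(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for a, b in self.channel_pairs:
            for ch in (a, b):
                if ch not in seen:
                    seen.append(ch)
        return tuple(seen)

    def to_dict(self) -> dict:
        return {
            "start_s": self.start_s,
            "duration_s": self.duration_s,
            "channel_pairs": [list(p) for p in self.channel_pairs],
            "phase_lag_rad": self.phase_lag_rad,
            "coupling_strength": self.coupling_strength,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingEvent":
        return cls(
            start_s=d["start_s"],
            duration_s=d["duration_s"],
            channel_pairs=tuple(tuple(p) for p in d["channel_pairs"]),
            phase_lag_rad=d["phase_lag_rad"],
            coupling_strength=d["coupling_strength"],
        )


@dataclass
class GroundTruth:
    """What the generator planted: events, mixing and noise parameters."""

    events: Tuple[CouplingEvent, ...]
    mixing_matrix: np.ndarray  # (n_channels, n_sources)
    noise_exponent: float
    carrier_band_hz: Tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "events": [e.to_dict() for e in self.events],
            "mixing_matrix": np.asarray(self.mixing_matrix).tolist(),
            "noise_exponent": self.noise_exponent,
            "carrier_band_hz": list(self.carrier_band_hz),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            events=tuple(CouplingEvent.from_dict(e) for e in d["events"]),
            mixing_matrix=np.asarray(d["mixing_matrix"], dtype=float),
            noise_exponent=d["noise_exponent"],
            carrier_band_hz=tuple(d["carrier_band_hz"]),
        )


# ---------------------------------------------------------------------------
# low-level stochastic building blocks
# ---------------------------------------------------------------------------


def _wiener_phase(
    rng: np.random.Generator, n: int, fs: float, f0: float, diffusion: float, phi0: float
) -> np.ndarray:
    """Phase of a diffusing oscillator: 2*pi*f0*t + Wiener(diffusion) + phi0."""
    t = np.arange(n) / fs
    steps = rng.normal(0.0, math.sqrt(diffusion / fs), size=n)
    steps[0] = 0.0
    return 2.0 * math.pi * f0 * t + np.cumsum(steps) + phi0


def _ou_process(
    rng: np.random.Generator, n: int, fs: float, std: float, tau_s: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise (AR(1)) with given std and time constant."""
    if std == 0.0 or n == 0:
        return np.zeros(n)
    a = math.exp(-1.0 / (fs * tau_s))
    innov_std = std * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, std)
    if n > 1:
        innov = rng.normal(0.0, innov_std, size=n - 1)
        x[1:], _ = lfilter([1.0], [1.0, -a], innov, zi=np.array([a * x[0]]))
    return x


def _one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float, rms: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum and target RMS."""
    if rms == 0.0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return x


def _blend_weight(
    intervals: Sequence[Tuple[int, int]], n0: int, n1: int, ramp: int
) -> np.ndarray:
    """Crossfade weight over span [n0, n1): 1 inside intervals, cosine ramps at edges."""
    w = np.zeros(n1 - n0)
    for a, b in intervals:
        a_rel, b_rel = a - n0, b - n0
        w[a_rel:b_rel] = 1.0
    if ramp > 1:
        for a, b in intervals:
            a_rel, b_rel = a - n0, b - n0
            k = np.arange(min(ramp, b_rel - a_rel))
            up = 0.5 - 0.5 * np.cos(math.pi * (k + 1) / ramp)
            w[a_rel : a_rel + len(k)] = np.minimum(w[a_rel : a_rel + len(k)], up)
            w[b_rel - len(k) : b_rel] = np.minimum(
                w[b_rel - len(k) : b_rel], up[::-1]
            )
    return w


def _merge_intervals(iv: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    iv = sorted(iv)
    out: List[Tuple[int, int]] = []
    for a, b in iv:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_recording(
    layout: Optional[ChannelLayout] = None,
    duration_s: float = 60.0,
    fs: float = 1000.0,
    events: Sequence[CouplingEvent] = (),
    noise_exponent: float = 1.0,
    mixing_strength: float = 0.0,
    seed: int = 0,
    *,
    carrier_hz: float = 40.0,
    band_halfwidth_hz: float = 10.0,
    snr_db: float = 5.0,
    linewidth_hz: float = 8.0,
    activation_gain: float = 1.0,
    am_depth: float = 0.1,
    jitter_tau_s: float = 0.05,
    ramp_s: float = 0.02,
) -> Tuple[Recording, GroundTruth]:
    """Generate a multichannel recording with planted coupling events.

    Parameters
    ----------
    layout : ChannelLayout, optional
        Channel montage (default: the 19-channel 10-20 balance montage).
    duration_s, fs : float
        Record length (s) and sampling rate (Hz); fs must satisfy the
        Nyquist bound for the carrier band.
    events : sequence of CouplingEvent
        Planted coupling episodes; all must lie within the record.
    noise_exponent : float
        1/f^alpha slope of the background noise (default 1).
    mixing_strength : float in [0, 1]
        Weight of the zero-lag common source blended into every channel
        (volume-conduction emulation): y_i = (1-m) x_i + m s.
    seed : int
        Seed for all randomness; identical arguments + seed give
        bit-identical output.
    carrier_hz, band_halfwidth_hz : float
        Carrier frequency and nominal half-bandwidth of the oscillators.
    snr_db : float
        Carrier-to-noise power ratio in dB (carrier is unit RMS).
    linewidth_hz : float
        Lorentzian full-width of the baseline oscillators (phase-diffusion
        rate D = 2*pi*linewidth).
    activation_gain : float
        Event-locked amplitude gain slope: locked oscillations are scaled by
        (1 + activation_gain * coupling_strength).
    am_depth : float
        Depth of slow (tau = 1 s) amplitude modulation of each channel.
    jitter_tau_s : float
        Correlation time of the within-event phase jitter (slow enough to
        survive band-pass filtering).
    ramp_s : float
        Waveform crossfade length at event boundaries.

    Returns
    -------
    (Recording, GroundTruth)
    """
    layout = layout if layout is not None else default_layout()
    band = (carrier_hz - band_halfwidth_hz, carrier_hz + band_halfwidth_hz)
    if fs < 2.0 * band[1]:
        raise ValueError(
            f"fs = {fs} Hz is below the Nyquist rate for the carrier band "
            f"{band} Hz"
        )
    if not 0.0 <= mixing_strength <= 1.0:
        raise ValueError("mixing_strength must lie in [0, 1]")
    n = int(round(duration_s * fs))
    events = tuple(events)
    for ev in events:
        if ev.end_s > duration_s + 1e-9:
            raise ValueError(
                f"event [{ev.start_s}, {ev.end_s}) s lies outside the "
                f"{duration_s} s recording"
            )
        for a, b in ev.channel_pairs:
            layout.index(a)
            layout.index(b)

    rng = np.random.default_rng(seed)
    n_ch = layout.n_channels
    diffusion = 2.0 * math.pi * linewidth_hz  # rad^2 / s
    noise_rms = 10.0 ** (-snr_db / 20.0)
    amp = math.sqrt(2.0)  # unit-RMS carrier

    # --- baseline oscillators, AM envelopes and 1/f noise (fixed rng order) ---
    base_phase = np.empty((n_ch, n))
    for i in range(n_ch):
        phi0 = rng.uniform(-math.pi, math.pi)
        base_phase[i] = _wiener_phase(rng, n, fs, carrier_hz, diffusion, phi0)
    am = np.empty((n_ch, n))
    for i in range(n_ch):
        am[i] = np.clip(_ou_process(rng, n, fs, am_depth, 1.0), -0.9, None)
    noise = np.empty((n_ch, n))
    for i in range(n_ch):
        noise[i] = _one_over_f_noise(rng, n, fs, noise_exponent, noise_rms)

    carrier = np.cos(base_phase)

    # --- planted events: cluster by time overlap, lock channels to drivers ---
    active = [ev for ev in events if ev.coupling_strength > 0.0]
    clusters: List[List[CouplingEvent]] = []
    for ev in sorted(active, key=lambda e: e.start_s):
        if clusters and ev.start_s < max(e.end_s for e in clusters[-1]):
            clusters[-1].append(ev)
        else:
            clusters.append([ev])

    for cluster in clusters:
        n0 = int(round(min(e.start_s for e in cluster) * fs))
        n1 = min(int(round(max(e.end_s for e in cluster) * fs)), n)
        span = n1 - n0
        if span <= 0:
            continue
        # union graph over the cluster with per-edge lag/strength
        edges: Dict[Tuple[str, str], Tuple[float, float]] = {}
        adj: Dict[str, List[str]] = {}
        ch_strength: Dict[str, float] = {}
        ch_intervals: Dict[str, List[Tuple[int, int]]] = {}
        for ev in cluster:
            a0 = max(int(round(ev.start_s * fs)), n0)
            b0 = min(int(round(ev.end_s * fs)), n1)
            for a, b in ev.channel_pairs:
                key = (a, b)
                if key not in edges and (b, a) not in edges:
                    edges[key] = (ev.phase_lag_rad, ev.coupling_strength)
                    adj.setdefault(a, []).append(b)
                    adj.setdefault(b, []).append(a)
                for ch in (a, b):
                    ch_strength[ch] = max(
                        ch_strength.get(ch, 0.0), ev.coupling_strength
                    )
                    ch_intervals.setdefault(ch, []).append((a0, b0))
        # connected components -> one driver each; offsets via BFS on the
        # spanning tree (extra edges of inconsistent cycles are ignored)
        seen: Dict[str, float] = {}
        for root in adj:
            if root in seen:
                continue
            comp = [root]
            seen[root] = 0.0
            queue = [root]
            while queue:
                u = queue.pop(0)
                for v in adj[u]:
                    if v in seen:
                        continue
                    if (u, v) in edges:
                        lag = edges[(u, v)][0]  # phi_u - phi_v = lag
                        seen[v] = seen[u] - lag
                    else:
                        lag = edges[(v, u)][0]
                        seen[v] = seen[u] + lag
                    comp.append(v)
                    queue.append(v)
            driver = _wiener_phase(
                rng, span, fs, carrier_hz, diffusion, rng.uniform(-math.pi, math.pi)
            )
            ramp = int(round(ramp_s * fs))
            for ch in comp:
                kappa = kappa_from_strength(ch_strength[ch])
                # per-channel jitter carries half the pair variance 1/kappa
                std = math.sqrt(1.0 / (2.0 * kappa)) if kappa > 0 else 0.0
                jitter = _ou_process(rng, span, fs, std, jitter_tau_s)
                phase_evt = driver + seen[ch] + jitter
                idx = layout.index(ch)
                intervals = _merge_intervals(ch_intervals[ch])
                min_len = min(b - a for a, b in intervals)
                w = _blend_weight(intervals, n0, n1, min(ramp, max(min_len // 4, 1)))
                gain = 1.0 + activation_gain * ch_strength[ch]
                seg = slice(n0, n1)
                carrier[idx, seg] = (1.0 - w) * carrier[idx, seg] + w * gain * np.cos(
                    phase_evt
                )

    data = amp * (1.0 + am) * carrier + noise

    # --- zero-lag common-source mixing (volume conduction) ---
    m = float(mixing_strength)
    source_phase = _wiener_phase(
        rng, n, fs, carrier_hz, diffusion, rng.uniform(-math.pi, math.pi)
    )
    source = amp * np.cos(source_phase) + _one_over_f_noise(
        rng, n, fs, noise_exponent, noise_rms
    )
    if m > 0.0:
        data = (1.0 - m) * data + m * source[None, :]
    mixing_matrix = np.hstack(
        [(1.0 - m) * np.eye(n_ch), np.full((n_ch, 1), m)]
    )

    rec = Recording(data=data, fs=fs, layout=layout)
    gt = GroundTruth(
        events=events,
        mixing_matrix=mixing_matrix,
        noise_exponent=noise_exponent,
        carrier_band_hz=band,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# paradigm presets
# ---------------------------------------------------------------------------

#: Per-region coupling strength during balance-adjustment events.  P1 is the
#: unobstructed stance (even activation); P2 blocks vision (occipital down,
#: frontal/central up); P3 blocks proprioception (central down,
#: frontal/occipital up); P4 blocks both (frontal dominant).
PARADIGM_REGION_STRENGTH: Mapping[str, Mapping[str, float]] = {
    "P1": {"frontal": 0.8, "central": 0.8, "occipital": 0.8},
    "P2": {"frontal": 0.9, "central": 0.8, "occipital": 0.35},
    "P3": {"frontal": 0.9, "central": 0.35, "occipital": 0.8},
    "P4": {"frontal": 0.9, "central": 0.4, "occipital": 0.35},
}

PARADIGMS: Tuple[str, ...] = ("P1", "P2", "P3", "P4")

#: Coupling strength of the cross-region core pairs (Fz-Cz, Fz-Pz) during
#: events; high in every paradigm, matching their role as screening indexes.
CORE_PAIR_STRENGTH = 0.9


def _poisson_onsets(
    rng: np.random.Generator,
    duration_s: float,
    rate_per_min: float,
    event_s: float,
    margin_s: float = 1.0,
) -> List[float]:
    """Non-overlapping Poisson-like event onsets with a refractory gap."""
    mean_gap = max(60.0 / rate_per_min - event_s, 0.1)
    onsets: List[float] = []
    t = margin_s + rng.exponential(mean_gap) * 0.25
    while t + event_s <= duration_s - margin_s:
        onsets.append(t)
        t += event_s + max(rng.exponential(mean_gap), 0.2)
    return onsets


def paradigm_preset(
    name: str,
    seed: int = 0,
    *,
    duration_s: float = 180.0,
    fs: float = 1000.0,
    event_rate_per_min: float = 12.0,
    event_duration_s: float = 1.0,
    layout: Optional[ChannelLayout] = None,
    **generator_kwargs,
) -> Tuple[Recording, GroundTruth]:
    """Generate a recording emulating one of the four balance paradigms.

    Events occur at stochastic onsets; at each event every region's channels
    lock to their core node (Fz, Cz or Pz) at the region's preset coupling
    strength, and the core pairs Fz-Cz / Fz-Pz lock strongly.  Per-channel
    phase offsets are redrawn at every event so pairwise lags vary across
    events.
    """
    if name not in PARADIGM_REGION_STRENGTH:
        raise ValueError(f"unknown paradigm {name!r}; expected one of {PARADIGMS}")
    layout = layout if layout is not None else default_layout()
    strengths = PARADIGM_REGION_STRENGTH[name]

    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(7,))
    rng = np.random.default_rng(ss)
    events: List[CouplingEvent] = []
    for onset in _poisson_onsets(rng, duration_s, event_rate_per_min, event_duration_s):
        offsets = {ch: rng.uniform(-math.pi, math.pi) for ch in layout.labels}
        offsets["Fz"] = 0.0
        for region, strength in strengths.items():
            core = CORE_NODES[region]
            for ch in layout.region_channels(region):
                if ch == core:
                    continue
                lag = float(_wrap_phase(offsets[core] - offsets[ch]))
                events.append(
                    CouplingEvent(
                        start_s=onset,
                        duration_s=event_duration_s,
                        channel_pairs=((core, ch),),
                        phase_lag_rad=lag,
                        coupling_strength=strength,
                    )
                )
        for core_pair in (("Fz", "Cz"), ("Fz", "Pz")):
            a, b = core_pair
            lag = float(_wrap_phase(offsets[a] - offsets[b]))
            events.append(
                CouplingEvent(
                    start_s=onset,
                    duration_s=event_duration_s,
                    channel_pairs=(core_pair,),
                    phase_lag_rad=lag,
                    coupling_strength=CORE_PAIR_STRENGTH,
                )
            )
    return generate_recording(
        layout=layout,
        duration_s=duration_s,
        fs=fs,
        events=events,
        seed=seed,
        **generator_kwargs,
    )
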