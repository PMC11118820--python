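"""Phase-locking synchronous screening of windowed EEG.

Balance adjustments occur at random times, so most windows of a standing
record are resting state with scattered phase information.  Each window is
scored by the PLV of the core node pairs (Fz-Cz and Fz-Pz by default); the
high-synchrony windows are selected and recombined into a new window set on
which the functional network is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .montage import DEFAULT_CORE_PAIRS
from .phase import hilbert_windows, phase_difference, plv
from .preprocess import WindowSet
from .synthetic import GroundTruth

__all__ = [
    "ScreeningResult",
    "score_windows",
    "select_windows",
    "recombine",
    "screening_recovery_report",
    "RecoveryReport",
]

_COMBINE = {"mean": np.mean, "min": np.min, "max": np.max}

#: fraction of a window that must overlap an event for a truth-positive label
TRUTH_OVERLAP_FRAC = 0.5


@dataclass
class ScreeningResult:
    """Scores, selection mask and the rule that produced them."""

    scores: np.ndarray
    selected: np.ndarray
    core_pairs: Tuple[Tuple[str, str], ...]
    rule: str
    threshold_used: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.scores.shape != self.selected.shape:
            raise ValueError("scores/selected length mismatch")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "threshold_used": self.threshold_used,
            "core_pairs": [list(p) for p in self.core_pairs],
            "n_windows": int(self.scores.size),
            "n_selected": self.n_selected,
        }


def score_windows(
    ws: WindowSet,
    core_pairs: Sequence[Tuple[str, str]] = DEFAULT_CORE_PAIRS,
    combine: str = "mean",
    per_window_hilbert: bool = False,
) -> np.ndarray:
    """Per-window screening score: combined core-pair PLV.

    The default combination is the arithmetic mean of the pair PLVs
    (configurable: mean | min | max).
    """
    core_pairs = tuple(tuple(p) for p in core_pairs)
    if not core_pairs:
        raise ValueError("core_pairs must not be empty")
    if combine not in _COMBINE:
        raise ValueError(f"combine must be one of {sorted(_COMBINE)}")
    for a, b in core_pairs:
        ws.layout.index(a)
        ws.layout.index(b)
    comb = _COMBINE[combine]
    scores = np.empty(ws.n_windows)
    for k, aw in enumerate(hilbert_windows(ws, per_window=per_window_hilbert)):
        vals = [plv(phase_difference(aw, pair)).value for pair in core_pairs]
        scores[k] = comb(vals)
    return scores


def select_windows(
    scores: np.ndarray,
    rule: str = "quantile",
    q: float = 0.3,
    tau: Optional[float] = None,
    core_pairs: Sequence[Tuple[str, str]] = DEFAULT_CORE_PAIRS,
) -> ScreeningResult:
    """Select high-synchrony windows.

    * ``rule="quantile"``: keep the top fraction ``q`` of windows (score >=
      the (1-q)-quantile; ties at the threshold are all kept).
    * ``rule="absolute"``: keep windows with score >= ``tau``; if none
      qualify the single highest-scoring window is kept.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0 or not np.any(np.isfinite(scores)):
        raise ValueError("no defined scores to select from")
    if rule == "quantile":
        if not 0.0 < q < 1.0:
            raise ValueError("quantile fraction q must lie in (0, 1)")
        k = max(1, int(math.ceil(q * scores.size)))
        threshold = float(np.sort(scores)[::-1][k - 1])
    elif rule == "absolute":
        if tau is None or not 0.0 <= tau <= 1.0:
            raise ValueError("absolute rule needs tau in [0, 1]")
        threshold = float(tau)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    selected = scores >= threshold
    if not selected.any():  # absolute threshold above every score
        selected = scores == np.nanmax(scores)
        threshold = float(np.nanmax(scores))
    return ScreeningResult(
        scores=scores,
        selected=selected,
        core_pairs=tuple(tuple(p) for p in core_pairs),
        rule=f"{rule}(q={q})" if rule == "quantile" else f"absolute(tau={tau})",
        threshold_used=threshold,
    )


def recombine(ws: WindowSet, sr: ScreeningResult) -> WindowSet:
    """The recombined window set: selected windows only, provenance preserved.

    Downstream metrics operate per window; no cross-window phase continuity
    is implied by the recombination.
    """
    if sr.selected.size != ws.n_windows:
        raise ValueError("selection mask length does not match window count")
    if not sr.selected.any():
        raise ValueError("cannot recombine an empty selection")
    return ws.subset(sr.selected)


@dataclass
class RecoveryReport:
    """Recovery of planted events by the screening stage."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    n_positive: int
    n_negative: int


def screening_recovery_report(
    sr: ScreeningResult, gt: GroundTruth, ws: WindowSet
) -> RecoveryReport:
    """Sensitivity/specificity of the selection against planted events.

    A window is truth-positive when at least half of it overlaps any planted
    event that involves one of the screening core pairs.  With no positive
    (or no negative) windows the corresponding rate is undefined (None).
    """
    if sr.selected.size != ws.n_windows:
        raise ValueError("screening result does not match window set")
    core = {frozenset(p) for p in sr.core_pairs}
    fs = ws.fs
    wlen = ws.window_samples
    positive = np.zeros(ws.n_windows, dtype=bool)
    for ev in gt.events:
        if ev.coupling_strength <= 0.0:
            continue
        if not any(frozenset(p) in core for p in ev.channel_pairs):
            continue
        ev_a, ev_b = ev.start_s * fs, ev.end_s * fs
        starts = ws.source_indices
        overlap = np.minimum(starts + wlen, ev_b) - np.maximum(starts, ev_a)
        positive |= overlap >= TRUTH_OVERLAP_FRAC * wlen
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    sens = float((sr.selected & positive).sum() / n_pos) if n_pos else None
    spec = float((~sr.selected & ~positive).sum() / n_neg) if n_neg else None
    return RecoveryReport(
        sensitivity=sens, specificity=spec, n_positive=n_pos, n_negative=n_neg
    )
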