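"""Run configuration with the study's default parameters.

Defaults follow the analysis protocol: 1000 Hz sampling, 50 Hz notch,
1-50 Hz band-pass, 30-50 Hz gamma extraction, 0.2 s non-overlapping
windows, Fz-Cz / Fz-Pz core screening pairs and a wPLI network.  Values can
be overridden from a YAML/JSON file or keyword arguments (CLI > file >
defaults).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .montage import DEFAULT_CORE_PAIRS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # preprocessing
    band_hz: Tuple[float, float] = (1.0, 50.0)
    notch_hz: float = 50.0
    gamma_hz: Tuple[float, float] = (30.0, 50.0)
    window_s: float = 0.2
    # screening
    core_pairs: Tuple[Tuple[str, str], ...] = DEFAULT_CORE_PAIRS
    combine: str = "mean"  # mean | min | max over core-pair PLVs
    screen_rule: str = "quantile"  # quantile | absolute
    screen_q: float = 0.3
    screen_tau: Optional[float] = None
    per_window_hilbert: bool = False
    # network
    fc_metric: str = "wPLI"
    edge_rule: str = "density"  # density | absolute
    edge_density: float = 0.33
    edge_tau: Optional[float] = None
    # spectral
    welch_segment_s: float = 1.0
    welch_overlap_frac: float = 0.5
    welch_window: str = "hamming"
    psd_band_hz: Tuple[float, float] = (30.0, 50.0)
    # bookkeeping
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_hz = tuple(self.band_hz)  # type: ignore[assignment]
        self.gamma_hz = tuple(self.gamma_hz)  # type: ignore[assignment]
        self.psd_band_hz = tuple(self.psd_band_hz)  # type: ignore[assignment]
        self.core_pairs = tuple(tuple(p) for p in self.core_pairs)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["core_pairs"] = [list(p) for p in self.core_pairs]
        for k in ("band_hz", "gamma_hz", "psd_band_hz"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML or JSON key-value file; kwargs take precedence."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)
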