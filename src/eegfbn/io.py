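"""Readers and writers for recordings, matrices and run artifacts.

Signals are read from EDF (via MNE's native reader), delimited text (one
column per channel with a header row of labels) or NumPy ``.npy`` dumps with
a JSON label sidecar; recordings are written as delimited text or ``.npy``.
Connectivity matrices, PSD tables and screening results are written as
labeled CSV; ground truth and run logs as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .montage import ChannelLayout, Recording, default_layout
from .phase import ConnectivityMatrix
from .screening import ScreeningResult
from .spectral import PSDEstimate
from .synthetic import GroundTruth

__all__ = [
    "read_recording",
    "write_recording_text",
    "write_recording_npy",
    "write_ground_truth",
    "read_ground_truth",
    "connectivity_to_csv",
    "connectivity_from_csv",
    "psd_to_csv",
    "screening_to_csv",
    "write_run_log",
    "save_heatmap",
]

logger = logging.getLogger("eegfbn")

_TEXT_SUFFIXES = {".csv", ".tsv", ".txt"}


def _match_layout(
    found_labels: Tuple[str, ...], data: np.ndarray, layout: ChannelLayout
) -> Recording | Tuple[np.ndarray, list]:
    """Reorder/drop channels to match the target layout (case-insensitive)."""
    lowered = {lb.lower(): k for k, lb in enumerate(found_labels)}
    missing = [ch for ch in layout.labels if ch.lower() not in lowered]
    if missing:
        raise ValueError(f"input is missing required channels: {missing}")
    extra = [
        lb for lb in found_labels if lb.lower() not in {c.lower() for c in layout.labels}
    ]
    if extra:
        logger.warning("dropping %d extra channels: %s", len(extra), extra)
    rows = [lowered[ch.lower()] for ch in layout.labels]
    return data[rows, :]


def read_recording(
    path: str | Path,
    fmt: Optional[str] = None,
    layout: Optional[ChannelLayout] = None,
    fs: Optional[float] = None,
) -> Recording:
    """Read a recording from EDF, delimited text or a binary array dump.

    Channel labels are matched case-insensitively against the layout (the
    19-channel balance montage by default); extra channels are dropped with
    a warning, missing required channels raise an error naming them.  For
    text/binary inputs ``fs`` must be supplied unless a ``<name>.json``
    sidecar stores it.
    """
    path = Path(path)
    layout = layout if layout is not None else default_layout()
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix == ".edf":
            fmt = "edf"
        elif suffix in _TEXT_SUFFIXES:
            fmt = "text"
        elif suffix == ".npy":
            fmt = "binary"
        else:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        labels = tuple(raw.ch_names)
        data = _match_layout(labels, data, layout)
        return Recording(data=data, fs=float(raw.info["sfreq"]), layout=layout)
    if fmt == "text":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        labels = tuple(str(c) for c in df.columns)
        data = df.to_numpy(dtype=float).T
        data = _match_layout(labels, data, layout)
        if fs is None:
            fs = _sidecar_fs(path)
        return Recording(data=data, fs=float(fs), layout=layout)
    if fmt == "binary":
        data = np.load(path)
        sidecar = path.with_suffix(".json")
        labels = layout.labels
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            labels = tuple(meta.get("labels", labels))
            fs = fs if fs is not None else meta.get("fs")
        if fs is None:
            raise ValueError("fs required for binary input (argument or sidecar)")
        data = _match_layout(tuple(labels), np.asarray(data, dtype=float), layout)
        return Recording(data=data, fs=float(fs), layout=layout)
    raise ValueError(f"unknown format {fmt!r}")


def _sidecar_fs(path: Path) -> float:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "fs" in meta:
            return float(meta["fs"])
    raise ValueError("sampling rate unknown: pass fs or provide a JSON sidecar")


def write_recording_text(rec: Recording, path: str | Path) -> Path:
    """One column per channel, header row of labels, plus an fs JSON sidecar."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.DataFrame(rec.data.T, columns=list(rec.layout.labels))
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")
    path.with_suffix(".json").write_text(
        json.dumps({"fs": rec.fs, "labels": list(rec.layout.labels)})
    )
    return path


def write_recording_npy(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    np.save(path, rec.data)
    path.with_suffix(".json").write_text(
        json.dumps({"fs": rec.fs, "labels": list(rec.layout.labels)})
    )
    return path


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(gt.to_dict(), indent=2))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def connectivity_to_csv(fc: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(fc.values, index=list(fc.labels), columns=list(fc.labels))
    df.to_csv(path)
    return path


def connectivity_from_csv(
    path: str | Path, metric: str, layout: Optional[ChannelLayout] = None
) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    layout = layout if layout is not None else default_layout()
    df = df.loc[list(layout.labels), list(layout.labels)]
    return ConnectivityMatrix(values=df.to_numpy(), metric=metric, layout=layout)


def psd_to_csv(psd: PSDEstimate, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(psd.power.T, columns=list(psd.labels))
    df.insert(0, "freq_hz", psd.freqs)
    df.to_csv(path, index=False)
    return path


def screening_to_csv(sr: ScreeningResult, ws, path: str | Path) -> Path:
    """Window index, start sample, score and selected flag."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "window": np.arange(sr.scores.size),
            "start_sample": np.asarray(ws.source_indices),
            "score": sr.scores,
            "selected": sr.selected.astype(int),
        }
    )
    df.to_csv(path, index=False)
    return path


def write_run_log(log: dict, path: str | Path) -> Path:
    path = Path(path)
    import eegfbn

    payload = dict(log)
    payload.setdefault("versions", {})
    payload["versions"].update(
        {"eegfbn": eegfbn.__version__, "numpy": np.__version__}
    )
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def save_heatmap(
    matrix: np.ndarray, labels, path: str | Path, title: str = ""
) -> Path:
    """Simple labeled heatmap (connectivity matrices, PSD summaries)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.asarray(matrix), cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
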