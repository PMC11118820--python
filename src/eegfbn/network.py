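"""Functional brain network construction and regional degree statistics.

Per-window wPLI matrices of the screened window set are averaged into one
functional-connectivity matrix per recording; the matrix is binarized (by
proportional density or an absolute threshold) into a graph whose node
degrees summarize each scalp region, and paired t-tests compare paradigms
against the baseline condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import RunConfig
from .montage import REGIONS, ChannelLayout, Recording
from .phase import ConnectivityMatrix, connectivity_per_window
from .preprocess import WindowSet, bandpass, gamma_band, notch, remove_baseline, segment
from .screening import ScreeningResult, recombine, score_windows, select_windows
from .spectral import PSDEstimate, welch_psd

__all__ = [
    "BrainGraph",
    "ParadigmComparison",
    "average_fc",
    "binarize",
    "region_degree_stats",
    "paired_region_test",
    "build_fbn_pipeline",
    "PipelineResult",
]

logger = logging.getLogger("eegfbn")


def average_fc(per_window: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise arithmetic mean of per-window connectivity matrices."""
    mats = list(per_window)
    if not mats:
        raise ValueError("cannot average an empty list of matrices")
    metric = mats[0].metric
    layout = mats[0].layout
    for m in mats[1:]:
        if m.metric != metric:
            raise ValueError("mixed metrics cannot be averaged")
        if m.layout.labels != layout.labels:
            raise ValueError("mixed layouts cannot be averaged")
    values = np.mean([m.values for m in mats], axis=0)
    flagged = tuple(sorted({ch for m in mats for ch in m.flagged}))
    return ConnectivityMatrix(
        values=values,
        metric=metric,
        layout=layout,
        n_windows_averaged=len(mats),
        flagged=flagged,
    )


def _pair_order(n: int) -> List[Tuple[int, int]]:
    """Fixed lexicographic order of the C(n,2) channel pairs (tie-break)."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass
class BrainGraph:
    """Binary functional brain network with per-region degree statistics."""

    adjacency: np.ndarray
    edge_rule: str
    layout: ChannelLayout
    degrees: np.ndarray = field(init=False)
    strength: np.ndarray = field(default=None)  # type: ignore[assignment]
    region_degree_stats: Dict[str, Tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape[0] != adj.shape[1] or not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be square and symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency diagonal must be empty")
        self.adjacency = adj
        self.degrees = adj.sum(axis=1).astype(int)
        self.region_degree_stats = region_degree_stats(self, self.layout)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.layout.labels)
        labels = self.layout.labels
        for i, j in zip(*np.nonzero(np.triu(self.adjacency, k=1))):
            g.add_edge(labels[i], labels[j])
        return g

    def edge_list(self, weights: Optional[np.ndarray] = None) -> List[Tuple[str, str, float]]:
        labels = self.layout.labels
        out = []
        for i, j in zip(*np.nonzero(np.triu(self.adjacency, k=1))):
            w = float(weights[i, j]) if weights is not None else 1.0
            out.append((labels[i], labels[j], w))
        return out


def binarize(
    fc: ConnectivityMatrix,
    rule: str = "density",
    density: float = 0.33,
    tau: Optional[float] = None,
) -> BrainGraph:
    """Threshold a connectivity matrix into a binary graph.

    * ``rule="density"``: keep the top ``round(density * C(n,2))`` weights as
      edges; ties at the cut are broken by fixed lexicographic channel-pair
      order (earlier pairs win).
    * ``rule="absolute"``: keep every weight >= ``tau``.

    The weighted node strength (row sums of the weight matrix) is retained
    alongside the binary degree.
    """
    n = fc.values.shape[0]
    w = fc.values.copy()
    pairs = _pair_order(n)
    weights = np.array([w[i, j] for i, j in pairs])
    if np.any(np.isnan(weights)):
        raise ValueError(
            f"matrix contains flagged (NaN) pairs for channels {fc.flagged}"
        )
    adj = np.zeros((n, n), dtype=bool)
    if rule == "density":
        if not 0.0 < density <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        k = int(round(density * len(pairs)))
        if k > 0:
            # stable sort on descending weight; lexicographic pair order wins ties
            order = np.argsort(-weights, kind="stable")[:k]
            for idx in order:
                i, j = pairs[idx]
                adj[i, j] = adj[j, i] = True
        rule_desc = f"density(d={density})"
    elif rule == "absolute":
        if tau is None or not 0.0 <= tau <= 1.0:
            raise ValueError("absolute rule needs tau in [0, 1]")
        for idx, (i, j) in enumerate(pairs):
            if weights[idx] >= tau:
                adj[i, j] = adj[j, i] = True
        rule_desc = f"absolute(tau={tau})"
    else:
        raise ValueError(f"unknown edge rule {rule!r}")
    strength = np.where(np.isfinite(w), w, 0.0)
    np.fill_diagonal(strength, 0.0)
    g = BrainGraph(adjacency=adj, edge_rule=rule_desc, layout=fc.layout)
    g.strength = strength.sum(axis=1)
    return g


def region_degree_stats(
    g: BrainGraph, layout: Optional[ChannelLayout] = None
) -> Dict[str, Tuple[float, float]]:
    """Sample mean and SD of node degree within each scalp region."""
    layout = layout if layout is not None else g.layout
    out: Dict[str, Tuple[float, float]] = {}
    for region in REGIONS:
        idx = layout.region_indices(region)
        if idx.size == 0:
            out[region] = (0.0, 0.0)
            continue
        deg = g.degrees[idx]
        sd = float(np.std(deg, ddof=1)) if deg.size > 1 else 0.0
        out[region] = (float(np.mean(deg)), sd)
    return out


@dataclass
class ParadigmComparison:
    """Paired t-test of per-subject region degrees between two conditions."""

    region: str
    t_statistic: float
    p_value: float
    paired_n: int
    mean_a: float
    mean_b: float
    degenerate: bool = False


def paired_region_test(
    cond_a: Mapping[str, float], cond_b: Mapping[str, float], region: str = ""
) -> ParadigmComparison:
    """Two-sided paired t-test on per-subject region mean degrees.

    Subjects present in only one condition are dropped with a warning.  With
    zero-variance, nonzero differences the t statistic is +/-inf and p is
    reported as 0 (flagged ``degenerate``); identical conditions give
    t = 0, p = 1.
    """
    common = sorted(set(cond_a) & set(cond_b))
    dropped = (set(cond_a) | set(cond_b)) - set(common)
    if dropped:
        logger.warning("dropping unpaired subjects: %s", sorted(dropped))
    if len(common) < 2:
        raise ValueError("paired t-test needs at least 2 paired subjects")
    a = np.array([cond_a[s] for s in common], dtype=float)
    b = np.array([cond_b[s] for s in common], dtype=float)
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            t, p, degen = 0.0, 1.0, False
        else:
            t = math.inf if diff.mean() > 0 else -math.inf
            p, degen = 0.0, True
    else:
        res = stats.ttest_rel(a, b)
        t, p, degen = float(res.statistic), float(res.pvalue), False
    return ParadigmComparison(
        region=region,
        t_statistic=t,
        p_value=p,
        paired_n=len(common),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        degenerate=degen,
    )


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    fc: ConnectivityMatrix
    graph: BrainGraph
    screening: ScreeningResult
    psd: PSDEstimate
    windows: WindowSet
    screened: WindowSet
    run_log: dict


def build_fbn_pipeline(rec: Recording, config: Optional[RunConfig] = None) -> PipelineResult:
    """Preprocess -> segment -> screen -> per-window wPLI -> average -> graph.

    Runs the full analysis on one recording and returns every intermediate
    plus a run log of all resolved parameters.
    """
    cfg = config if config is not None else RunConfig()
    rec0 = remove_baseline(rec)
    rec1 = notch(rec0, cfg.notch_hz)
    rec2 = bandpass(rec1, *cfg.band_hz)
    recg = bandpass(rec2, *cfg.gamma_hz)
    ws = segment(recg, cfg.window_s)
    scores = score_windows(
        ws,
        core_pairs=cfg.core_pairs,
        combine=cfg.combine,
        per_window_hilbert=cfg.per_window_hilbert,
    )
    sr = select_windows(
        scores,
        rule=cfg.screen_rule,
        q=cfg.screen_q,
        tau=cfg.screen_tau,
        core_pairs=cfg.core_pairs,
    )
    screened = recombine(ws, sr)
    logger.info(
        "screening kept %d / %d windows (rule %s)", sr.n_selected, ws.n_windows, sr.rule
    )
    mats = connectivity_per_window(
        screened, metric=cfg.fc_metric, per_window_hilbert=cfg.per_window_hilbert
    )
    fc = average_fc(mats)
    graph = binarize(fc, rule=cfg.edge_rule, density=cfg.edge_density, tau=cfg.edge_tau)
    logger.info("graph: %d edges, region degrees %s", graph.n_edges, graph.region_degree_stats)
    psd = welch_psd(
        recg,
        segment_len=int(round(cfg.welch_segment_s * rec.fs)),
        overlap_frac=cfg.welch_overlap_frac,
        window_fn=cfg.welch_window,
    )
    run_log = {
        "config": cfg.to_dict(),
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "fs": rec.fs,
        "n_windows": ws.n_windows,
        "n_selected": sr.n_selected,
        "screen_threshold": sr.threshold_used,
        "n_edges": graph.n_edges,
        "region_degree_stats": {
            r: list(v) for r, v in graph.region_degree_stats.items()
        },
    }
    return PipelineResult(
        fc=fc,
        graph=graph,
        screening=sr,
        psd=psd,
        windows=ws,
        screened=screened,
        run_log=run_log,
    )
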