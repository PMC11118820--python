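import math

import numpy as np
import pytest

from eegfbn import (
    BrainGraph,
    ConnectivityMatrix,
    RunConfig,
    average_fc,
    binarize,
    build_fbn_pipeline,
    default_layout,
    paired_region_test,
    paradigm_preset,
    region_degree_stats,
)
from eegfbn.montage import ChannelLayout


def fc_from(values, metric="wPLI", layout=None):
    layout = layout if layout is not None else default_layout()
    return ConnectivityMatrix(values=values, metric=metric, layout=layout)


def random_fc(seed=0, metric="wPLI"):
    rng = np.random.default_rng(seed)
    n = 19
    m = rng.uniform(0.05, 0.95, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return fc_from(m, metric=metric)


# --- averaging ---


def test_average_of_identical_matrices_is_identity():
    fc = random_fc(0)
    avg = average_fc([fc, fc, fc])
    assert np.allclose(avg.values, fc.values)
    assert avg.n_windows_averaged == 3


def test_average_of_matrix_and_complement():
    fc = random_fc(1)
    comp_values = 1.0 - fc.values
    np.fill_diagonal(comp_values, 0.0)
    avg = average_fc([fc, fc_from(comp_values)])
    off = ~np.eye(19, dtype=bool)
    assert np.allclose(avg.values[off], 0.5)


def test_average_elementwise_mean():
    mats = []
    for v in (0.2, 0.4, 0.9):
        m = np.zeros((19, 19))
        m[0, 1] = m[1, 0] = v
        mats.append(fc_from(m))
    avg = average_fc(mats)
    assert avg.values[0, 1] == pytest.approx(0.5)


def test_average_rejects_empty_and_mixed():
    with pytest.raises(ValueError):
        average_fc([])
    with pytest.raises(ValueError):
        average_fc([random_fc(0, "wPLI"), random_fc(1, "PLV")])


# --- binarization ---


def test_absolute_zero_threshold_gives_complete_graph():
    fc = random_fc(2)
    g = binarize(fc, rule="absolute", tau=0.0)
    assert np.all(g.degrees == 18)
    assert g.n_edges == 171


def test_density_keeping_single_edge():
    fc = random_fc(3)
    g = binarize(fc, rule="density", density=1 / 171)
    assert g.n_edges == 1
    assert sorted(g.degrees)[-2:] == [1, 1] and g.degrees.sum() == 2


def test_three_node_density_ranking():
    layout = ChannelLayout(
        labels=("a", "b", "c"),
        region_of={"a": "frontal", "b": "central", "c": "occipital"},
    )
    vals = np.array([[0.0, 0.9, 0.5], [0.9, 0.0, 0.1], [0.5, 0.1, 0.0]])
    g = binarize(fc_from(vals, layout=layout), rule="density", density=2 / 3)
    # top-2 weights: ab (0.9) and ac (0.5)
    assert g.adjacency[0, 1] and g.adjacency[0, 2] and not g.adjacency[1, 2]
    assert list(g.degrees) == [2, 1, 1]


def test_density_rule_edge_count_and_degree_sum():
    for seed in range(3):
        fc = random_fc(seed + 10)
        for d in (0.1, 0.33, 0.8):
            g = binarize(fc, rule="density", density=d)
            assert g.n_edges == round(d * 171)
            assert g.degrees.sum() == 2 * g.n_edges


def test_density_ties_broken_lexicographically():
    vals = np.full((19, 19), 0.5)
    np.fill_diagonal(vals, 0.0)
    g1 = binarize(fc_from(vals), rule="density", density=2 / 171)
    g2 = binarize(fc_from(vals), rule="density", density=2 / 171)
    assert np.array_equal(g1.adjacency, g2.adjacency)
    # with all weights tied, the first two lexicographic pairs win
    labels = default_layout().labels
    assert g1.adjacency[0, 1] and g1.adjacency[0, 2]


def test_binarize_rejects_bad_parameters():
    fc = random_fc(4)
    with pytest.raises(ValueError):
        binarize(fc, rule="density", density=0.0)
    with pytest.raises(ValueError):
        binarize(fc, rule="absolute", tau=None)
    with pytest.raises(ValueError):
        binarize(fc, rule="top-k")


# --- region degree statistics ---


def test_region_degree_stats_on_known_graphs(layout):
    n = 19
    empty = BrainGraph(np.zeros((n, n), bool), "manual", layout)
    assert all(m == 0.0 and s == 0.0 for m, s in empty.region_degree_stats.values())

    complete = ~np.eye(n, dtype=bool)
    g = BrainGraph(complete, "manual", layout)
    assert all(m == 18.0 and s == 0.0 for m, s in g.region_degree_stats.values())

    # star from Fz to every frontal channel
    adj = np.zeros((n, n), bool)
    fz = layout.index("Fz")
    for ch in layout.region_channels("frontal"):
        if ch != "Fz":
            adj[fz, layout.index(ch)] = adj[layout.index(ch), fz] = True
    g = BrainGraph(adj, "manual", layout)
    frontal_degrees = [g.degrees[layout.index(c)] for c in layout.region_channels("frontal")]
    mean, sd = g.region_degree_stats["frontal"]
    assert mean == pytest.approx(np.mean(frontal_degrees))
    assert sd == pytest.approx(np.std(frontal_degrees, ddof=1))
    assert g.region_degree_stats["central"] == (0.0, 0.0)


def test_brain_graph_invariants_rejected(layout):
    with pytest.raises(ValueError):
        BrainGraph(np.eye(19, dtype=bool), "manual", layout)  # self loops
    bad = np.zeros((19, 19), bool)
    bad[0, 1] = True  # asymmetric
    with pytest.raises(ValueError):
        BrainGraph(bad, "manual", layout)


def test_graph_exports(layout):
    fc = random_fc(5)
    g = binarize(fc, rule="density", density=0.33)
    nxg = g.to_networkx()
    assert nxg.number_of_nodes() == 19
    assert nxg.number_of_edges() == g.n_edges
    edges = g.edge_list(weights=fc.values)
    assert len(edges) == g.n_edges
    assert all(w > 0 for _, _, w in edges)


# --- paired tests ---


def test_paired_test_identical_conditions():
    a = {f"s{i}": 5.0 + i for i in range(5)}
    res = paired_region_test(a, dict(a), region="frontal")
    assert res.t_statistic == 0.0 and res.p_value == 1.0


def test_paired_test_matches_closed_form():
    diffs = np.array([2.0, -1.0, 3.0, 0.0, 1.0])
    a = {f"s{i}": 10.0 + d for i, d in enumerate(diffs)}
    b = {f"s{i}": 10.0 for i in range(5)}
    res = paired_region_test(a, b)
    expected_t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(diffs.size))
    assert res.t_statistic == pytest.approx(expected_t, rel=1e-12)
    assert res.paired_n == 5


def test_paired_test_zero_variance_differences_flagged():
    a = {f"s{i}": 3.0 for i in range(4)}
    b = {f"s{i}": 2.0 for i in range(4)}
    res = paired_region_test(a, b)
    assert math.isinf(res.t_statistic) and res.t_statistic > 0
    assert res.p_value == 0.0 and res.degenerate


def test_paired_test_drops_unpaired_subjects():
    a = {"s1": 1.0, "s2": 2.0, "s3": 3.0}
    b = {"s2": 2.5, "s3": 2.0, "s4": 9.0}
    res = paired_region_test(a, b)
    assert res.paired_n == 2
    with pytest.raises(ValueError):
        paired_region_test({"s1": 1.0}, {"s1": 2.0})


# --- pipeline ---


def test_pipeline_builds_19_node_network_deterministically():
    rec, _ = paradigm_preset("P2", seed=3, duration_s=20)
    cfg = RunConfig()
    res1 = build_fbn_pipeline(rec, cfg)
    res2 = build_fbn_pipeline(rec, cfg)
    assert res1.fc.values.shape == (19, 19)
    assert res1.graph.adjacency.shape == (19, 19)
    assert res1.fc.offdiag_values().size == 171
    assert np.array_equal(res1.fc.values, res2.fc.values)
    assert np.array_equal(res1.graph.adjacency, res2.graph.adjacency)
    assert res1.run_log["n_windows"] == 100
    assert res1.run_log["n_selected"] == 30  # q = 0.3
    assert 0 <= res1.screening.threshold_used <= 1


def test_pipeline_recovers_blocked_vision_pattern():
    rec, _ = paradigm_preset("P2", seed=0, duration_s=40)
    res = build_fbn_pipeline(rec)
    stats = res.graph.region_degree_stats
    assert stats["frontal"][0] > stats["occipital"][0]
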