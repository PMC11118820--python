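import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfbn import (
    AnalyticWindow,
    DegenerateChannelError,
    PhaseDiffSeries,
    analytic_signal,
    pairwise_matrix,
    phase_difference,
    pli,
    plv,
    wpli,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops over the defining formulas)
# ---------------------------------------------------------------------------


def plv_brute(theta):
    acc = 0 + 0j
    for t in theta:
        acc += cmath.exp(1j * t)
    return abs(acc / len(theta))


def pli_brute(theta):
    acc = 0.0
    for t in theta:
        s = math.sin(t)
        acc += (s > 0) - (s < 0)
    return abs(acc / len(theta))


def wpli_brute(z1, z2):
    num = 0.0
    den = 0.0
    for a, b in zip(z1, z2):
        im = (a * b.conjugate()).imag
        num += im
        den += abs(im)
    return 0.0 if den == 0.0 else abs(num) / den


def window_from_phases(phases, amplitudes=None, fs=1000.0, labels=("s1", "s2")):
    phases = np.asarray(phases, dtype=float)
    amp = np.ones_like(phases) if amplitudes is None else np.asarray(amplitudes)
    return AnalyticWindow(analytic=amp * np.exp(1j * phases), fs=fs, labels=labels)


# ---------------------------------------------------------------------------
# analytic signal
# ---------------------------------------------------------------------------


def test_analytic_signal_of_cosine_matches_closed_form():
    """cos(2*pi*40 t) -> unit amplitude, phase advancing 2*pi*40/fs per sample."""
    fs, f = 1000.0, 40.0
    t = np.arange(int(fs)) / fs
    aw = analytic_signal(np.cos(2 * math.pi * f * t)[None, :], fs)
    inner = slice(100, 900)  # interior 80%
    amp = aw.amplitude[0, inner]
    assert np.sqrt(np.mean((amp - 1.0) ** 2)) < 0.01
    dphi = np.angle(np.exp(1j * np.diff(aw.phase[0, inner])))
    expected = 2 * math.pi * f / fs
    assert np.sqrt(np.mean((dphi - expected) ** 2)) < 0.01 * expected


def test_analytic_signal_of_sine_is_quarter_cycle_shifted():
    fs, f = 1000.0, 40.0
    t = np.arange(int(fs)) / fs
    aw = analytic_signal(
        np.vstack([np.cos(2 * math.pi * f * t), np.sin(2 * math.pi * f * t)]), fs
    )
    inner = slice(100, 900)
    assert np.sqrt(np.mean((aw.amplitude[1, inner] - 1.0) ** 2)) < 0.01
    diff = np.angle(np.exp(1j * (aw.phase[1, inner] - aw.phase[0, inner])))
    assert np.allclose(diff, -math.pi / 2, atol=0.02)


def test_constant_channel_is_flagged_degenerate():
    aw = analytic_signal(np.vstack([np.full(100, 3.0), np.sin(np.arange(100.0))]), 100.0)
    assert aw.degenerate[0] and not aw.degenerate[1]
    with pytest.raises(DegenerateChannelError):
        phase_difference(aw, ("ch0", "ch1"))


def test_analytic_signal_rejects_bad_input():
    with pytest.raises(ValueError):
        analytic_signal(np.zeros((1, 1)), 100.0)
    with pytest.raises(ValueError):
        analytic_signal(np.array([[np.nan, 1.0]]), 100.0)


# ---------------------------------------------------------------------------
# phase difference
# ---------------------------------------------------------------------------


def test_phase_difference_examples():
    phases = np.vstack([np.linspace(0, 4, 50), np.linspace(0, 4, 50) - math.pi / 2])
    aw = window_from_phases(phases)
    assert np.allclose(phase_difference(aw, ("s1", "s1")).theta, 0.0)
    assert np.allclose(phase_difference(aw, ("s1", "s2")).theta, math.pi / 2)


def test_phase_difference_wraps_into_half_open_interval():
    # phi1 - phi2 = 3*pi/2 must wrap to -pi/2
    aw = window_from_phases(np.vstack([np.full(10, 3 * math.pi / 2), np.zeros(10)]))
    assert np.allclose(phase_difference(aw, ("s1", "s2")).theta, -math.pi / 2)


def test_phase_difference_unknown_channel():
    aw = window_from_phases(np.zeros((2, 10)))
    with pytest.raises(KeyError):
        phase_difference(aw, ("s1", "nope"))


# ---------------------------------------------------------------------------
# PLV / PLI / wPLI examples
# ---------------------------------------------------------------------------


def test_plv_examples():
    const = PhaseDiffSeries(np.full(100, 0.7), ("a", "b"))
    assert plv(const).value == pytest.approx(1.0, abs=1e-12)
    alternating = PhaseDiffSeries(np.array([0.0, math.pi] * 10), ("a", "b"))
    assert plv(alternating).value == pytest.approx(0.0, abs=1e-12)
    quadrants = PhaseDiffSeries(np.array([0, math.pi / 2, math.pi, 3 * math.pi / 2]), ("a", "b"))
    assert plv(quadrants).value == pytest.approx(plv_brute(quadrants.theta), abs=1e-12)
    assert plv(quadrants).value == pytest.approx(0.0, abs=1e-12)


def test_pli_examples():
    assert pli(PhaseDiffSeries(np.full(10, math.pi / 2), ("a", "b"))).value == 1.0
    sym = PhaseDiffSeries(np.array([math.pi / 4, -math.pi / 4] * 5), ("a", "b"))
    assert pli(sym).value == pytest.approx(0.0, abs=1e-12)
    three = PhaseDiffSeries(np.array([math.pi / 4, math.pi / 4, -math.pi / 4]), ("a", "b"))
    assert three.theta.size == 3
    assert pli(three).value == pytest.approx(1.0 / 3.0, abs=1e-12)
    assert pli(three).signed == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_wpli_examples():
    # constant quarter-cycle lag, equal amplitudes -> 1
    aw = window_from_phases(
        np.vstack([np.linspace(0, 3, 20), np.linspace(0, 3, 20) - math.pi / 2])
    )
    assert wpli(aw, ("s1", "s2")).value == pytest.approx(1.0, abs=1e-12)
    # identical channels: Im X == 0 -> defined as 0
    same = window_from_phases(np.vstack([np.linspace(0, 3, 20)] * 2))
    assert wpli(same, ("s1", "s2")).value == 0.0
    # Im X samples {+2, +1, -1} -> (2+1-1)/(2+1+1) = 0.5
    z2 = np.exp(1j * np.zeros(3))
    z1 = np.array([2j, 1j, -1j]) + 0.0
    aw3 = AnalyticWindow(np.vstack([z1, z2]), 1000.0, ("s1", "s2"))
    imx = np.imag(z1 * np.conj(z2))
    assert np.allclose(imx, [2, 1, -1])
    assert wpli(aw3, ("s1", "s2")).value == pytest.approx(0.5, abs=1e-12)
    assert wpli(aw3, ("s1", "s2")).value == pytest.approx(wpli_brute(z1, z2), abs=1e-12)


# ---------------------------------------------------------------------------
# oracle equivalence on tiny random windows
# ---------------------------------------------------------------------------


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=16),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_metrics_equal_brute_force_on_tiny_windows(n, seed):
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-math.pi, math.pi, size=(2, n))
    amps = rng.uniform(0.1, 3.0, size=(2, n))
    aw = window_from_phases(phases, amplitudes=amps)
    theta = phase_difference(aw, ("s1", "s2"))
    assert plv(theta).value == pytest.approx(plv_brute(theta.theta), abs=1e-12)
    assert pli(theta).value == pytest.approx(pli_brute(theta.theta), abs=1e-12)
    assert wpli(aw, ("s1", "s2")).value == pytest.approx(
        wpli_brute(aw.analytic[0], aw.analytic[1]), abs=1e-12
    )


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    rotation=st.floats(min_value=-math.pi, max_value=math.pi),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_metrics_invariant_to_global_phase_rotation(rotation, seed):
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-math.pi, math.pi, size=(2, 32))
    amps = rng.uniform(0.5, 2.0, size=(2, 32))
    a = window_from_phases(phases, amps)
    b = window_from_phases(phases + rotation, amps)
    ta, tb = phase_difference(a, ("s1", "s2")), phase_difference(b, ("s1", "s2"))
    assert plv(ta).value == pytest.approx(plv(tb).value, abs=1e-12)
    assert pli(ta).value == pytest.approx(pli(tb).value, abs=1e-12)
    assert wpli(a, ("s1", "s2")).value == pytest.approx(
        wpli(b, ("s1", "s2")).value, abs=1e-12
    )


def test_plv_amplitude_invariant_wpli_amplitude_weighted():
    rng = np.random.default_rng(7)
    n = 256
    # mixed-sign lags so amplitude weighting has something to bite on
    theta = rng.choice([math.pi / 3, -math.pi / 6], size=n)
    phases = np.vstack([np.zeros(n), -theta])
    flat = window_from_phases(phases)
    # weight positive-lag samples more heavily
    amp2 = 1.0 + 0.9 * (np.sin(theta) > 0)
    weighted = window_from_phases(phases, amplitudes=np.vstack([np.ones(n), amp2]))
    t_flat = phase_difference(flat, ("s1", "s2"))
    t_weighted = phase_difference(weighted, ("s1", "s2"))
    assert plv(t_flat).value == pytest.approx(plv(t_weighted).value, abs=1e-12)
    # constant rescale leaves wPLI alone ...
    scaled = window_from_phases(phases, amplitudes=np.full((2, n), 2.5))
    assert wpli(flat, ("s1", "s2")).value == pytest.approx(
        wpli(scaled, ("s1", "s2")).value, abs=1e-12
    )
    # ... but amplitude-lag covariance moves it
    assert abs(
        wpli(weighted, ("s1", "s2")).value - wpli(flat, ("s1", "s2")).value
    ) > 0.05


# ---------------------------------------------------------------------------
# pairwise matrices
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("metric,diag", [("PLV", 1.0), ("PLI", 0.0), ("wPLI", 0.0)])
def test_pairwise_matrix_shape_symmetry_diagonal(metric, diag, layout):
    rng = np.random.default_rng(0)
    aw = AnalyticWindow(
        np.exp(1j * rng.uniform(-math.pi, math.pi, size=(19, 64))),
        1000.0,
        layout.labels,
    )
    m = pairwise_matrix(aw, metric, layout=layout)
    assert m.values.shape == (19, 19)
    assert np.allclose(m.values, m.values.T, atol=1e-12)
    assert np.allclose(np.diag(m.values), diag)
    assert m.offdiag_values().size == 171  # C(19, 2)


def test_pairwise_matrix_three_channels():
    rng = np.random.default_rng(1)
    aw = AnalyticWindow(
        np.exp(1j * rng.uniform(-math.pi, math.pi, size=(3, 32))),
        1000.0,
        ("a", "b", "c"),
    )
    m = pairwise_matrix(aw, "PLV")
    assert m.offdiag_values().size == 3
    # entries match the scalar implementation
    for pair in (("a", "b"), ("a", "c"), ("b", "c")):
        expected = plv(phase_difference(aw, pair)).value
        assert m.pair_value(*pair) == pytest.approx(expected, abs=1e-12)


def test_pairwise_matrix_matches_scalar_wpli_and_pli():
    rng = np.random.default_rng(2)
    amp = rng.uniform(0.2, 2.0, size=(4, 50))
    aw = AnalyticWindow(
        amp * np.exp(1j * rng.uniform(-math.pi, math.pi, size=(4, 50))),
        1000.0,
        ("a", "b", "c", "d"),
    )
    mw = pairwise_matrix(aw, "wPLI")
    mp = pairwise_matrix(aw, "PLI")
    for pair in (("a", "b"), ("b", "d"), ("c", "d")):
        assert mw.pair_value(*pair) == pytest.approx(wpli(aw, pair).value, abs=1e-12)
        assert mp.pair_value(*pair) == pytest.approx(
            pli(phase_difference(aw, pair)).value, abs=1e-12
        )


def test_degenerate_channel_rows_flagged_not_zeroed():
    sig = np.vstack([np.zeros(64), np.sin(np.arange(64) * 0.3), np.cos(np.arange(64) * 0.3)])
    aw = analytic_signal(sig, 100.0, ("dead", "s1", "s2"))
    m = pairwise_matrix(aw, "PLV")
    assert m.flagged == ("dead",)
    assert np.isnan(m.values[0, 1]) and np.isnan(m.values[2, 0])
    assert np.isfinite(m.values[1, 2])
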