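"""Distance profiles, trough extraction, decay/propagation fits, comparisons."""

import numpy as np
import pytest

from unitlfp.errors import EmptyResultError, FitError
from unitlfp.geometry import distance_shells, electrode_distance_mm
from unitlfp.profiles import (
    DistanceProfile,
    ExpDecayFit,
    bootstrap_difference,
    compare_space_constants,
    distance_profile,
    find_trough,
    fit_exp_decay,
    fit_propagation,
    population_average,
)
from unitlfp.stlfp import StLfpMap

from conftest import square_geometry


def _map_from_values(geometry, value_of_channel, trigger, n_lags=32):
    chans = [c for c in geometry.live_channels if c != trigger]
    lag = (np.arange(n_lags) - n_lags // 2) * 0.8
    traces = np.array(
        [np.full(n_lags, 0.0) - value_of_channel(c) * np.exp(-((lag / 4.0) ** 2)) for c in chans]
    )
    return StLfpMap(
        trigger_unit="u0",
        channels=chans,
        traces=traces,
        lag_axis_ms=lag,
        n_spikes_used=2000,
        excluded_channel=trigger,
    )


def test_profile_constant_map(geom4):
    m = _map_from_values(geom4, lambda c: 1.0, trigger=5)
    p = distance_profile(m, geom4, 5)
    assert np.all(np.diff(p.distances_mm) > 0)
    np.testing.assert_allclose(p.trough_amp, -1.0, atol=1e-12)


def test_profile_exponential_map_exact(geom4):
    lam = 0.5
    m = _map_from_values(
        geom4, lambda c: np.exp(-electrode_distance_mm(geom4, 5, c) / lam), trigger=5
    )
    p = distance_profile(m, geom4, 5)
    np.testing.assert_allclose(np.abs(p.trough_amp), np.exp(-p.distances_mm / lam), rtol=1e-10)


def test_profile_matches_loop_oracle(geom4, rng):
    vals = {c: rng.normal() for c in geom4.live_channels}
    m = _map_from_values(geom4, lambda c: vals[c], trigger=5)
    p = distance_profile(m, geom4, 5, max_mm=2.4)
    shells = distance_shells(geom4, 5, 2.4)
    for d, tr in zip(p.distances_mm, p.traces):
        members = sorted(shells[round(float(d), 9)])
        expected = np.mean([m.traces[m.channels.index(c)] for c in members], axis=0)
        np.testing.assert_allclose(tr, expected, atol=1e-12)
        assert p.n_electrodes[list(p.distances_mm).index(d)] == len(members)


@pytest.mark.parametrize(
    "trace_fn, expected_amp, expected_lat",
    [
        # -cos has its interior minimum exactly at lag 0
        (lambda t: -np.cos(2 * np.pi * t / 30.0), -1.0, 0.0),
        # monotone decreasing: trough pinned to the right window edge
        (lambda t: -t, -15.0, 15.0),
    ],
)
def test_find_trough_examples(trace_fn, expected_amp, expected_lat):
    lags = np.arange(-40, 41) * 1.0  # 1 ms steps
    amp, lat = find_trough(trace_fn(lags), lags)
    assert amp == pytest.approx(expected_amp, abs=1e-9)
    assert lat == pytest.approx(expected_lat)


def test_find_trough_tie_breaks_earliest():
    lags = np.arange(-10, 16) * 1.0
    tr = np.zeros_like(lags)
    tr[lags == 2.0] = -5.0
    tr[lags == 6.0] = -5.0
    amp, lat = find_trough(tr, lags)
    assert (amp, lat) == (-5.0, 2.0)


def test_fit_exp_decay_noiseless_exact():
    x = np.arange(1, 9) * 0.4
    y = 10.0 * np.exp(-x / 0.44) + 1.0
    fit = fit_exp_decay(x, y)
    assert fit.A == pytest.approx(10.0, abs=1e-6)
    assert fit.lambda_mm == pytest.approx(0.44, abs=1e-6)
    assert fit.C == pytest.approx(1.0, abs=1e-6)
    assert fit.rss < 1e-12
    assert not fit.unreliable


def test_fit_exp_decay_constant_data_flagged():
    x = np.arange(1, 9) * 0.4
    fit = fit_exp_decay(x, np.full(8, 3.0))
    assert fit.unreliable


def test_fit_exp_decay_needs_four_points():
    with pytest.raises(FitError):
        fit_exp_decay(np.array([0.4, 0.8, 1.2]), np.array([3.0, 2.0, 1.0]))


def test_fit_exp_decay_recovers_under_noise():
    """Median fitted lambda within 10% of truth over 200 noisy replicates."""
    x = np.arange(1, 9) * 0.4
    true = 10.0 * np.exp(-x / 0.44) + 1.0
    rng = np.random.default_rng(2024)
    lams = []
    for _ in range(200):
        y = true * (1.0 + 0.05 * rng.standard_normal(x.size))
        lams.append(fit_exp_decay(x, y).lambda_mm)
    assert abs(np.median(lams) - 0.44) < 0.1 * 0.44


def test_fit_propagation_exact_line():
    x = np.arange(1, 7) * 0.4
    fit = fit_propagation(x, x / 0.2 + 1.5)
    assert fit.speed_defined
    assert fit.speed_m_per_s == pytest.approx(0.2, rel=1e-9)
    assert fit.intercept_ms == pytest.approx(1.5)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_propagation_flat_or_inverted_undefined():
    x = np.arange(1, 7) * 0.4
    assert not fit_propagation(x, np.full(6, 3.0)).speed_defined
    assert not fit_propagation(x, -x / 0.2).speed_defined
    with pytest.raises(FitError):
        fit_propagation(np.array([0.4, 0.4, 0.4]), np.array([1.0, 2.0, 3.0]))


def test_fit_propagation_recovers_under_noise():
    """Median recovered speed within 15% over 100 noisy replicates."""
    x = np.arange(1, 7) * 0.4
    rng = np.random.default_rng(77)
    speeds = []
    for _ in range(100):
        lat = x / 0.2 + 0.4 * rng.standard_normal(x.size)
        f = fit_propagation(x, lat)
        if f.speed_defined:
            speeds.append(f.speed_m_per_s)
    assert abs(np.median(speeds) - 0.2) < 0.15 * 0.2


def test_bootstrap_identical_groups_high_p(rng):
    g = rng.normal(size=12)
    p = bootstrap_difference(g, g, n_boot=1000, seed=5)
    assert p > 0.5


def test_bootstrap_separated_groups_small_p():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=20)
        b = rng.normal(3.0, 1.0, size=20)
        if bootstrap_difference(a, b, n_boot=1000, seed=seed) < 0.01:
            hits += 1
    assert hits >= 19  # >= 95% of runs


def test_bootstrap_label_symmetry(rng):
    a = rng.normal(0.0, 1.0, size=10)
    b = rng.normal(1.0, 1.0, size=10)
    p_ab = bootstrap_difference(a, b, n_boot=2000, seed=9)
    p_ba = bootstrap_difference(b, a, n_boot=2000, seed=9)
    assert abs(p_ab - p_ba) < 0.05


def test_bootstrap_stability_in_n_boot(rng):
    a = rng.normal(0.0, 1.0, size=15)
    b = rng.normal(0.8, 1.0, size=15)
    p1 = bootstrap_difference(a, b, n_boot=1000, seed=3)
    p2 = bootstrap_difference(a, b, n_boot=2000, seed=3)
    assert abs(p1 - p2) < 0.02


def test_bootstrap_requires_three_per_group():
    with pytest.raises(EmptyResultError):
        bootstrap_difference([1.0, 2.0], [1.0, 2.0, 3.0])


def _fit(lam, sd):
    return ExpDecayFit(A=1.0, lambda_mm=lam, C=0.0, sd_A=0.0, sd_lambda=sd, sd_C=0.0, rss=0.0)


def test_compare_space_constants_hand_values():
    # z = 0.2 / sqrt(2e-4) = 14.14 -> p << 0.001
    assert compare_space_constants(_fit(0.5, 0.01), _fit(0.7, 0.01)) < 1e-6
    # z = 0.1 / 0.2828 = 0.354 -> p = 0.72 > 0.05
    p = compare_space_constants(_fit(0.5, 0.2), _fit(0.6, 0.2))
    assert p == pytest.approx(0.7236, abs=0.01)
    assert compare_space_constants(_fit(0.5, 0.1), _fit(0.5, 0.1)) == pytest.approx(1.0)


def test_compare_space_constants_refuses_unreliable():
    bad = _fit(0.5, 0.1)
    bad.unreliable = True
    with pytest.raises(FitError, match="unreliable"):
        compare_space_constants(bad, _fit(0.5, 0.1))


def _profile(distances, amps, n_spikes=2000, cell_type="FS"):
    d = np.asarray(distances, dtype=float)
    lags = np.array([-1.0, 0.0, 1.0])
    traces = np.array([[0.0, a, 0.0] for a in amps], dtype=float)
    return DistanceProfile(
        distances_mm=d,
        traces=traces,
        lag_axis_ms=lags,
        n_electrodes=np.ones(d.size, dtype=int),
        trough_amp=np.asarray(amps, dtype=float),
        trough_latency_ms=np.zeros(d.size),
        n_spikes=n_spikes,
        cell_type=cell_type,
    )


def test_population_average_filters_and_averages():
    d = [0.4, 0.8]
    p1 = _profile(d, [-2.0, -1.0])
    p2 = _profile(d, [2.0, 1.0])
    p_small = _profile(d, [-99.0, -99.0], n_spikes=10)  # below the threshold
    pop = population_average([p1, p2, p_small], min_spikes=1000)
    assert pop.n_neurons == 2
    np.testing.assert_allclose(pop.traces[:, 1], 0.0, atol=1e-12)  # cancellation
    pop_same = population_average([p1, p1], min_spikes=1000)
    np.testing.assert_allclose(pop_same.traces, p1.traces)
    with pytest.raises(EmptyResultError):
        population_average([p_small], min_spikes=1000)
    with pytest.raises(EmptyResultError):
        population_average([p1], min_spikes=1000, cell_type="RS")
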