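"""Spike-triggered averaging: exactness, bands, surrogates, grid infill."""

import numpy as np
import pytest

from unitlfp.errors import DataError, EmptyResultError
from unitlfp.stlfp import (
    StLfpMap,
    compute_stlfp,
    fill_missing_channels,
    jitter_surrogates,
    sem_band,
)

from conftest import square_geometry


def _template_session(make_session, n_ch=4, fs=1250.0, n_spikes=100):
    """LFP that repeats a fixed template around regularly spaced spikes."""
    rng = np.random.default_rng(7)
    template = rng.normal(size=(n_ch, 251))
    spikes = 0.2 + 0.4 * np.arange(n_spikes)
    n_samples = int((spikes[-1] + 0.3) * fs)
    lfp = np.zeros((n_ch, n_samples))
    for t in spikes:
        i = int(round(t * fs))
        lfp[:, i - 125 : i + 126] += template
    return make_session(lfp, spikes, fs), template


def test_identical_segments_recover_template(make_session):
    ses, template = _template_session(make_session)
    m = compute_stlfp(ses, "u0", (100.0, 100.0))
    # trigger channel (0) excluded; remaining rows equal the template exactly
    assert m.channels == [1, 2, 3]
    np.testing.assert_allclose(m.traces, template[1:], atol=1e-12)
    assert m.n_spikes_used == 100
    assert 0.0 in m.lag_axis_ms


def test_single_spike_equals_segment(make_session, rng):
    lfp = rng.normal(size=(4, 2500))
    ses = make_session(lfp, [1.0])
    m = compute_stlfp(ses, "u0", (100.0, 100.0))
    i = 1250
    np.testing.assert_array_equal(m.traces, lfp[1:, i - 125 : i + 126])


def test_matches_naive_loop_oracle(make_session):
    """Vectorized st-LFP equals a per-spike loop on random sessions."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n_ch = int(rng.integers(2, 6))
        lfp = rng.normal(size=(n_ch, 4000))
        n_sp = int(rng.integers(3, 30))
        spikes = np.sort(rng.uniform(0.3, 2.8, size=n_sp))
        spikes = spikes[np.diff(spikes, prepend=-1) > 1e-4]
        ses = make_session(lfp, spikes)
        m = compute_stlfp(ses, "u0", (20.0, 20.0))
        pre = post = 25  # 20 ms at 1250 Hz
        acc = np.zeros((n_ch - 1, pre + post + 1))
        for t in spikes:
            i = int(np.rint(t * 1250.0))
            acc += lfp[1:, i - pre : i + post + 1]
        np.testing.assert_allclose(m.traces, acc / len(spikes), rtol=0, atol=1e-13)


def test_linearity_in_lfp(make_session, rng):
    spikes = np.linspace(0.5, 2.5, 20)
    a = rng.normal(size=(3, 4000))
    b = rng.normal(size=(3, 4000))
    ma = compute_stlfp(make_session(a, spikes), "u0")
    mb = compute_stlfp(make_session(b, spikes), "u0")
    mab = compute_stlfp(make_session(a + b, spikes), "u0")
    np.testing.assert_allclose(mab.traces, ma.traces + mb.traces, atol=1e-12)


def test_time_shift_covariance(make_session, rng):
    """Shifting spikes and LFP together leaves the st-LFP unchanged."""
    fs = 1250.0
    lfp = rng.normal(size=(3, 4000))
    # quarter-sample offsets keep the nearest-sample rounding away from the
    # knife-edge .5 cases, which float arithmetic could resolve differently
    # before and after the shift
    spikes = (np.sort(rng.choice(np.arange(700, 2400), 15, replace=False)) + 0.25) / fs
    shift = 160  # samples
    m0 = compute_stlfp(make_session(lfp, spikes, fs), "u0", (50.0, 50.0))
    shifted = np.roll(lfp, shift, axis=1)
    m1 = compute_stlfp(
        make_session(shifted, spikes + shift / fs, fs), "u0", (50.0, 50.0)
    )
    np.testing.assert_allclose(m0.traces, m1.traces, atol=1e-12)


def test_noise_averaging_shrinks_sqrt_n(make_session):
    """White LFP independent of 1000 spikes: amplitude shrinks ~sqrt(1000)."""
    rng = np.random.default_rng(3)
    lfp = rng.normal(size=(2, 700_000))
    spikes = np.arange(1000) * 0.5 + 0.25
    m = compute_stlfp(make_session(lfp, spikes), "u0", (20.0, 20.0))
    # single-segment noise amplitude is ~1; the mean of 1000 should sit at
    # ~1/sqrt(1000) ~ 0.032 with max-statistics inflation over 51 lags
    peak = np.abs(m.traces).max()
    assert 0.01 < peak < 4.0 / np.sqrt(1000)


def test_window_clipping_and_excluded_intervals(make_session, rng):
    lfp = rng.normal(size=(3, 2500))  # 2 s
    spikes = [0.02, 0.5, 1.0, 1.5, 1.99]  # first and last clip the window
    ses = make_session(lfp, spikes, excluded_intervals=[(0.9, 1.1)])
    m = compute_stlfp(ses, "u0", (100.0, 100.0))
    assert m.n_spikes_used == 2  # 0.5 and 1.5 only


def test_zero_usable_spikes_raises(make_session, rng):
    lfp = rng.normal(size=(3, 2500))
    ses = make_session(lfp, [0.01])
    with pytest.raises(EmptyResultError, match="u0"):
        compute_stlfp(ses, "u0", (100.0, 100.0))


def test_sem_band_hand_example():
    segs = np.array([[0.0], [2.0]])
    low, high = sem_band(segs)
    # mean 1, SD sqrt(2), sem 1 -> half-width exactly 1.96
    assert low[0] == pytest.approx(1 - 1.96)
    assert high[0] == pytest.approx(1 + 1.96)


def test_sem_band_zero_width_for_identical_and_large_n(rng):
    segs = np.ones((5, 7))
    low, high = sem_band(segs)
    np.testing.assert_allclose(high - low, 0.0)
    x = rng.normal(size=(40000, 1))
    low, high = sem_band(x)
    assert (high[0] - low[0]) / 2 == pytest.approx(1.96 / np.sqrt(40000), rel=0.02)
    with pytest.raises(DataError):
        sem_band(np.ones((1, 3)))


def test_jitter_zero_sd_gives_zero_width_band(make_session, rng):
    lfp = rng.normal(size=(3, 5000))
    spikes = np.linspace(0.5, 3.5, 30)
    ses = make_session(lfp, spikes)
    m = compute_stlfp(ses, "u0", (20.0, 20.0))
    low, high = jitter_surrogates(ses, "u0", (20.0, 20.0), n_rep=100, jitter_sd_s=0.0, seed=0)
    np.testing.assert_allclose(low, m.traces, atol=1e-12)
    np.testing.assert_allclose(high, m.traces, atol=1e-12)


def test_jitter_deterministic_given_seed(make_session, rng):
    lfp = rng.normal(size=(3, 5000))
    ses = make_session(lfp, np.linspace(0.5, 3.5, 30))
    b1 = jitter_surrogates(ses, "u0", (20.0, 20.0), n_rep=100, seed=42)
    b2 = jitter_surrogates(ses, "u0", (20.0, 20.0), n_rep=100, seed=42)
    np.testing.assert_array_equal(b1[0], b2[0])
    b3 = jitter_surrogates(ses, "u0", (20.0, 20.0), n_rep=100, seed=43)
    assert not np.array_equal(b1[0], b3[0])


def _map_on(geometry, values_by_channel):
    chans = sorted(values_by_channel)
    traces = np.array([[values_by_channel[c], values_by_channel[c]] for c in chans])
    return StLfpMap(
        trigger_unit="u0",
        channels=chans,
        traces=traces.astype(float),
        lag_axis_ms=np.array([0.0, 0.8]),
        n_spikes_used=10,
        excluded_channel=-1,
    )


def test_fill_missing_interior_and_corner():
    g = square_geometry(3)
    # channel 4 = (1,1) missing, neighbours 1,3,5,7 have 1,2,3,4
    vals = {0: 9.0, 1: 1.0, 2: 9.0, 3: 2.0, 5: 3.0, 6: 9.0, 7: 4.0, 8: 9.0}
    grid = fill_missing_channels(_map_on(g, vals), g)
    assert grid[1, 1, 0] == pytest.approx(2.5)
    # corner (0,0) missing with neighbours (0,1)=2 and (1,0)=4
    vals2 = {1: 2.0, 3: 4.0, 2: 0.0, 4: 0.0, 5: 0.0, 6: 0.0, 7: 0.0, 8: 0.0}
    grid2 = fill_missing_channels(_map_on(g, vals2), g)
    assert grid2[0, 0, 0] == pytest.approx(3.0)


def test_fill_missing_identity_when_complete():
    g = square_geometry(2)
    vals = {0: 1.0, 1: 2.0, 2: 3.0, 3: 4.0}
    grid = fill_missing_channels(_map_on(g, vals), g)
    np.testing.assert_allclose(grid[:, :, 0], [[1.0, 2.0], [3.0, 4.0]])


def test_map_validation():
    with pytest.raises(DataError, match="contain 0"):
        StLfpMap("u", [1], np.zeros((1, 2)), np.array([1.0, 2.0]), 1, 0)
    with pytest.raises(DataError, match="trigger electrode"):
        StLfpMap("u", [1], np.zeros((1, 2)), np.array([0.0, 0.8]), 1, 1)
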