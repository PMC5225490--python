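"""Spike-triggered LFP averaging.

The spike-triggered LFP (st-LFP) of a unit is the average of short LFP
segments centred on each spike time, computed per channel, giving a
spatio-temporal map (channels x lags).  The electrode that recorded the
trigger unit is excluded from the map to avoid spike-waveform artifacts.

Uncertainty comes in two flavours: parametric +/-1.96 s.e.m. bands over the
spike-segment ensemble, and distribution-free 95% bands from surrogate spike
trains whose times are jittered with Gaussian noise — the jitter destroys
fine spike-LFP locking while preserving slow co-modulation, so exceedances of
the surrogate band mark genuinely spike-locked structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, EmptyResultError, ParameterError
from .geometry import ArrayGeometry
from .session import RecordingSession, SpikeUnit

__all__ = [
    "StLfpMap",
    "compute_stlfp",
    "sem_band",
    "jitter_surrogates",
    "fill_missing_channels",
]


@dataclass
class StLfpMap:
    """Spatio-temporal spike-triggered average for one trigger unit.

    ``traces`` rows follow ``channels`` (live channels minus the trigger
    electrode, which is recorded in ``excluded_channel`` — its row is absent,
    never silently zero).  ``lag_axis_ms`` contains 0 at the spike onset.
    """

    trigger_unit: str
    channels: list[int]
    traces: np.ndarray
    lag_axis_ms: np.ndarray
    n_spikes_used: int
    excluded_channel: int
    sem: np.ndarray | None = None
    surrogate_band: tuple[np.ndarray, np.ndarray] | None = None
    whitened: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_axis_ms) <= 0):
            raise DataError("lag axis must be strictly increasing")
        if not np.isclose(self.lag_axis_ms, 0.0).any():
            raise DataError("lag axis must contain 0 (spike onset)")
        if self.excluded_channel in self.channels:
            raise DataError("trigger electrode must not appear among map channels")
        if self.traces.shape != (len(self.channels), self.lag_axis_ms.size):
            raise DataError("traces shape does not match channels x lags")

    def channel_trace(self, channel: int) -> np.ndarray:
        return self.traces[self.channels.index(channel)]


def _usable_spike_indices(
    session: RecordingSession, unit: SpikeUnit, pre: int, post: int
) -> np.ndarray:
    """Spike sample indices whose full window fits the recording and avoids
    excluded intervals.  Times map to the nearest LFP sample (half-even)."""
    idx = np.rint(unit.spike_times_s * session.fs_hz).astype(np.int64)
    ok = (idx - pre >= 0) & (idx + post < session.n_samples)
    if session.excluded_intervals:
        t0 = (idx - pre) / session.fs_hz
        t1 = (idx + post) / session.fs_hz
        for a, b in session.excluded_intervals:
            ok &= ~((t0 <= b) & (t1 >= a))
    return idx[ok]


def _window_samples(fs_hz: float, window_ms: tuple[float, float]) -> tuple[int, int]:
    pre_ms, post_ms = window_ms
    if pre_ms < 0 or post_ms < 0:
        raise ParameterError("window margins must be non-negative")
    return int(round(pre_ms * fs_hz / 1000.0)), int(round(post_ms * fs_hz / 1000.0))


def _segment_mean_sem(
    lfp: np.ndarray,
    spike_idx: np.ndarray,
    pre: int,
    post: int,
    want_sem: bool,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Streaming mean (and s.e.m.) of LFP segments around spike indices."""
    n_lags = pre + post + 1
    offsets = np.arange(-pre, post + 1)
    n = spike_idx.size
    acc = np.zeros((lfp.shape[0], n_lags))
    acc2 = np.zeros_like(acc) if want_sem else None
    for start in range(0, n, chunk):
        sl = spike_idx[start : start + chunk]
        segs = lfp[:, sl[:, None] + offsets[None, :]]  # (ch, spikes, lags)
        acc += segs.sum(axis=1)
        if want_sem:
            acc2 += (segs**2).sum(axis=1)
    mean = acc / n
    sem = None
    if want_sem:
        if n < 2:
            raise DataError("s.e.m. undefined for fewer than 2 segments")
        var = (acc2 - n * mean**2) / (n - 1)
        sem = np.sqrt(np.maximum(var, 0.0) / n)
    return mean, sem


def compute_stlfp(
    session: RecordingSession,
    unit_id: str,
    window_ms: tuple[float, float] = (100.0, 100.0),
    with_sem: bool = True,
) -> StLfpMap:
    """Average LFP segments around each spike of ``unit_id``.

    ``traces[i, tau] = (1/n_sp) sum_k LFP_i(t_k + tau)``.  Spikes whose window
    leaves the recording or overlaps an excluded interval are dropped and
    ``n_spikes_used`` reflects the count actually averaged.  The trigger
    electrode's row is excluded.
    """
    unit = session.unit(unit_id)
    pre, post = _window_samples(session.fs_hz, window_ms)
    spike_idx = _usable_spike_indices(session, unit, pre, post)
    if spike_idx.size == 0:
        raise EmptyResultError(f"unit {unit_id}: no usable spikes for st-LFP")
    rows = [i for i, ch in enumerate(session.channels) if ch != unit.channel]
    channels = [ch for ch in session.channels if ch != unit.channel]
    lfp = session.lfp[rows]
    mean, sem = _segment_mean_sem(
        lfp, spike_idx, pre, post, want_sem=with_sem and spike_idx.size >= 2
    )
    lag_axis_ms = np.arange(-pre, post + 1) / session.fs_hz * 1000.0
    return StLfpMap(
        trigger_unit=unit_id,
        channels=channels,
        traces=mean,
        lag_axis_ms=lag_axis_ms,
        n_spikes_used=int(spike_idx.size),
        excluded_channel=unit.channel,
        sem=sem,
        meta={"window_ms": tuple(window_ms)},
    )


def sem_band(segments: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- 1.96 s.e.m. band over an ensemble of segments.

    Returns ``(mean - 1.96*sem, mean + 1.96*sem)`` where sem is the sample
    standard deviation (ddof=1) divided by sqrt(n).
    """
    segments = np.asarray(segments, dtype=float)
    n = segments.shape[axis]
    if n < 2:
        raise DataError("s.e.m. band undefined for fewer than 2 segments")
    mean = segments.mean(axis=axis)
    sem = segments.std(axis=axis, ddof=1) / np.sqrt(n)
    return mean - 1.96 * sem, mean + 1.96 * sem


def jitter_surrogates(
    session: RecordingSession,
    unit_id: str,
    window_ms: tuple[float, float] = (100.0, 100.0),
    n_rep: int = 1000,
    jitter_sd_s: float = 0.1,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise 95% band of st-LFPs from Gaussian-jittered spike trains.

    Each repetition adds iid N(0, jitter_sd_s^2) noise to every spike time and
    recomputes the st-LFP; the band is the pointwise 2.5th-97.5th percentile
    across repetitions.  Jittered spikes that fall outside the usable part of
    the recording are dropped for that repetition only.  Deterministic given
    ``seed``.
    """
    if n_rep < 100:
        raise ParameterError("need at least 100 surrogate repetitions")
    unit = session.unit(unit_id)
    pre, post = _window_samples(session.fs_hz, window_ms)
    rows = [i for i, ch in enumerate(session.channels) if ch != unit.channel]
    lfp = session.lfp[rows]
    rng = np.random.default_rng(seed)
    times = unit.spike_times_s
    reps = np.empty((n_rep, lfp.shape[0], pre + post + 1))
    for r in range(n_rep):
        jittered = times + rng.normal(0.0, jitter_sd_s, size=times.size)
        idx = np.rint(jittered * session.fs_hz).astype(np.int64)
        ok = (idx - pre >= 0) & (idx + post < session.n_samples)
        if session.excluded_intervals:
            t0 = (idx - pre) / session.fs_hz
            t1 = (idx + post) / session.fs_hz
            for a, b in session.excluded_intervals:
                ok &= ~((t0 <= b) & (t1 >= a))
        idx = idx[ok]
        if idx.size == 0:
            raise EmptyResultError(
                f"unit {unit_id}: a surrogate repetition has no usable spikes"
            )
        reps[r], _ = _segment_mean_sem(lfp, idx, pre, post, want_sem=False)
    low, high = np.percentile(reps, [2.5, 97.5], axis=0)
    return low, high


def fill_missing_channels(
    stlfp_map: StLfpMap, geometry: ArrayGeometry
) -> np.ndarray:
    """Dense (rows x cols x lags) grid with missing sites infilled.

    Sites without data (dead channels, the excluded trigger electrode,
    unmapped grid positions) receive the mean of their available
    Manhattan-1 neighbours; sites with data are passed through unchanged.
    A site with no live neighbour stays NaN and triggers a warning.  For
    visualisation only — analysis never uses imputed values.
    """
    n_lags = stlfp_map.lag_axis_ms.size
    grid = np.full((geometry.n_rows, geometry.n_cols, n_lags), np.nan)
    have = np.zeros((geometry.n_rows, geometry.n_cols), dtype=bool)
    for ch, trace in zip(stlfp_map.channels, stlfp_map.traces):
        r, c = geometry.position(ch)
        grid[r, c] = trace
        have[r, c] = True
    out = grid.copy()
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            if have[r, c]:
                continue
            neigh = [
                grid[rr, cc]
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if 0 <= rr < geometry.n_rows
                and 0 <= cc < geometry.n_cols
                and have[rr, cc]
            ]
            if neigh:
                out[r, c] = np.mean(neigh, axis=0)
            else:
                warnings.warn(
                    f"grid site ({r}, {c}) has no live neighbour; left as NaN",
                    stacklevel=2,
                )
    return out
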