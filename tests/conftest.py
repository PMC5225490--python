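"""Shared fixtures: small geometries and quickly built sessions."""

import numpy as np
import pytest

from unitlfp.geometry import ArrayGeometry
from unitlfp.session import RecordingSession, SpikeUnit


def square_geometry(n: int, spacing_mm: float = 0.4, dead=()) -> ArrayGeometry:
    grid = {r * n + c: (r, c) for r in range(n) for c in range(n)}
    return ArrayGeometry(
        n_rows=n, n_cols=n, spacing_mm=spacing_mm,
        channel_grid=grid, dead_channels=frozenset(dead),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geom4():
    return square_geometry(4)


@pytest.fixture
def make_session():
    """Factory for small sessions with arbitrary LFP and spike trains."""

    def _make(
        lfp: np.ndarray,
        spike_times_s,
        fs_hz: float = 1250.0,
        geometry: ArrayGeometry | None = None,
        channel: int = 0,
        excluded_intervals=(),
    ) -> RecordingSession:
        n_ch = lfp.shape[0]
        if geometry is None:
            side = int(np.ceil(np.sqrt(n_ch)))
            grid_all = {r * side + c: (r, c) for r in range(side) for c in range(side)}
            grid = dict(list(grid_all.items())[:n_ch])
            geometry = ArrayGeometry(
                n_rows=side, n_cols=side, spacing_mm=0.4, channel_grid=grid
            )
        unit = SpikeUnit(
            unit_id="u0", channel=channel, spike_times_s=np.asarray(spike_times_s)
        )
        return RecordingSession(
            lfp=lfp,
            fs_hz=fs_hz,
            units=[unit],
            geometry=geometry,
            excluded_intervals=list(excluded_intervals),
        )

    return _make
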