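"""Recording-session containers and native on-disk format.

A :class:`RecordingSession` bundles the multichannel LFP, the sorted spike
trains, the array geometry and the sampling metadata.  LFP rows correspond to
the geometry's live (non-dead) channels in sorted channel-id order.

The native format is a directory with three inspectable files::

    session/
      lfp.npy        float array, shape (n_live_channels, n_samples)
      spikes.csv     columns unit_id, time_s
      metadata.json  fs_hz, geometry, excluded intervals, per-unit metadata

Mean spike waveforms are short vectors and live in metadata.json.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .geometry import ArrayGeometry

__all__ = ["SpikeUnit", "RecordingSession", "read_session", "write_session"]

#: labels a unit may carry
UNIT_LABELS = ("FS", "RS", "unknown")


@dataclass
class SpikeUnit:
    """A sorted single unit: spike times plus waveform metadata.

    ``channel`` is the electrode on which the unit was detected; that channel
    is excluded from the unit's spike-triggered averages to avoid spike-shape
    artifacts.  ``mean_waveform`` (if present) is sampled at
    ``waveform_fs_hz``, typically the 30 kHz acquisition rate.
    """

    unit_id: str
    channel: int
    spike_times_s: np.ndarray
    mean_waveform: np.ndarray | None = None
    waveform_fs_hz: float | None = None
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.ndim != 1:
            raise DataError(f"unit {self.unit_id}: spike times must be 1-D")
        if np.any(np.diff(self.spike_times_s) <= 0):
            raise DataError(f"unit {self.unit_id}: spike times must be strictly increasing")
        if self.mean_waveform is not None:
            self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)
            if self.mean_waveform.size < 32:
                raise DataError(
                    f"unit {self.unit_id}: mean waveform has "
                    f"{self.mean_waveform.size} samples, need >= 32"
                )
        if self.label not in UNIT_LABELS:
            raise DataError(f"unit {self.unit_id}: label {self.label!r} not in {UNIT_LABELS}")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass
class RecordingSession:
    """Multichannel LFP + spike trains + geometry + sampling metadata."""

    lfp: np.ndarray
    fs_hz: float
    units: list[SpikeUnit]
    geometry: ArrayGeometry
    excluded_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.lfp.ndim != 2:
            raise DataError("lfp must be 2-D (channels x samples)")
        live = self.geometry.live_channels
        if self.lfp.shape[0] != len(live):
            raise DataError(
                f"lfp has {self.lfp.shape[0]} rows but geometry has "
                f"{len(live)} live channels"
            )
        t_max = self.lfp.shape[1] / self.fs_hz
        for u in self.units:
            if u.n_spikes and (u.spike_times_s[0] < 0 or u.spike_times_s[-1] >= t_max):
                raise DataError(
                    f"unit {u.unit_id}: spike times outside [0, {t_max:.3f}) s"
                )

    @property
    def channels(self) -> list[int]:
        """Live channel ids in LFP row order."""
        return self.geometry.live_channels

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_index(self, channel: int) -> int:
        """Row index of a live channel in the LFP array."""
        try:
            return self.channels.index(channel)
        except ValueError:
            raise DataError(f"channel {channel} is not a live channel of this session")

    def unit(self, unit_id: str) -> SpikeUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise DataError(f"no unit with id {unit_id!r}")


def _geometry_to_dict(g: ArrayGeometry) -> dict:
    return {
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "spacing_mm": g.spacing_mm,
        "channels": [
            {"id": int(ch), "row": int(r), "col": int(c)}
            for ch, (r, c) in sorted(g.channel_grid.items())
        ],
        "dead_channels": sorted(int(c) for c in g.dead_channels),
    }


def _geometry_from_dict(d: dict) -> ArrayGeometry:
    for key in ("n_rows", "n_cols", "spacing_mm", "channels"):
        if key not in d:
            raise FormatError(f"geometry metadata is missing required field {key!r}")
    grid = {int(e["id"]): (int(e["row"]), int(e["col"])) for e in d["channels"]}
    return ArrayGeometry(
        n_rows=int(d["n_rows"]),
        n_cols=int(d["n_cols"]),
        spacing_mm=float(d["spacing_mm"]),
        channel_grid=grid,
        dead_channels=frozenset(int(c) for c in d.get("dead_channels", [])),
    )


def write_session(session: RecordingSession, path: str | Path) -> Path:
    """Write a session to its native directory format; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "lfp.npy", session.lfp)
    rows = [
        {"unit_id": u.unit_id, "time_s": t}
        for u in session.units
        for t in u.spike_times_s
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        path / "spikes.csv", index=False
    )
    meta = {
        "fs_hz": session.fs_hz,
        "geometry": _geometry_to_dict(session.geometry),
        "excluded_intervals": [[float(a), float(b)] for a, b in session.excluded_intervals],
        "units": [
            {
                "unit_id": u.unit_id,
                "channel": int(u.channel),
                "label": u.label,
                "waveform_fs_hz": u.waveform_fs_hz,
                "mean_waveform": (
                    None if u.mean_waveform is None else u.mean_waveform.tolist()
                ),
            }
            for u in session.units
        ],
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session(path: str | Path) -> RecordingSession:
    """Read a session from the native directory format.

    Raises :class:`FormatError` naming the missing field if the metadata is
    incomplete.
    """
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FormatError(f"{path} has no metadata.json")
    meta = json.loads(meta_path.read_text())
    for key in ("fs_hz", "geometry", "units"):
        if key not in meta:
            raise FormatError(f"metadata.json is missing required field {key!r}")
    if "spacing_mm" not in meta["geometry"]:
        raise FormatError("geometry metadata is missing required field 'spacing_mm'")
    geometry = _geometry_from_dict(meta["geometry"])
    lfp = np.load(path / "lfp.npy")
    spikes = pd.read_csv(path / "spikes.csv") if (path / "spikes.csv").exists() else None
    units = []
    for um in meta["units"]:
        if spikes is not None and len(spikes):
            times = spikes.loc[spikes["unit_id"] == um["unit_id"], "time_s"].to_numpy()
        else:
            times = np.empty(0)
        units.append(
            SpikeUnit(
                unit_id=str(um["unit_id"]),
                channel=int(um["channel"]),
                spike_times_s=np.sort(times),
                mean_waveform=(
                    None if um.get("mean_waveform") is None
                    else np.asarray(um["mean_waveform"], dtype=float)
                ),
                waveform_fs_hz=um.get("waveform_fs_hz"),
                label=um.get("label", "unknown"),
            )
        )
    return RecordingSession(
        lfp=lfp,
        fs_hz=float(meta["fs_hz"]),
        units=units,
        geometry=geometry,
        excluded_intervals=[tuple(iv) for iv in meta.get("excluded_intervals", [])],
    )
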