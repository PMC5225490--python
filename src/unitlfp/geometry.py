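"""Electrode-array geometry.

A multielectrode grid (e.g. a 10x10 Utah array with 400 um pitch) is described
by an explicit map from channel id to (row, col) position plus a list of dead
channels.  Distances between electrodes are Manhattan (city-block) distances in
grid steps scaled by the inter-electrode spacing, which is the convention used
when st-LFP traces are pooled over equidistant electrodes: the set of channels
at k steps from a trigger electrode forms the k-th "distance shell".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import GeometryError

__all__ = ["ArrayGeometry", "electrode_distance_mm", "distance_shells", "utah_geometry"]


@dataclass(frozen=True)
class ArrayGeometry:
    """Grid layout of a multielectrode array.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions.
    spacing_mm : float
        Inter-electrode pitch in millimetres; must be positive.
    channel_grid : dict[int, tuple[int, int]]
        Map channel id -> (row, col).  Positions must be unique and in bounds.
    dead_channels : frozenset[int]
        Channels that are wired but unusable; must be a subset of the mapped
        channels.  Dead channels are excluded from analysis, never imputed
        (neighbour-average infill exists for visualisation only).
    """

    n_rows: int
    n_cols: int
    spacing_mm: float
    channel_grid: dict[int, tuple[int, int]]
    dead_channels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise GeometryError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        seen: dict[tuple[int, int], int] = {}
        for ch, (r, c) in self.channel_grid.items():
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise GeometryError(f"channel {ch} position ({r}, {c}) out of bounds")
            if (r, c) in seen:
                raise GeometryError(
                    f"channels {seen[(r, c)]} and {ch} share position ({r}, {c})"
                )
            seen[(r, c)] = ch
        object.__setattr__(self, "dead_channels", frozenset(self.dead_channels))
        missing = self.dead_channels - self.channel_grid.keys()
        if missing:
            raise GeometryError(f"dead channels {sorted(missing)} are not mapped")

    @property
    def live_channels(self) -> list[int]:
        """Sorted mapped channels excluding dead ones."""
        return sorted(self.channel_grid.keys() - self.dead_channels)

    def position(self, channel: int) -> tuple[int, int]:
        try:
            return self.channel_grid[channel]
        except KeyError:
            raise GeometryError(f"channel {channel} is not mapped in this geometry")


def electrode_distance_mm(geometry: ArrayGeometry, ch_a: int, ch_b: int) -> float:
    """Manhattan distance between two electrodes in millimetres.

    ``(|row_a - row_b| + |col_a - col_b|) * spacing_mm``.
    """
    ra, ca = geometry.position(ch_a)
    rb, cb = geometry.position(ch_b)
    return (abs(ra - rb) + abs(ca - cb)) * geometry.spacing_mm


def distance_shells(
    geometry: ArrayGeometry, trigger_ch: int, max_mm: float
) -> dict[float, set[int]]:
    """Group live channels into Manhattan-distance shells around a trigger.

    Returns a dict keyed by distance in mm (multiples of the spacing, from one
    step up to ``max_mm``) mapping to the set of live channels at exactly that
    distance.  The trigger channel and dead channels are excluded from every
    shell; the shells partition the live non-trigger channels within range.
    """
    geometry.position(trigger_ch)  # raises if unmapped
    if max_mm < geometry.spacing_mm:
        raise GeometryError(
            f"max_mm={max_mm} is below one grid step ({geometry.spacing_mm} mm)"
        )
    max_steps = int(round(max_mm / geometry.spacing_mm + 1e-9))
    shells: dict[float, set[int]] = {}
    for ch in geometry.live_channels:
        if ch == trigger_ch:
            continue
        d = electrode_distance_mm(geometry, trigger_ch, ch)
        steps = int(round(d / geometry.spacing_mm))
        if 1 <= steps <= max_steps:
            key = round(steps * geometry.spacing_mm, 9)
            shells.setdefault(key, set()).add(ch)
    return dict(sorted(shells.items()))


def utah_geometry(
    spacing_mm: float = 0.4,
    dead_channels: tuple[int, ...] = (0, 9, 90, 99),
    n_rows: int = 10,
    n_cols: int = 10,
) -> ArrayGeometry:
    """Standard 10x10 intracortical grid, row-major channel ids 0..99.

    Defaults give a 0.4 mm pitch with the four corner sites dead, leaving 96
    usable electrodes as on the common commercial arrays.
    """
    grid = {r * n_cols + c: (r, c) for r in range(n_rows) for c in range(n_cols)}
    return ArrayGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        spacing_mm=spacing_mm,
        channel_grid=grid,
        dead_channels=frozenset(dead_channels),
    )
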