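"""Grid decomposition of the arena into corner/wall/center zones.

The 50x50 cm arena splits into a 5x5 grid of 10x10 cm cells: the 4 corner
cells form the corner zone, the 12 edge (non-corner) cells the wall zone and
the 9 interior cells the center zone. Occupancy uses the body-center point
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArenaGeometry, Trajectory

ZONES = ("corner", "wall", "center")


class ZoneError(ValueError):
    pass


def cell_index(x: float, y: float, arena: ArenaGeometry) -> tuple[int, int]:
    """Grid cell of a point; half-open cells, the far edges closed."""
    side = arena.side_length
    if not (0 <= x <= side and 0 <= y <= side):
        raise ZoneError(f"point ({x}, {y}) outside arena of side {side}")
    m = arena.cells_per_side
    ix = min(int(x // arena.grid_cell), m - 1)
    iy = min(int(y // arena.grid_cell), m - 1)
    return ix, iy


def _zone_of_cell(ix: int, iy: int, m: int) -> str:
    edge_x = ix in (0, m - 1)
    edge_y = iy in (0, m - 1)
    if edge_x and edge_y:
        return "corner"
    if edge_x or edge_y:
        return "wall"
    return "center"


def build_zone_map(arena: ArenaGeometry | None = None) -> dict[tuple[int, int], str]:
    """Map every grid cell to its zone label."""
    arena = arena or ArenaGeometry()
    m = arena.cells_per_side
    return {
        (ix, iy): _zone_of_cell(ix, iy, m) for ix in range(m) for iy in range(m)
    }


def zone_cell_counts(arena: ArenaGeometry | None = None) -> dict[str, int]:
    zmap = build_zone_map(arena)
    return {zone: sum(1 for z in zmap.values() if z == zone) for zone in ZONES}


def assign_zone(point: tuple[float, float], arena: ArenaGeometry | None = None) -> str:
    """Zone label of a single point."""
    arena = arena or ArenaGeometry()
    ix, iy = cell_index(point[0], point[1], arena)
    return _zone_of_cell(ix, iy, arena.cells_per_side)


@dataclass
class OccupancyResult:
    """Zone time fractions and a normalized dwell-time heatmap."""

    fractions: dict[str, float]
    heatmap: np.ndarray  # (m, m); heatmap[iy, ix]; sums to 1
    n_frames: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ZoneError(f"zone fractions sum to {total}, expected 1")


def zone_occupancy(
    traj: Trajectory, window: tuple[float, float] | None = None
) -> OccupancyResult:
    """Time fractions per zone and per-cell dwell heatmap over a window."""
    arena = traj.arena
    m = arena.cells_per_side
    if window is None:
        mask = np.ones(traj.n_frames, dtype=bool)
    else:
        mask = traj.window_mask(*window)
    pos = traj.center[mask]
    if pos.shape[0] == 0:
        raise ZoneError("no frames in window")
    cell = np.clip((pos // arena.grid_cell).astype(int), 0, m - 1)
    counts = np.zeros((m, m))
    np.add.at(counts, (cell[:, 1], cell[:, 0]), 1.0)
    heat = counts / counts.sum()
    fractions = dict.fromkeys(ZONES, 0.0)
    for (ix, iy), zone in build_zone_map(arena).items():
        fractions[zone] += heat[iy, ix]
    # renormalize away accumulated rounding so the invariant holds exactly
    total = sum(fractions.values())
    fractions = {k: v / total for k, v in fractions.items()}
    return OccupancyResult(fractions=fractions, heatmap=heat, n_frames=int(pos.shape[0]))
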