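from __future__ import annotations

import numpy as np
import pytest

from openfield.core import ArenaGeometry, SessionMetadata, Trajectory
from openfield.simulate import BehaviorParams, PharmacodynamicParams


def make_traj(
    center,
    head=None,
    tail=None,
    dt: float = 0.1,
    arena: ArenaGeometry | None = None,
    meta: SessionMetadata | None = None,
    t0: float = 0.0,
) -> Trajectory:
    """Build a trajectory from a center path; head/tail default to a fixed
    2 cm offset along x (clipped to the arena)."""
    arena = arena or ArenaGeometry()
    center = np.asarray(center, dtype=float)
    n = len(center)
    if head is None:
        head = np.clip(center + [2.0, 0.0], 0.0, arena.side_length)
    if tail is None:
        tail = np.clip(center - [2.0, 0.0], 0.0, arena.side_length)
    return Trajectory(
        t=t0 + np.arange(n) * dt,
        head=np.asarray(head, dtype=float),
        center=center,
        tail=np.asarray(tail, dtype=float),
        dt=dt,
        arena=arena,
        meta=meta or SessionMetadata(animal_id="test"),
    )


def stationary_traj(n: int = 100, pos=(25.0, 25.0), dt: float = 0.1) -> Trajectory:
    center = np.tile(np.asarray(pos, dtype=float), (n, 1))
    return make_traj(center, dt=dt)


@pytest.fixture
def bp() -> BehaviorParams:
    return BehaviorParams()


@pytest.fixture
def pd_sch() -> PharmacodynamicParams:
    return PharmacodynamicParams(ed50=0.02)


@pytest.fixture
def pd_hal() -> PharmacodynamicParams:
    return PharmacodynamicParams(ed50=0.2)


@pytest.fixture
def saline_meta() -> SessionMetadata:
    return SessionMetadata(animal_id="m00")
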