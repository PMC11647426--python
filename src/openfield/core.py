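"""Core domain types and tabular trajectory I/O.

Coordinates are in centimetres with the origin at the arena's lower-left
corner (x right, y up); time is in seconds since injection. Each animal's
quadrant is treated as an independent square arena, so one trajectory file
describes one animal-session.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

SESSION_SECONDS = 90 * 60.0
DEFAULT_DT = 1.0 / 30.0

DRUGS = ("saline", "SCH23390", "haloperidol")
SLOTS = ("0900", "1200")

_COLUMNS = ["t", "head_x", "head_y", "center_x", "center_y", "tail_x", "tail_y"]

# timestamps are written at 1e-9 precision; spacing is validated at 1e-6
_T_SPACING_TOL = 1e-6


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file does not conform to the tabular dialect."""


class TrajectoryValidationError(ValueError):
    """Raised when trajectory content violates a domain invariant."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Square open-field arena divided into a regular grid of cells."""

    side_length: float = 50.0
    grid_cell: float = 10.0
    wall_height: float = 35.0

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.grid_cell <= 0:
            raise ValueError("grid_cell must be positive")
        n = self.side_length / self.grid_cell
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "side_length must be an integer multiple of grid_cell "
                f"(got {self.side_length} / {self.grid_cell})"
            )

    @property
    def cells_per_side(self) -> int:
        return int(round(self.side_length / self.grid_cell))

    @property
    def n_cells(self) -> int:
        return self.cells_per_side**2


@dataclass(frozen=True)
class SessionMetadata:
    """Identity and treatment assignment of one animal-session."""

    animal_id: str
    drug: str = "saline"
    dose: float = 0.0
    sex: str = "F"
    test_round: int = 1
    quadrant: int = 1
    slot: str = "0900"

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.drug == "saline" and self.dose != 0:
            raise ValueError("saline sessions must have dose 0")
        if not 1 <= self.test_round <= 4:
            raise ValueError("test_round must be in 1..4")
        if not 1 <= self.quadrant <= 4:
            raise ValueError("quadrant must be in 1..4")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.slot not in SLOTS:
            raise ValueError(f"slot must be one of {SLOTS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionMetadata":
        return cls(
            animal_id=str(d["animal_id"]),
            drug=str(d["drug"]),
            dose=float(d["dose"]),
            sex=str(d.get("sex", "F")),
            test_round=int(d.get("test_round", 1)),
            quadrant=int(d.get("quadrant", 1)),
            slot=str(d.get("slot", "0900")),
        )


@dataclass
class Trajectory:
    """Uniformly sampled head/center/tail track for one session.

    Arrays ``head``, ``center`` and ``tail`` have shape (n_frames, 2).
    Frame ``i`` covers the half-open interval ``[t[i], t[i] + dt)``.
    """

    t: np.ndarray
    head: np.ndarray
    center: np.ndarray
    tail: np.ndarray
    dt: float
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    meta: SessionMetadata = field(
        default_factory=lambda: SessionMetadata(animal_id="unknown")
    )

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("head", "center", "tail"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise TrajectoryValidationError(f"{name} must have shape (n, 2)")
            if arr.shape[0] != self.t.shape[0]:
                raise TrajectoryValidationError(f"{name} length mismatch with t")
            setattr(self, name, arr)
        self.validate()

    @property
    def n_frames(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        """Session length in seconds (last frame inclusive of its dt)."""
        return float(self.t[-1] - self.t[0] + self.dt)

    def validate(self) -> None:
        if self.n_frames == 0:
            raise TrajectoryValidationError("trajectory must contain >= 1 frame")
        if self.dt <= 0:
            raise TrajectoryValidationError("dt must be positive")
        if self.t[0] < 0:
            raise TrajectoryValidationError("timestamps must be >= 0")
        if self.n_frames > 1:
            gaps = np.diff(self.t)
            if np.any(gaps <= 0):
                idx = int(np.argmax(gaps <= 0))
                raise TrajectoryValidationError(
                    f"timestamps not strictly increasing at frame {idx + 1}"
                )
            if np.max(np.abs(gaps - self.dt)) > _T_SPACING_TOL:
                idx = int(np.argmax(np.abs(gaps - self.dt) > _T_SPACING_TOL))
                raise TrajectoryValidationError(
                    f"non-uniform frame spacing at frame {idx + 1}: "
                    f"gap {gaps[idx]:.6g}s vs dt {self.dt:.6g}s"
                )
        if self.t[-1] >= SESSION_SECONDS + _T_SPACING_TOL:
            raise TrajectoryValidationError("session exceeds 90 minutes")
        side = self.arena.side_length
        for name in ("head", "center", "tail"):
            arr = getattr(self, name)
            bad = np.any((arr < -1e-9) | (arr > side + 1e-9), axis=1)
            if np.any(bad):
                idx = int(np.argmax(bad))
                raise TrajectoryValidationError(
                    f"{name} coordinate outside arena at frame {idx}: "
                    f"{tuple(arr[idx])}"
                )

    def point(self, which: str) -> np.ndarray:
        if which not in ("head", "center", "tail"):
            raise ValueError("point must be 'head', 'center' or 'tail'")
        return getattr(self, which)

    def window_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask of frames whose timestamp lies in ``[start, end)``."""
        return (self.t >= start - 1e-9) & (self.t < end - 1e-9)


def frame_speeds(traj: Trajectory, point: str = "center") -> np.ndarray:
    """Per-step speeds (cm/s) of a tracked point; length ``n_frames - 1``.

    ``speeds[i]`` is the displacement between frames ``i`` and ``i + 1``
    divided by ``dt``.
    """
    if traj.n_frames < 2:
        raise TrajectoryValidationError("need >= 2 frames to compute speeds")
    p = traj.point(point)
    return np.linalg.norm(np.diff(p, axis=0), axis=1) / traj.dt


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write the CSV dialect understood by :func:`read_trajectory`.

    Metadata goes into ``#``-prefixed ``key=value`` lines; coordinates are
    written at 1e-6 cm and timestamps at 1e-9 s precision.
    """
    if traj.n_frames == 0:  # pragma: no cover - unreachable via constructor
        raise TrajectoryValidationError("refusing to write an empty trajectory")
    buf = io.StringIO()
    for key, value in traj.meta.to_dict().items():
        buf.write(f"# {key}={value}\n")
    buf.write(f"# dt={traj.dt!r}\n")
    buf.write(f"# side_length={traj.arena.side_length!r}\n")
    buf.write(f"# grid_cell={traj.arena.grid_cell!r}\n")
    buf.write(",".join(_COLUMNS) + "\n")
    data = np.column_stack(
        [traj.t, traj.head, traj.center, traj.tail]
    )
    np.savetxt(buf, data, fmt=["%.9f"] + ["%.6f"] * 6, delimiter=",")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trajectory(path: str | os.PathLike) -> Trajectory:
    """Parse a trajectory CSV with its ``#`` metadata header block."""
    meta_kv: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta_kv[key.strip()] = value.strip()
        elif line.strip():
            break
    try:
        table = pd.read_csv(io.StringIO(text), comment="#")
    except Exception as exc:  # malformed CSV body
        raise TrajectoryFormatError(f"{path}: cannot parse table: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    if len(table) == 0:
        raise TrajectoryFormatError(f"{path}: no data rows")
    arena = ArenaGeometry(
        side_length=float(meta_kv.get("side_length", 50.0)),
        grid_cell=float(meta_kv.get("grid_cell", 10.0)),
    )
    try:
        meta = SessionMetadata.from_dict(meta_kv) if "animal_id" in meta_kv else (
            SessionMetadata(animal_id="unknown")
        )
    except (KeyError, ValueError) as exc:
        raise TrajectoryFormatError(f"{path}: bad metadata header: {exc}") from exc
    t = table["t"].to_numpy(dtype=float)
    if "dt" in meta_kv:
        dt = float(meta_kv["dt"])
    elif len(t) > 1:
        dt = float(t[1] - t[0])
    else:
        dt = DEFAULT_DT
    return Trajectory(
        t=t,
        head=table[["head_x", "head_y"]].to_numpy(dtype=float),
        center=table[["center_x", "center_y"]].to_numpy(dtype=float),
        tail=table[["tail_x", "tail_y"]].to_numpy(dtype=float),
        dt=dt,
        arena=arena,
        meta=meta,
    )


_MANIFEST_COLUMNS = [
    "path",
    "animal_id",
    "sex",
    "drug",
    "dose",
    "test_round",
    "quadrant",
    "slot",
    "seed",
]


def write_manifest(rows: list[dict], path: str | os.PathLike) -> None:
    """Write a cohort manifest CSV (one row per session file)."""
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns and c != "seed"]
    if missing:
        raise TrajectoryFormatError(f"{path}: manifest missing columns {missing}")
    return df


def iter_sessions(
    manifest: pd.DataFrame, root: str | os.PathLike = "."
) -> Iterator[tuple[SessionMetadata, Trajectory]]:
    """Yield (metadata, trajectory) pairs for every manifest row."""
    for _, row in manifest.iterrows():
        full = os.path.join(root, str(row["path"]))
        if not os.path.exists(full):
            raise FileNotFoundError(
                f"trajectory file for session {row['animal_id']!r} "
                f"round {row['test_round']} not found: {full}"
            )
        traj = read_trajectory(full)
        yield traj.meta, traj
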