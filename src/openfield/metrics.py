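"""Motor output metrics extracted from a single-session trajectory.

Implements distance travelled, rotation counting from the tail-to-head body
axis, maximum speed with the 80 cm/s jitter filter, immobility and freezing
segmentation with the 2 s minimum duration, mobile-episode counting, 5-minute
binning and aggregation over the 10-60 min timeframe of interest (TOI).

Conventions
-----------
* Frame ``i`` occupies ``[t[i], t[i] + dt)``; per-step speed ``i`` (between
  frames ``i`` and ``i + 1``) is attributed to the *earlier* frame.
* Immobility: boxcar-smoothed center speed below ``v_thresh`` sustained for
  at least ``min_dur`` seconds; brief supra-threshold flickers shorter than
  ``gap_merge`` seconds between candidate runs are merged first.
* Freezing: immobile frames whose smoothed head AND tail speeds are also
  below ``v_thresh``, again sustained ``min_dur``. Freezing frames are a
  subset of immobile frames by construction.
* Mobile episodes and immobile episodes partition the session; episode
  counts per window follow the episode *onset*.
* Bins are half-open ``[5k, 5(k+1))`` minutes; a full session has 18.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory, TrajectoryValidationError, frame_speeds
from .zones import zone_occupancy

FILTER_CAP = 80.0  # cm/s; speed recordings above this are one-frame jitter
MIN_EPISODE_S = 2.0
TOI = (600.0, 3600.0)  # 10-60 min in seconds
BIN_S = 300.0
V_THRESH = 1.0  # cm/s
SMOOTH_WIN_S = 0.5
GAP_MERGE_S = 0.2
MIN_BODY_LENGTH = 1.0  # cm; frames with a shorter body axis are skipped

KINDS = ("immobile", "freezing", "mobile")


@dataclass(frozen=True)
class Episode:
    start: float
    end: float
    kind: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EpisodeSet:
    """Disjoint, time-ordered labelled intervals of one or more kinds."""

    episodes: list[Episode] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[Episode]:
        if kind not in KINDS:
            raise ValueError(f"unknown episode kind {kind!r}")
        return [e for e in self.episodes if e.kind == kind]

    def total_time(self, kind: str, window: tuple[float, float] | None = None) -> float:
        eps = self.of_kind(kind)
        if window is None:
            return sum(e.duration for e in eps)
        lo, hi = window
        return sum(max(0.0, min(e.end, hi) - max(e.start, lo)) for e in eps)

    def merged(self, other: "EpisodeSet") -> "EpisodeSet":
        eps = sorted(self.episodes + other.episodes, key=lambda e: (e.start, e.kind))
        return EpisodeSet(eps)


def _per_frame_speeds(traj: Trajectory, point: str) -> np.ndarray:
    """Speed attributed to each frame (length n); last frame repeats."""
    s = frame_speeds(traj, point)
    return np.append(s, s[-1])


def _boxcar(values: np.ndarray, win_frames: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges."""
    if win_frames <= 1:
        return values.astype(float)
    kernel = np.ones(win_frames)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def smooth_window_frames(smooth_win: float, dt: float) -> int:
    """Odd frame count covering ``smooth_win`` seconds (>= 1)."""
    half = int(smooth_win / (2 * dt) + 1e-9)
    return 2 * half + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _merge_short_gaps(mask: np.ndarray, max_gap_frames: int) -> np.ndarray:
    """Fill False gaps shorter than ``max_gap_frames`` between True runs."""
    if max_gap_frames <= 0:
        return mask
    out = mask.copy()
    runs = _runs(mask)
    for (s0, e0), (s1, _) in zip(runs[:-1], runs[1:]):
        if s1 - e0 < max_gap_frames:
            out[e0:s1] = True
    return out


def _candidate_mask(
    traj: Trajectory,
    points: tuple[str, ...],
    v_thresh: float,
    smooth_win: float,
    gap_merge: float,
) -> np.ndarray:
    win = smooth_window_frames(smooth_win, traj.dt)
    mask = np.ones(traj.n_frames, dtype=bool)
    for point in points:
        smoothed = _boxcar(_per_frame_speeds(traj, point), win)
        mask &= smoothed < v_thresh
    gap_frames = int(round(gap_merge / traj.dt))
    return _merge_short_gaps(mask, gap_frames)


def segment_immobility(
    traj: Trajectory,
    min_dur: float = MIN_EPISODE_S,
    v_thresh: float = V_THRESH,
    smooth_win: float = SMOOTH_WIN_S,
    gap_merge: float = GAP_MERGE_S,
) -> EpisodeSet:
    """Immobile (center stationary >= ``min_dur``) and mobile episodes.

    Returns an :class:`EpisodeSet` containing both ``immobile`` episodes and
    the complementary ``mobile`` intervals, which together partition the
    session.
    """
    if min_dur <= 0:
        raise ValueError("min_dur must be positive")
    if traj.n_frames < 2:
        raise TrajectoryValidationError("need >= 2 frames to segment")
    mask = _candidate_mask(traj, ("center",), v_thresh, smooth_win, gap_merge)
    min_frames = int(round(min_dur / traj.dt))
    dt = traj.dt
    t0 = traj.t[0]
    immobile: list[Episode] = []
    for s, e in _runs(mask):
        if e - s >= min_frames:
            immobile.append(Episode(t0 + s * dt, t0 + e * dt, "immobile"))
    episodes: list[Episode] = []
    cursor = t0
    end_of_session = t0 + traj.n_frames * dt
    for ep in immobile:
        if ep.start > cursor + 1e-12:
            episodes.append(Episode(cursor, ep.start, "mobile"))
        episodes.append(ep)
        cursor = ep.end
    if cursor < end_of_session - 1e-12:
        episodes.append(Episode(cursor, end_of_session, "mobile"))
    return EpisodeSet(episodes)


def segment_freezing(
    traj: Trajectory,
    immobile: EpisodeSet,
    min_dur: float = MIN_EPISODE_S,
    v_thresh: float = V_THRESH,
    smooth_win: float = SMOOTH_WIN_S,
    gap_merge: float = GAP_MERGE_S,
) -> EpisodeSet:
    """Freezing episodes: head and tail also still within immobile frames."""
    if min_dur <= 0:
        raise ValueError("min_dur must be positive")
    still = _candidate_mask(
        traj, ("head", "tail"), v_thresh, smooth_win, gap_merge
    )
    in_immobile = np.zeros(traj.n_frames, dtype=bool)
    dt = traj.dt
    for ep in immobile.of_kind("immobile"):
        s = int(round((ep.start - traj.t[0]) / dt))
        e = int(round((ep.end - traj.t[0]) / dt))
        in_immobile[s:e] = True
    mask = still & in_immobile
    min_frames = int(round(min_dur / dt))
    t0 = traj.t[0]
    freezing = [
        Episode(t0 + s * dt, t0 + e * dt, "freezing")
        for s, e in _runs(mask)
        if e - s >= min_frames
    ]
    return EpisodeSet(freezing)


def segment_all(traj: Trajectory, **kwargs) -> EpisodeSet:
    """Immobile + mobile + freezing episodes in a single set."""
    imm = segment_immobility(traj, **kwargs)
    frz = segment_freezing(traj, imm, **kwargs)
    return imm.merged(frz)


def mobile_episode_count(
    episodes: EpisodeSet, window: tuple[float, float]
) -> int:
    """Mobile-bout initiations whose onset lies within ``[start, end)``."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive duration")
    return sum(1 for e in episodes.of_kind("mobile") if lo <= e.start < hi)


def episode_onset_count(
    episodes: EpisodeSet, kind: str, window: tuple[float, float]
) -> int:
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive duration")
    return sum(1 for e in episodes.of_kind(kind) if lo <= e.start < hi)


@dataclass
class RotationCount:
    cw: int
    ccw: int
    skipped_frames: int = 0

    @property
    def total(self) -> int:
        return self.cw + self.ccw


def body_headings(traj: Trajectory, min_body_length: float = MIN_BODY_LENGTH):
    """Tail-to-head axis angle (rad) per frame; degenerate frames dropped."""
    axis = traj.head - traj.tail
    length = np.linalg.norm(axis, axis=1)
    valid = length >= min_body_length
    angles = np.arctan2(axis[valid, 1], axis[valid, 0])
    return angles, traj.t[valid], int(np.sum(~valid))


def count_rotations(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    min_body_length: float = MIN_BODY_LENGTH,
) -> RotationCount:
    """Full 360-degree body rotations from a signed heading accumulator.

    CCW is the positive mathematical direction. Each wrapped heading change
    feeds a signed accumulator; whenever its magnitude reaches 360 degrees a
    rotation of that sign is counted and 360 degrees of that sign removed.
    """
    angles, times, skipped = body_headings(traj, min_body_length)
    if window is not None:
        sel = (times >= window[0] - 1e-9) & (times < window[1] - 1e-9)
        angles = angles[sel]
    if angles.size < 2:
        return RotationCount(0, 0, skipped)
    two_pi = 2 * np.pi
    deltas = np.diff(angles)
    deltas = (deltas + np.pi) % two_pi - np.pi
    cw = ccw = 0
    acc = 0.0
    for d in deltas:
        acc += d
        while acc >= two_pi - 1e-9:
            ccw += 1
            acc -= two_pi
        while acc <= -(two_pi - 1e-9):
            cw += 1
            acc += two_pi
    return RotationCount(cw=cw, ccw=ccw, skipped_frames=skipped)


@dataclass
class BinSeries:
    """One value of a metric per 5-minute bin."""

    metric: str
    bin_edges: np.ndarray  # length n_bins + 1, seconds
    values: np.ndarray  # NaN where missing
    missing: np.ndarray  # bool mask

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def bin_end_minutes(self) -> np.ndarray:
        return self.bin_edges[1:] / 60.0

    def window_values(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        starts, ends = self.bin_edges[:-1], self.bin_edges[1:]
        if not (np.any(np.isclose(starts, lo)) and np.any(np.isclose(ends, hi))):
            raise ValueError("window is not aligned to bin edges")
        sel = (starts >= lo - 1e-9) & (ends <= hi + 1e-9)
        if not np.any(sel):
            raise ValueError("no bins inside window")
        return self.values[sel]


def _session_bin_edges(traj: Trajectory, bin_s: float = BIN_S) -> np.ndarray:
    n_bins = int(np.ceil((traj.t[-1] + traj.dt - 1e-9) / bin_s))
    return np.arange(n_bins + 1) * bin_s


def max_speed_binned(
    traj: Trajectory, filter_cap: float = FILTER_CAP, bin_s: float = BIN_S
) -> BinSeries:
    """Per-bin maximum center speed after discarding jitter above the cap."""
    edges = _session_bin_edges(traj, bin_s)
    speeds = frame_speeds(traj, "center")
    t_step = traj.t[:-1]  # step attributed to its earlier frame
    keep = speeds <= filter_cap
    values = np.full(len(edges) - 1, np.nan)
    missing = np.zeros(len(edges) - 1, dtype=bool)
    idx = np.clip((t_step / bin_s).astype(int), 0, len(edges) - 2)
    for b in range(len(edges) - 1):
        sel = (idx == b) & keep
        if np.any(sel):
            values[b] = float(np.max(speeds[sel]))
        else:
            missing[b] = True
    return BinSeries("max_speed", edges, values, missing)


def abs_and_avg_max_speed(
    bins: BinSeries, window: tuple[float, float]
) -> tuple[float, float]:
    """(absolute, averaged) max speed over bin-aligned ``window``.

    Missing bins count as 0, deliberately: the bin-averaged variant is
    meant to be dragged down by long inactive stretches.
    """
    vals = np.nan_to_num(bins.window_values(window), nan=0.0)
    return float(np.max(vals)), float(np.mean(vals))


def distance_travelled(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    filter_cap: float = FILTER_CAP,
) -> float:
    """Path length (cm) of the body center, jitter steps excluded."""
    if traj.n_frames < 2:
        raise TrajectoryValidationError("need >= 2 frames")
    steps = np.linalg.norm(np.diff(traj.center, axis=0), axis=1)
    keep = steps / traj.dt <= filter_cap
    if window is not None:
        lo, hi = window
        t_step = traj.t[:-1]
        keep &= (t_step >= lo - 1e-9) & (t_step < hi - 1e-9)
    return float(np.sum(steps[keep]))


def pct_time(
    episodes: EpisodeSet, kind: str, window: tuple[float, float]
) -> float:
    """Percentage of the window covered by episodes of ``kind``."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive duration")
    return 100.0 * episodes.total_time(kind, window) / (hi - lo)


_BINNED_METRICS = (
    "distance",
    "max_speed",
    "mobile_episodes",
    "pct_immobile",
    "freezing_episodes",
    "pct_freezing",
    "rotations",
)


def all_bin_series(
    traj: Trajectory,
    episodes: EpisodeSet | None = None,
    bin_s: float = BIN_S,
    filter_cap: float = FILTER_CAP,
    **seg_kwargs,
) -> dict[str, BinSeries]:
    """Every per-bin metric series used by the time-course statistics."""
    if episodes is None:
        episodes = segment_all(traj, **seg_kwargs)
    edges = _session_bin_edges(traj, bin_s)
    n_bins = len(edges) - 1
    out: dict[str, BinSeries] = {"max_speed": max_speed_binned(traj, filter_cap, bin_s)}
    windows = [(edges[b], edges[b + 1]) for b in range(n_bins)]
    none_missing = np.zeros(n_bins, dtype=bool)

    def series(name, fn):
        vals = np.array([float(fn(w)) for w in windows])
        out[name] = BinSeries(name, edges, vals, none_missing.copy())

    series("distance", lambda w: distance_travelled(traj, w, filter_cap))
    series("mobile_episodes", lambda w: mobile_episode_count(episodes, w))
    series("pct_immobile", lambda w: pct_time(episodes, "immobile", w))
    series("freezing_episodes", lambda w: episode_onset_count(episodes, "freezing", w))
    series("pct_freezing", lambda w: pct_time(episodes, "freezing", w))
    series("rotations", lambda w: count_rotations(traj, w).total)
    return out


@dataclass
class TOISummary:
    """Per-session scalar metrics aggregated over the timeframe of interest."""

    animal_id: str
    drug: str
    dose: float
    test_round: int
    distance_cm: float
    rotations_total: int
    rotations_cw: int
    rotations_ccw: int
    abs_max_speed: float
    avg_max_speed: float
    abs_max_speed_early: float  # 10-35 min
    abs_max_speed_late: float  # 35-60 min
    mobile_episode_count: int
    pct_time_immobile: float
    freezing_episode_count: int
    pct_time_freezing: float
    corner_fraction: float
    wall_fraction: float
    center_fraction: float

    def __post_init__(self) -> None:
        for name in ("pct_time_immobile", "pct_time_freezing"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.avg_max_speed > self.abs_max_speed + 1e-9:
            raise ValueError("avg_max_speed exceeds abs_max_speed")


def toi_summary(
    traj: Trajectory,
    toi: tuple[float, float] = TOI,
    episodes: EpisodeSet | None = None,
    filter_cap: float = FILTER_CAP,
    **seg_kwargs,
) -> TOISummary:
    """All TOI metrics for one session; the session must cover the TOI."""
    lo, hi = toi
    session_end = traj.t[-1] + traj.dt
    if session_end < hi - 1e-6:
        have = int(session_end // BIN_S)
        need = int(round(hi / BIN_S))
        missing = [f"{int(b * 5)}-{int((b + 1) * 5)} min" for b in range(have, need)]
        raise TrajectoryValidationError(
            f"session ends at {session_end:.0f}s and does not cover the TOI; "
            f"missing bins: {', '.join(missing)}"
        )
    if episodes is None:
        episodes = segment_all(traj, **seg_kwargs)
    speed_bins = max_speed_binned(traj, filter_cap)
    abs_ms, avg_ms = abs_and_avg_max_speed(speed_bins, toi)
    mid = (lo + hi) / 2.0
    abs_early, _ = abs_and_avg_max_speed(speed_bins, (lo, mid))
    abs_late, _ = abs_and_avg_max_speed(speed_bins, (mid, hi))
    rot = count_rotations(traj, toi)
    occ = zone_occupancy(traj, toi)
    return TOISummary(
        animal_id=traj.meta.animal_id,
        drug=traj.meta.drug,
        dose=traj.meta.dose,
        test_round=traj.meta.test_round,
        distance_cm=distance_travelled(traj, toi, filter_cap),
        rotations_total=rot.total,
        rotations_cw=rot.cw,
        rotations_ccw=rot.ccw,
        abs_max_speed=abs_ms,
        avg_max_speed=avg_ms,
        abs_max_speed_early=abs_early,
        abs_max_speed_late=abs_late,
        mobile_episode_count=mobile_episode_count(episodes, toi),
        pct_time_immobile=pct_time(episodes, "immobile", toi),
        freezing_episode_count=episode_onset_count(episodes, "freezing", toi),
        pct_time_freezing=pct_time(episodes, "freezing", toi),
        corner_fraction=occ.fractions["corner"],
        wall_fraction=occ.fractions["wall"],
        center_fraction=occ.fractions["center"],
    )
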