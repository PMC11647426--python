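"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorized code paths in the package: plain
Python loops over frames, per-window arithmetic with slice means, and Monte
Carlo where the package uses quadrature.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_point_speeds(points: np.ndarray, dt: float) -> list[float]:
    out = []
    for i in range(len(points) - 1):
        dx = points[i + 1][0] - points[i][0]
        dy = points[i + 1][1] - points[i][1]
        out.append(math.hypot(dx, dy) / dt)
    return out


def _oracle_still_mask(
    points: np.ndarray, dt: float, v_thresh: float, smooth_win: float
) -> list[bool]:
    n = len(points)
    speeds = oracle_point_speeds(points, dt)
    speeds = speeds + [speeds[-1]]
    half = int(smooth_win / (2 * dt) + 1e-9)
    mask = []
    for i in range(n):
        window = speeds[max(0, i - half) : min(n, i + half + 1)]
        mask.append(float(np.mean(window)) < v_thresh)
    return mask


def _oracle_merge_gaps(mask: list[bool], max_gap: int) -> list[bool]:
    out = list(mask)
    i = 0
    n = len(out)
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            if i > 0 and j < n and (j - i) < max_gap:
                for k in range(i, j):
                    out[k] = True
            i = j
        else:
            i += 1
    return out


def _oracle_runs_at_least(mask: list[bool], min_frames: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_frames:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def oracle_immobile_runs(
    center: np.ndarray,
    dt: float,
    min_dur: float,
    v_thresh: float,
    smooth_win: float,
    gap_merge: float,
) -> list[tuple[int, int]]:
    """Immobile episodes as frame-index runs, by exhaustive scanning."""
    mask = _oracle_still_mask(center, dt, v_thresh, smooth_win)
    mask = _oracle_merge_gaps(mask, int(round(gap_merge / dt)))
    return _oracle_runs_at_least(mask, int(round(min_dur / dt)))


def oracle_freezing_runs(
    head: np.ndarray,
    tail: np.ndarray,
    immobile_runs: list[tuple[int, int]],
    n: int,
    dt: float,
    min_dur: float,
    v_thresh: float,
    smooth_win: float,
    gap_merge: float,
) -> list[tuple[int, int]]:
    head_still = _oracle_merge_gaps(
        _oracle_still_mask(head, dt, v_thresh, smooth_win), int(round(gap_merge / dt))
    )
    tail_still = _oracle_merge_gaps(
        _oracle_still_mask(tail, dt, v_thresh, smooth_win), int(round(gap_merge / dt))
    )
    in_immobile = [False] * n
    for s, e in immobile_runs:
        for i in range(s, e):
            in_immobile[i] = True
    mask = [h and t and m for h, t, m in zip(head_still, tail_still, in_immobile)]
    return _oracle_runs_at_least(mask, int(round(min_dur / dt)))


def oracle_rotations(headings_deg: list[float]) -> tuple[int, int]:
    """(cw, ccw) full turns from a signed accumulator, degree arithmetic."""
    cw = ccw = 0
    acc = 0.0
    for prev, cur in zip(headings_deg[:-1], headings_deg[1:]):
        d = cur - prev
        while d > 180.0:
            d -= 360.0
        while d <= -180.0:
            d += 360.0
        acc += d
        while acc >= 360.0 - 1e-7:
            ccw += 1
            acc -= 360.0
        while acc <= -(360.0 - 1e-7):
            cw += 1
            acc += 360.0
    return cw, ccw


def oracle_distance(center: np.ndarray, dt: float, cap: float) -> float:
    total = 0.0
    for i in range(len(center) - 1):
        step = math.hypot(
            center[i + 1][0] - center[i][0], center[i + 1][1] - center[i][1]
        )
        if step / dt <= cap:
            total += step
    return total


def oracle_dunnett_mc(
    group_sizes: list[int],
    t_observed: list[float],
    df: int,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> list[float]:
    """Monte Carlo null of max-|t| Dunnett statistics for balanced designs.

    Draws null normal data for (control + m treatments), computes each
    pooled-variance t statistic vs control, and returns for every observed
    statistic P(max_j |T_j| >= |t_obs|).
    """
    rng = np.random.default_rng(seed)
    n0 = group_sizes[0]
    treat_sizes = group_sizes[1:]
    maxima = np.empty(n_draws)
    chunk = 20_000
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        data = [rng.standard_normal((b, n)) for n in group_sizes]
        means = [d.mean(axis=1) for d in data]
        ss = sum(((d - m[:, None]) ** 2).sum(axis=1) for d, m in zip(data, means))
        sp2 = ss / df
        ts = np.stack(
            [
                (means[j + 1] - means[0]) / np.sqrt(sp2 * (1 / n + 1 / n0))
                for j, n in enumerate(treat_sizes)
            ]
        )
        maxima[done : done + b] = np.abs(ts).max(axis=0)
        done += b
    return [float(np.mean(maxima >= abs(t))) for t in t_observed]
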