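"""Synthetic open-field session generator with pharmacodynamic suppression.

Locomotion is a two-state semi-Markov process: immobile periods (a fraction
of which are complete freezes) alternate with mobile bouts modelled as a
correlated random walk with wall/corner attraction and reflecting arena
boundaries. Drug effect follows an Emax/Hill dose term multiplied by a
normalized Bateman (difference-of-exponentials) time course; it scales down
both the bout-initiation hazard and the within-bout speed.

All thresholds and rates are expressed in physical units (seconds, cm,
minutes) so the generated statistics are robust to the frame rate.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    ArenaGeometry,
    DEFAULT_DT,
    SESSION_SECONDS,
    SessionMetadata,
    Trajectory,
    write_manifest,
    write_trajectory,
)

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PharmacodynamicParams:
    """Emax/Hill dose response with Bateman onset/washout kinetics."""

    emax: float = 0.92  # maximal fractional suppression of locomotor drive
    ed50: float = 0.02  # mg/kg
    hill: float = 1.5
    ka: float = 0.2  # 1/min, onset
    ke: float = 0.05  # 1/min, washout

    def __post_init__(self) -> None:
        if not 0.0 <= self.emax <= 1.0:
            raise ValueError("emax must be in [0, 1]")
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")
        if self.hill <= 0:
            raise ValueError("hill must be positive")
        if not self.ka > self.ke > 0:
            raise ValueError("require ka > ke > 0")

    @property
    def t_peak(self) -> float:
        """Minute at which the Bateman time course peaks."""
        return math.log(self.ka / self.ke) / (self.ka - self.ke)


@dataclass(frozen=True)
class BehaviorParams:
    """Baseline (saline) locomotion parameters."""

    bout_rate0: float = 15.0  # mobile-bout initiation hazard at t=0, bouts/min
    bout_mean_dur: float = 3.0  # s
    speed_scale: float = 8.0  # cm/s, mean within-bout step speed
    speed_sigma: float = 0.5  # log-sd of within-bout speed
    habituation_tau: float = 40.0  # min, within-session hazard decline
    round_factor: float = 0.85  # hazard multiplier per prior exposure
    thigmotaxis_strength: float = 1.2  # 1/s, heading drift toward nearest corner
    heading_persistence: float = 4.0  # s, inverse turning-noise rate
    freeze_frac: float = 0.3  # probability an immobile period is a freeze
    posture_noise: float = 0.15  # cm, head/tail wobble sd per frame
    body_length: float = 4.5  # cm, head-to-tail distance

    def __post_init__(self) -> None:
        positive = (
            "bout_rate0",
            "bout_mean_dur",
            "speed_scale",
            "habituation_tau",
            "thigmotaxis_strength",
            "heading_persistence",
            "body_length",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.freeze_frac <= 1.0:
            raise ValueError("freeze_frac must be in [0, 1]")
        if not 0.0 < self.round_factor <= 1.0:
            raise ValueError("round_factor must be in (0, 1]")
        if self.posture_noise < 0 or self.speed_sigma < 0:
            raise ValueError("noise scales must be >= 0")


def bateman(t_min, ka: float, ke: float):
    """Difference-of-exponentials time course normalized to peak 1."""
    if not ka > ke > 0:
        raise ValueError("require ka > ke > 0")
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    t_peak = math.log(ka / ke) / (ka - ke)
    norm = math.exp(-ke * t_peak) - math.exp(-ka * t_peak)
    return (np.exp(-ke * t) - np.exp(-ka * t)) / norm


def dose_effect(t_min, dose: float, pd_params: PharmacodynamicParams):
    """Fractional locomotor suppression E(t, dose) in [0, emax]."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if dose == 0:
        return np.zeros_like(t)
    hill_term = dose**pd_params.hill / (dose**pd_params.hill + pd_params.ed50**pd_params.hill)
    return pd_params.emax * hill_term * bateman(t, pd_params.ka, pd_params.ke)


def bout_hazard_per_s(
    t_min, bp: BehaviorParams, test_round: int = 1, suppression=0.0
):
    """Mobile-bout initiation hazard (1/s) at session time ``t_min``."""
    t = np.asarray(t_min, dtype=float)
    base = (bp.bout_rate0 / 60.0) * bp.round_factor ** (test_round - 1)
    return base * np.exp(-t / bp.habituation_tau) * (1.0 - np.asarray(suppression))


def simulate_session(
    meta: SessionMetadata,
    pd_params: PharmacodynamicParams | None,
    bp: BehaviorParams,
    seed,
    arena: ArenaGeometry | None = None,
    dt: float = DEFAULT_DT,
    duration: float = SESSION_SECONDS,
) -> Trajectory:
    """Simulate one animal-session; ``seed`` fixes all randomness."""
    arena = arena or ArenaGeometry()
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if meta.dose > 0 and pd_params is None:
        raise ValueError("pd_params required for a non-zero dose")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    t_min = t / 60.0
    if meta.dose > 0:
        supp = dose_effect(t_min, meta.dose, pd_params)
    else:
        supp = np.zeros(n)
    hazard = bout_hazard_per_s(t_min, bp, meta.test_round, supp)
    speed_mean = bp.speed_scale * (1.0 - supp)

    # pre-drawn per-frame randomness (only consumed on mobile frames)
    sig = bp.speed_sigma
    speed_mult = np.exp(sig * rng.standard_normal(n) - 0.5 * sig * sig)
    turn_noise = rng.standard_normal(n) * math.sqrt(dt / bp.heading_persistence)
    head_noise = rng.normal(0.0, bp.posture_noise, (n, 2))
    tail_noise = rng.normal(0.0, bp.posture_noise, (n, 2))

    side = arena.side_length
    half_body = bp.body_length / 2.0
    cx = np.empty(n)
    cy = np.empty(n)
    heading = np.empty(n)
    frozen = np.zeros(n, dtype=bool)
    mobile = np.zeros(n, dtype=bool)

    x = float(rng.uniform(2.0, side - 2.0))
    y = float(rng.uniform(2.0, side - 2.0))
    th = float(rng.uniform(-math.pi, math.pi))
    thig = bp.thigmotaxis_strength * dt
    i = 0
    state_mobile = True  # animals are dropped in moving
    while i < n:
        if state_mobile:
            k = max(1, int(round(rng.exponential(bp.bout_mean_dur) / dt)))
            end = min(n, i + k)
            for j in range(i, end):
                v = speed_mean[j] * speed_mult[j]
                # drift toward the nearest corner plus turning noise
                gx = 0.0 if x < side / 2.0 else side
                gy = 0.0 if y < side / 2.0 else side
                goal = math.atan2(gy - y, gx - x)
                th += turn_noise[j] + thig * math.sin(goal - th)
                x += v * dt * math.cos(th)
                y += v * dt * math.sin(th)
                # reflecting boundaries
                if x < 0.0:
                    x = -x
                    th = math.pi - th
                elif x > side:
                    x = 2.0 * side - x
                    th = math.pi - th
                if y < 0.0:
                    y = -y
                    th = -th
                elif y > side:
                    y = 2.0 * side - y
                    th = -th
                cx[j] = x
                cy[j] = y
                heading[j] = th
            mobile[i:end] = True
            i = end
            state_mobile = False
        else:
            h = float(hazard[i])
            dur = rng.exponential(1.0 / h) if h > 1e-9 else duration
            k = max(1, int(round(dur / dt)))
            end = min(n, i + k)
            cx[i:end] = x
            cy[i:end] = y
            heading[i:end] = th
            # drug suppression deepens immobility into catatonic freezes
            p_freeze = bp.freeze_frac + (1.0 - bp.freeze_frac) * float(supp[i])
            if rng.random() < p_freeze:
                frozen[i:end] = True
            i = end
            state_mobile = True

    center = np.column_stack([cx, cy])
    u = np.column_stack([np.cos(heading), np.sin(heading)])
    head = center + half_body * u
    tail = center - half_body * u
    # posture wobble: head always (except freezes), tail only while immobile
    wobble = ~frozen
    head[wobble] += head_noise[wobble]
    still_wobble = wobble & ~mobile
    tail[still_wobble] += tail_noise[still_wobble]
    np.clip(head, 0.0, side, out=head)
    np.clip(tail, 0.0, side, out=tail)

    return Trajectory(
        t=t, head=head, center=center, tail=tail, dt=dt, arena=arena, meta=meta
    )


# ---------------------------------------------------------------------------
# lattice dosing design


@dataclass(frozen=True)
class Assignment:
    animal_id: str
    sex: str
    batch: int
    test_round: int
    day: int
    drug: str
    dose: float
    quadrant: int
    slot: str


@dataclass
class DesignPlan:
    """Batch/round treatment schedule for a cohort."""

    assignments: list[Assignment]

    @property
    def n_sessions(self) -> int:
        return len(self.assignments)

    def validate(self) -> None:
        by_animal: dict[str, list[Assignment]] = {}
        by_batch_round: dict[tuple[int, int], list[Assignment]] = {}
        for a in self.assignments:
            by_animal.setdefault(a.animal_id, []).append(a)
            by_batch_round.setdefault((a.batch, a.test_round), []).append(a)
        for (batch, rnd), group in by_batch_round.items():
            n_saline = sum(1 for a in group if a.drug == "saline")
            if n_saline != 1:
                raise ValueError(
                    f"batch {batch} round {rnd}: {n_saline} saline animals, expected 1"
                )
            if sorted(a.quadrant for a in group) != [1, 2, 3, 4]:
                raise ValueError(f"batch {batch} round {rnd}: bad quadrant assignment")
        for animal, arr in by_animal.items():
            if len(arr) > 4:
                raise ValueError(f"animal {animal}: more than 4 assignments")
            combos = [(a.drug, a.dose) for a in arr]
            if len(set(combos)) != len(combos):
                raise ValueError(f"animal {animal}: repeated (drug, dose) combination")
            days = sorted(a.day for a in arr)
            if any(d2 - d1 < 5 for d1, d2 in zip(days[:-1], days[1:])):
                raise ValueError(f"animal {animal}: assignments closer than 5 days")


def make_lattice_design(
    n_animals: int,
    doses: dict[str, list[float]],
    seed,
    n_rounds: int = 4,
    day_spacing: int = 7,
    female_frac: float = 0.8,
) -> DesignPlan:
    """Build a balanced batch/round dosing plan.

    Animals are tested in fixed batches of four; within each batch-round one
    animal (rotating with the round) receives saline and the others receive
    treatment combinations chosen greedily to balance combo usage while never
    repeating a (drug, dose) pair for the same animal.
    """
    if n_animals % 4 != 0:
        raise ValueError("n_animals must be divisible by 4")
    if n_animals == 0:
        raise ValueError("need at least one batch of 4 animals")
    if not 1 <= n_rounds <= 4:
        raise ValueError("n_rounds must be in 1..4")
    if day_spacing < 5:
        raise ValueError("day_spacing must be >= 5 days")
    combos = [(drug, float(d)) for drug, ds in doses.items() for d in ds]
    if any(drug == "saline" for drug, _ in combos):
        raise ValueError("dose lists must not include saline")
    if len(set(combos)) != len(combos):
        raise ValueError("duplicate (drug, dose) in dose lists")
    treat_per_animal = n_rounds - (1 if n_rounds >= 1 else 0)
    if len(combos) < max(3, treat_per_animal):
        raise ValueError("too few (drug, dose) combinations for this design")
    n_batches = n_animals // 4

    rng = np.random.default_rng(seed)
    width = len(str(n_animals - 1))
    animal_ids = [f"m{idx:0{width}d}" for idx in range(n_animals)]
    sexes = ["F" if rng.random() < female_frac else "M" for _ in animal_ids]
    used: dict[str, set[tuple[str, float]]] = {a: set() for a in animal_ids}
    combo_counts = dict.fromkeys(combos, 0)
    assignments: list[Assignment] = []
    for rnd in range(1, n_rounds + 1):
        day = (rnd - 1) * day_spacing
        for batch in range(n_batches):
            members = list(range(batch * 4, batch * 4 + 4))
            saline_member = members[(rnd - 1 + batch) % 4]
            quadrants = rng.permutation(4) + 1
            slot = ("0900", "1200")[(batch + rnd) % 2]
            taken_this_batch: set[tuple[str, float]] = set()
            for pos, member in enumerate(members):
                animal = animal_ids[member]
                if member == saline_member:
                    drug, dose = "saline", 0.0
                else:
                    options = [
                        c
                        for c in combos
                        if c not in used[animal] and c not in taken_this_batch
                    ]
                    if not options:
                        raise ValueError(
                            f"infeasible design: no unused treatment for {animal}"
                        )
                    low = min(combo_counts[c] for c in options)
                    pool = [c for c in options if combo_counts[c] == low]
                    drug, dose = pool[rng.integers(len(pool))]
                    combo_counts[(drug, dose)] += 1
                    used[animal].add((drug, dose))
                    taken_this_batch.add((drug, dose))
                assignments.append(
                    Assignment(
                        animal_id=animal,
                        sex=sexes[member],
                        batch=batch,
                        test_round=rnd,
                        day=day,
                        drug=drug,
                        dose=dose,
                        quadrant=int(quadrants[pos]),
                        slot=slot,
                    )
                )
    plan = DesignPlan(assignments)
    plan.validate()
    return plan


def session_seed(master_seed, animal_id: str, test_round: int) -> np.random.SeedSequence:
    """Deterministic per-session seed derived from the master seed."""
    return np.random.SeedSequence(
        entropy=(int(master_seed), zlib.crc32(animal_id.encode()), int(test_round))
    )


def simulate_cohort(
    plan: DesignPlan,
    pd_by_drug: dict[str, PharmacodynamicParams],
    bp: BehaviorParams,
    seed,
    out_dir=None,
    arena: ArenaGeometry | None = None,
    dt: float = DEFAULT_DT,
    duration: float = SESSION_SECONDS,
):
    """Simulate every assignment in a plan.

    Returns ``(sessions, manifest)`` where sessions is a list of
    :class:`~openfield.core.Trajectory`. When ``out_dir`` is given the
    trajectories and a ``manifest.csv`` are also written there.
    """
    import os

    sessions: list[Trajectory] = []
    rows: list[dict] = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    for a in plan.assignments:
        meta = SessionMetadata(
            animal_id=a.animal_id,
            sex=a.sex,
            drug=a.drug,
            dose=a.dose,
            test_round=a.test_round,
            quadrant=a.quadrant,
            slot=a.slot,
        )
        ss = session_seed(seed, a.animal_id, a.test_round)
        pd_params = pd_by_drug.get(a.drug) if a.drug != "saline" else None
        traj = simulate_session(
            meta, pd_params, bp, ss, arena=arena, dt=dt, duration=duration
        )
        sessions.append(traj)
        fname = f"{a.animal_id}_r{a.test_round}.csv"
        rows.append(
            {
                "path": fname,
                "animal_id": a.animal_id,
                "sex": a.sex,
                "drug": a.drug,
                "dose": a.dose,
                "test_round": a.test_round,
                "quadrant": a.quadrant,
                "slot": a.slot,
                "seed": str(ss.entropy),
            }
        )
        if out_dir is not None:
            write_trajectory(traj, os.path.join(out_dir, fname))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        write_manifest(rows, os.path.join(out_dir, "manifest.csv"))
    return sessions, manifest


# ---------------------------------------------------------------------------
# dose-response parameter recovery


def expected_toi_distance(
    dose: float,
    pd_params: PharmacodynamicParams,
    bp: BehaviorParams,
    test_round: int = 1,
    toi_min: tuple[float, float] = (10.0, 60.0),
    scale: float = 1.0,
) -> float:
    """Quasi-stationary approximation of the mean TOI distance (cm).

    The two-state process spends a fraction ``m*lam / (1 + m*lam)`` of its
    time mobile (bout mean duration ``m``, initiation hazard ``lam``), and a
    mobile frame covers ``speed_scale * (1 - E)`` cm/s on average.
    """
    tt = np.linspace(toi_min[0], toi_min[1], 201)
    supp = dose_effect(tt, dose, pd_params) if dose > 0 else np.zeros_like(tt)
    lam = bout_hazard_per_s(tt, bp, test_round, supp)
    p_mobile = bp.bout_mean_dur * lam / (1.0 + bp.bout_mean_dur * lam)
    rate = p_mobile * (1.0 - supp) * bp.speed_scale  # cm/s
    return scale * float(np.trapezoid(rate, tt * 60.0))


def fit_dose_response(
    doses,
    mean_distances,
    bp: BehaviorParams,
    pd_template: PharmacodynamicParams,
    test_round: int = 1,
    toi_min: tuple[float, float] = (10.0, 60.0),
) -> PharmacodynamicParams:
    """Least-squares refit of ``emax`` and ``ed50`` from mean TOI distances.

    ``doses`` should include 0 (saline) to pin the overall scale, which is
    fitted as a free nuisance factor. ``hill``, ``ka`` and ``ke`` are held at
    the template values.
    """
    from scipy.optimize import least_squares

    doses = np.asarray(doses, dtype=float)
    obs = np.asarray(mean_distances, dtype=float)
    if doses.shape != obs.shape or doses.size < 3:
        raise ValueError("need matching dose/distance arrays with >= 3 points")

    positive = doses[doses > 0]
    x0 = np.array([0.0, math.log(0.8 / 0.2), math.log(np.median(positive))])

    def unpack(x):
        log_scale, logit_emax, log_ed50 = x
        emax = 1.0 / (1.0 + math.exp(-logit_emax))
        return math.exp(log_scale), emax, math.exp(log_ed50)

    def residuals(x):
        scale, emax, ed50 = unpack(x)
        pdp = replace(pd_template, emax=emax, ed50=ed50)
        pred = np.array(
            [
                expected_toi_distance(d, pdp, bp, test_round, toi_min, scale)
                for d in doses
            ]
        )
        return (pred - obs) / np.maximum(obs, 1e-9)

    # normalize the nuisance scale first against the saline point
    sal = obs[doses == 0]
    if sal.size:
        base = expected_toi_distance(0.0, pd_template, bp, test_round, toi_min)
        x0[0] = math.log(max(sal.mean() / base, 1e-9))
    sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
    _, emax, ed50 = unpack(sol.x)
    return replace(pd_template, emax=emax, ed50=ed50)
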