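"""Synthetic foraging rafts driven by the two-rate social dive process.

Agents swim on an unbounded plane with a loosely aligned correlated walk
(shared travel direction, weak attraction to the flock centroid, and a
follow tendency toward the nearest bird ahead, which produces the
front-back neighbour anisotropy seen in real rafts).  Dive decisions run
on a coarser lattice (``dive_step``, default 0.5 s): at each interval
start every surfaced bird is labelled social or not from the exact times
and locations of earlier conspecific dives, then draws a Bernoulli trial
with the per-step probability converted from p1 or p0.  The labelling
uses the identical predicate the inference stage applies, so generator
and likelihood are self-consistent by construction.

A diving bird's trajectory ends at its (continuous, uniform-in-interval)
dive instant and it never resurfaces unless ``respawn`` is enabled, in
which case a fresh bird id enters after an exponential delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import DIVE_COLUMNS, TRACK_COLUMNS, RaftDataset
from .observations import social_flags_at
from .params import SHAG_RAFT_PARAMS, DiveModelParams, per_step_probability

__all__ = ["RaftConfig", "simulate_raft", "simulate_rafts", "simulate_wave_raft"]


@dataclass(frozen=True)
class RaftConfig:
    """Simulation settings for one raft.

    Speeds are body lengths per second; ``heading_noise`` is the standard
    deviation of the per-movement-step heading kick in degrees; the three
    steering weights are per-second turn-rate gains toward the shared
    travel direction, the flock centroid, and the nearest bird ahead.
    """

    n_birds: int = 103
    duration: float = 60.0
    sim_step: float = 0.04  # movement integration step (25 fps)
    dive_step: float = 0.5  # dive-decision lattice = analysis discretization
    mean_speed: float = 1.1
    speed_sd: float = 0.3
    target_nnd: float = 9.3
    heading_noise: float = 3.0
    alignment_weight: float = 0.5
    attraction_weight: float = 0.15
    follow_weight: float = 0.5
    dive_params: DiveModelParams = field(default_factory=lambda: SHAG_RAFT_PARAMS)
    respawn: bool = False
    respawn_delay: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_birds < 0:
            raise ValueError("n_birds must be >= 0")
        for name in ("duration", "sim_step", "dive_step", "mean_speed", "target_nnd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.sim_step > 0.5:
            raise ValueError("sim_step must be <= 0.5 s")
        n_steps = self.duration / self.sim_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("duration must be a whole number of sim steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.sim_step))


def _wrap_pi(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def _initial_positions(rng, n, target_nnd):
    # uniform square sized so the Poisson-process mean NND matches target
    side = 2.0 * target_nnd * math.sqrt(max(n, 1))
    return rng.uniform(-side / 2, side / 2, size=(2, n))


def _turn_rates(x, y, h, mu, cfg: RaftConfig):
    """Per-second turn rate for each moving bird (radians/s)."""
    turn = cfg.alignment_weight * _wrap_pi(mu - h)
    m = x.size
    if m >= 2 and (cfg.attraction_weight or cfg.follow_weight):
        if cfg.attraction_weight:
            cx, cy = x.mean(), y.mean()
            turn = turn + cfg.attraction_weight * _wrap_pi(
                np.arctan2(cy - y, cx - x) - h
            )
        if cfg.follow_weight:
            dx = x[None, :] - x[:, None]
            dy = y[None, :] - y[:, None]
            dist = np.hypot(dx, dy)
            bear = np.arctan2(dy, dx)
            forward = np.cos(bear - h[:, None]) > 0.0
            np.fill_diagonal(forward, False)
            dist = np.where(forward, dist, np.inf)
            nearest = np.argmin(dist, axis=1)
            has = np.isfinite(dist[np.arange(m), nearest])
            foll = np.where(has, _wrap_pi(bear[np.arange(m), nearest] - h), 0.0)
            turn = turn + cfg.follow_weight * foll
    return turn


class _Flock:
    """Growable per-bird state plus the (frames x birds) position store."""

    def __init__(self, cfg: RaftConfig, rng):
        n, F = cfg.n_birds, cfg.n_steps
        self.X = np.full((n, F), np.nan)
        self.Y = np.full((n, F), np.nan)
        x0 = _initial_positions(rng, n, cfg.target_nnd)
        self.X[:, 0], self.Y[:, 0] = x0[0], x0[1]
        self.mu = rng.uniform(0.0, 2 * np.pi)
        self.h = self.mu + rng.normal(0.0, np.radians(20.0), n)
        self.v = np.clip(rng.normal(cfg.mean_speed, cfg.speed_sd, n), 0.25, 2.45)
        self.first_frame = np.zeros(n, dtype=int)
        self.moving = np.ones(n, dtype=bool)
        self.t_dive = np.full(n, np.nan)  # scheduled exact dive instants
        self.n = n

    def add_bird(self, cfg, rng, j, x, y):
        self.X = np.vstack([self.X, np.full((1, self.X.shape[1]), np.nan)])
        self.Y = np.vstack([self.Y, np.full((1, self.Y.shape[1]), np.nan)])
        self.X[-1, j], self.Y[-1, j] = x, y
        self.h = np.append(self.h, self.mu + rng.normal(0.0, np.radians(20.0)))
        self.v = np.append(
            self.v, np.clip(rng.normal(cfg.mean_speed, cfg.speed_sd), 0.25, 2.45)
        )
        self.first_frame = np.append(self.first_frame, j)
        self.moving = np.append(self.moving, True)
        self.t_dive = np.append(self.t_dive, np.nan)
        self.n += 1
        return self.n - 1


def simulate_raft(config: RaftConfig, seed: int | None = None, raft_id=0) -> RaftDataset:
    """Simulate one raft; identical (config, seed) gives identical output.

    The returned dataset's ``metadata['labels']`` table records, for every
    Bernoulli trial the generator performed, the bird, interval index,
    interval start, social flag and outcome - the ground truth against
    which the discretizer/inference labelling can be checked exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    meta = {
        "duration": config.duration,
        "fps": 1.0 / config.sim_step,
        "dive_step": config.dive_step,
        "config": config,
    }
    if config.n_birds == 0:
        return RaftDataset(
            pd.DataFrame(columns=TRACK_COLUMNS), pd.DataFrame(columns=DIVE_COLUMNS), meta
        )

    cfg = config
    dt = cfg.sim_step
    F = cfg.n_steps
    times = np.arange(F) * dt
    flock = _Flock(cfg, rng)

    ps0 = per_step_probability(cfg.dive_params.p0, cfg.dive_step)
    ps1 = per_step_probability(cfg.dive_params.p1, cfg.dive_step)
    n_intervals = int(np.floor((cfg.duration - 1e-9) / cfg.dive_step)) + 1
    t_starts = np.arange(n_intervals) * cfg.dive_step
    # interval k is processed just after stepping past its start
    k_frame = np.searchsorted(times, t_starts, side="right") - 1
    intervals_at: dict[int, list[int]] = {}
    for k, jk in enumerate(k_frame):
        intervals_at.setdefault(int(jk), []).append(k)

    dive_rows: list[tuple] = []  # bird, t, x, y, heading
    dive_t: list[float] = []
    dive_x: list[float] = []
    dive_y: list[float] = []
    label_rows: list[tuple] = []  # bird, interval, t_start, social, dived
    final_points: dict[int, tuple[float, float, float]] = {}
    respawn_queue: list[float] = []

    def finalize(i, j, xj, yj, xn, yn, tn):
        """Close bird i's trajectory at its dive instant within (t_j, tn]."""
        td = flock.t_dive[i]
        frac = (td - times[j]) / (tn - times[j])
        xd = xj + frac * (xn - xj)
        yd = yj + frac * (yn - yj)
        hd = math.degrees(math.atan2(yn - yj, xn - xj))
        final_points[i] = (td, xd, yd)
        dive_rows.append((i, td, xd, yd, hd))
        dive_t.append(td)
        dive_x.append(xd)
        dive_y.append(yd)
        flock.moving[i] = False
        if cfg.respawn:
            respawn_queue.append(td + rng.exponential(cfg.respawn_delay))

    for j in range(F):
        tn = times[j] + dt if j == F - 1 else times[j + 1]
        idx = np.flatnonzero(flock.moving & (flock.first_frame <= j))
        if idx.size:
            x = flock.X[idx, j]
            y = flock.Y[idx, j]
            h = flock.h[idx]
            turn = _turn_rates(x, y, h, flock.mu, cfg)
            h = h + dt * turn + np.radians(cfg.heading_noise) * rng.standard_normal(
                idx.size
            )
            xn = x + flock.v[idx] * dt * np.cos(h)
            yn = y + flock.v[idx] * dt * np.sin(h)
            flock.h[idx] = h
            if j + 1 < F:
                flock.X[idx, j + 1] = xn
                flock.Y[idx, j + 1] = yn
            # close out birds whose scheduled dive falls inside this step
            pend = idx[np.nan_to_num(flock.t_dive[idx], nan=np.inf) <= tn]
            for col, i in enumerate(idx):
                if i in pend:
                    finalize(i, j, x[col], y[col], xn[col], yn[col], tn)
                    if j + 1 < F:
                        flock.X[i, j + 1] = np.nan
                        flock.Y[i, j + 1] = np.nan

        for k in intervals_at.get(j, []):
            t_k = t_starts[k]
            any_dives = len(dive_t) > 0
            elig = np.flatnonzero(
                flock.moving
                & np.isnan(flock.t_dive)
                & (
                    (flock.first_frame < j)
                    | ((flock.first_frame <= j) & (not any_dives))
                )
            )
            if not elig.size:
                continue
            ex = flock.X[elig, j]
            ey = flock.Y[elig, j]
            prev = np.maximum(j - 1, flock.first_frame[elig])
            hdg = np.degrees(
                np.arctan2(ey - flock.Y[elig, prev], ex - flock.X[elig, prev])
            )
            flags = social_flags_at(
                ex,
                ey,
                hdg,
                np.asarray(dive_t),
                np.asarray(dive_x),
                np.asarray(dive_y),
                t_k,
                cfg.dive_params,
            )
            p = np.where(flags, ps1, ps0)
            dives_now = rng.random(elig.size) < p
            for col, i in enumerate(elig):
                label_rows.append((i, k, t_k, bool(flags[col]), bool(dives_now[col])))
            divers = elig[dives_now]
            if divers.size:
                td = t_k + cfg.dive_step * rng.random(divers.size)
                flock.t_dive[divers] = td
                # a dive instant may land before the frame we already reached
                for col, i in enumerate(divers):
                    if td[col] <= tn and j + 1 <= F:
                        xj, yj = flock.X[i, j], flock.Y[i, j]
                        if j + 1 < F and np.isfinite(flock.X[i, j + 1]):
                            xn_i, yn_i = flock.X[i, j + 1], flock.Y[i, j + 1]
                        else:
                            xn_i = xj + flock.v[i] * dt * np.cos(flock.h[i])
                            yn_i = yj + flock.v[i] * dt * np.sin(flock.h[i])
                        finalize(i, j, xj, yj, xn_i, yn_i, tn)
                        if j + 1 < F:
                            flock.X[i, j + 1] = np.nan
                            flock.Y[i, j + 1] = np.nan

        if cfg.respawn and respawn_queue and j + 1 < F:
            due = [t for t in respawn_queue if t <= times[j + 1]]
            for _ in due:
                respawn_queue.remove(_)
                alive = np.flatnonzero(flock.moving)
                if alive.size:
                    cx = flock.X[alive, j + 1 if j + 1 < F else j]
                    cy = flock.Y[alive, j + 1 if j + 1 < F else j]
                    cx = np.nanmean(cx) if np.isfinite(cx).any() else 0.0
                    cy = np.nanmean(cy) if np.isfinite(cy).any() else 0.0
                else:
                    cx = cy = 0.0
                flock.add_bird(
                    cfg,
                    rng,
                    j + 1,
                    cx + rng.normal(0.0, 2 * cfg.target_nnd),
                    cy + rng.normal(0.0, 2 * cfg.target_nnd),
                )

    # ---- assemble tables --------------------------------------------
    track_parts = []
    for i in range(flock.n):
        mask = np.isfinite(flock.X[i])
        t_i = times[mask]
        x_i = flock.X[i][mask]
        y_i = flock.Y[i][mask]
        if i in final_points:
            td, xd, yd = final_points[i]
            t_i = np.append(t_i, td)
            x_i = np.append(x_i, xd)
            y_i = np.append(y_i, yd)
        track_parts.append(
            pd.DataFrame(
                {
                    "raft_id": raft_id,
                    "bird_id": i,
                    "time_s": t_i,
                    "x_bl": x_i,
                    "y_bl": y_i,
                }
            )
        )
    tracks = pd.concat(track_parts, ignore_index=True)
    dives = pd.DataFrame(
        [(raft_id, b, t, x, y, h) for b, t, x, y, h in dive_rows],
        columns=DIVE_COLUMNS,
    )
    meta["labels"] = pd.DataFrame(
        label_rows, columns=["bird_id", "interval", "t_start", "social", "dived"]
    )
    return RaftDataset(tracks, dives, meta)


def simulate_rafts(
    n_rafts: int,
    config: RaftConfig,
    seed: int,
    sizes: list[int] | None = None,
) -> RaftDataset:
    """Simulate several independent rafts and pool them (raft ids 0..n-1)."""
    child_seeds = np.random.SeedSequence(seed).spawn(n_rafts)
    parts = []
    for r in range(n_rafts):
        cfg = config if sizes is None else replace(config, n_birds=int(sizes[r]))
        sub_seed = int(child_seeds[r].generate_state(1)[0] % (2**31))
        parts.append(simulate_raft(cfg, seed=sub_seed, raft_id=r))
    return RaftDataset.concat(parts)


def simulate_wave_raft(
    config: RaftConfig,
    seed: int | None = None,
    raft_id=0,
    wave_speed: float = 5.0,
    trigger_prob: float = 0.8,
) -> RaftDataset:
    """Diagnostic raft where dives are triggered by a moving front.

    Movement is the usual correlated walk, but instead of the social
    process a dive front sweeps through the flock from front to back (in
    the flock frame) at ``wave_speed`` BL/s; each bird the front has
    passed dives with probability ``trigger_prob`` per interval.  This
    emulates birds reacting to the same advancing stimulus and produces
    the before-and-in-front / after-and-behind signature the wave
    diagnostic is designed to reveal.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cfg = config
    dt = cfg.sim_step
    F = cfg.n_steps
    times = np.arange(F) * dt
    if cfg.n_birds == 0:
        return RaftDataset(
            pd.DataFrame(columns=TRACK_COLUMNS), pd.DataFrame(columns=DIVE_COLUMNS), {}
        )
    flock = _Flock(cfg, rng)
    for j in range(F - 1):
        idx = np.arange(cfg.n_birds)
        x = flock.X[idx, j]
        y = flock.Y[idx, j]
        h = flock.h
        turn = _turn_rates(x, y, h, flock.mu, cfg)
        h = h + dt * turn + np.radians(cfg.heading_noise) * rng.standard_normal(h.size)
        flock.h = h
        flock.X[idx, j + 1] = x + flock.v * dt * np.cos(h)
        flock.Y[idx, j + 1] = y + flock.v * dt * np.sin(h)

    ux, uy = math.cos(flock.mu), math.sin(flock.mu)
    along0 = flock.X[:, 0] * ux + flock.Y[:, 0] * uy
    front0 = along0.max()
    n_intervals = int(np.floor((cfg.duration - 1e-9) / cfg.dive_step)) + 1
    dived = np.zeros(cfg.n_birds, dtype=bool)
    rows = []
    for k in range(n_intervals):
        t_k = k * cfg.dive_step
        jk = int(np.searchsorted(times, t_k, side="right")) - 1
        along = (flock.X[:, jk] - flock.X[:, 0].mean()) * ux + (
            flock.Y[:, jk] - flock.Y[:, 0].mean()
        ) * uy + (along0.mean() - 0.0)
        passed = along - cfg.mean_speed * t_k >= front0 - wave_speed * t_k
        candidates = np.flatnonzero(~dived & passed)
        fire = candidates[rng.random(candidates.size) < trigger_prob]
        for i in fire:
            td = t_k + cfg.dive_step * rng.random()
            jd = int(np.searchsorted(times, td, side="right")) - 1
            jn = min(jd + 1, F - 1)
            if jn == jd:
                xd, yd = flock.X[i, jd], flock.Y[i, jd]
            else:
                frac = (td - times[jd]) / (times[jn] - times[jd])
                xd = flock.X[i, jd] + frac * (flock.X[i, jn] - flock.X[i, jd])
                yd = flock.Y[i, jd] + frac * (flock.Y[i, jn] - flock.Y[i, jd])
            hd = math.degrees(
                math.atan2(flock.Y[i, jn] - flock.Y[i, jd], flock.X[i, jn] - flock.X[i, jd])
            ) if jn != jd else math.degrees(flock.h[i])
            rows.append((raft_id, i, td, xd, yd, hd))
            flock.X[i, times > td] = np.nan
            flock.Y[i, times > td] = np.nan
            dived[i] = True
    track_parts = []
    for i in range(cfg.n_birds):
        mask = np.isfinite(flock.X[i])
        df = pd.DataFrame(
            {
                "raft_id": raft_id,
                "bird_id": i,
                "time_s": times[mask],
                "x_bl": flock.X[i][mask],
                "y_bl": flock.Y[i][mask],
            }
        )
        track_parts.append(df)
    dives = pd.DataFrame(rows, columns=DIVE_COLUMNS)
    meta = {"duration": cfg.duration, "fps": 1.0 / dt, "wave_speed": wave_speed}
    return RaftDataset(pd.concat(track_parts, ignore_index=True), dives, meta)
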