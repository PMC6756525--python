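"""Discretized Bernoulli observations and the social-cue predicate.

Trajectories are discretized into fixed intervals (default 0.5 s).  Each
record is one surfaced bird in one interval, with a binary ``dived``
outcome, and carries a candidate-cue list: every conspecific dive whose
exact time lies within the maximal look-back window and whose distance is
within the maximal detection range (the prior upper bounds), so that
:func:`social_labels` can be evaluated for any parameter proposal without
returning to the raw data.

Conspecific dives keep their exact (continuous) times; only the focal
bird's exposure is discretized.  Focal position and heading are taken at
the interval start (last observed sample at or before it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import RaftDataset, heading_from_displacements
from .params import DiveModelParams, Priors

__all__ = ["DiscretizedObservations", "discretize", "is_social", "social_labels"]

RECORD_COLUMNS = [
    "raft_id",
    "bird_id",
    "interval",
    "t_start",
    "x_bl",
    "y_bl",
    "heading_deg",
    "dived",
]


def _wrap180(angle_deg):
    """Wrap angles to [-180, 180)."""
    return (np.asarray(angle_deg) + 180.0) % 360.0 - 180.0


def abs_bearing(dx, dy, heading_deg):
    """Absolute bearing (degrees, [0, 180]) of an offset from a heading."""
    return np.abs(_wrap180(np.degrees(np.arctan2(dy, dx)) - heading_deg))


@dataclass
class DiscretizedObservations:
    """Per-bird per-interval dive indicators with candidate-cue lists.

    Cues are stored flat in CSR form: record ``i`` owns the slice
    ``cue_ptr[i]:cue_ptr[i+1]`` of the ``cue_*`` arrays.
    """

    table: pd.DataFrame
    cue_dt: np.ndarray
    cue_dist: np.ndarray
    cue_bearing: np.ndarray
    cue_ptr: np.ndarray
    step: float
    max_lag: float
    max_dist: float

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def n_cues(self) -> int:
        return int(self.cue_dt.size)

    @property
    def dived(self) -> np.ndarray:
        return self.table["dived"].to_numpy(dtype=np.uint8)

    def cues(self, i: int) -> pd.DataFrame:
        s = slice(self.cue_ptr[i], self.cue_ptr[i + 1])
        return pd.DataFrame(
            {
                "dt_s": self.cue_dt[s],
                "distance_bl": self.cue_dist[s],
                "abs_bearing_deg": self.cue_bearing[s],
            }
        )

    def social_labels(self, params: DiveModelParams) -> np.ndarray:
        return social_labels(self, params)


def social_labels(obs: DiscretizedObservations, params: DiveModelParams) -> np.ndarray:
    """Boolean social label for every record under ``params``."""
    from ._kernels import social_labels_kernel

    return social_labels_kernel(
        obs.cue_dt,
        obs.cue_dist,
        obs.cue_bearing,
        obs.cue_ptr,
        params.lag,
        params.distance,
        params.half_angle,
    ).astype(bool)


def is_social(obs: DiscretizedObservations, i: int, params: DiveModelParams) -> bool:
    """True iff record ``i`` has a qualifying cue: exact lag within ``params.lag``,
    distance strictly below ``params.distance`` and absolute bearing within
    half the visual arc."""
    s = slice(obs.cue_ptr[i], obs.cue_ptr[i + 1])
    return bool(
        np.any(
            (obs.cue_dt[s] <= params.lag)
            & (obs.cue_dist[s] < params.distance)
            & (obs.cue_bearing[s] <= params.half_angle)
        )
    )


def social_flags_at(x, y, heading_deg, dive_t, dive_x, dive_y, t_now, params):
    """Social flag for focal birds at one instant, given past dives.

    Used by the simulator so that its internal labels are computed with the
    identical arithmetic the discretizer uses (strictly positive lag,
    distance strictly below D, absolute bearing within theta/2).
    """
    x = np.asarray(x, float)
    flags = np.zeros(x.shape, dtype=bool)
    if dive_t.size == 0 or x.size == 0:
        return flags
    dt = t_now - np.asarray(dive_t, float)
    recent = (dt > 0.0) & (dt <= params.lag)
    if not recent.any():
        return flags
    dx = np.asarray(dive_x, float)[recent][None, :] - x[:, None]
    dy = np.asarray(dive_y, float)[recent][None, :] - np.asarray(y, float)[:, None]
    dist = np.hypot(dx, dy)
    bear = abs_bearing(dx, dy, np.asarray(heading_deg, float)[:, None])
    ok = (dist < params.distance) & (bear <= params.half_angle)
    return ok.any(axis=1)


def discretize(
    dataset: RaftDataset,
    step: float = 0.5,
    priors: Priors | None = None,
    max_lag: float | None = None,
    max_dist: float | None = None,
    exclude_bird_ids: set | None = None,
) -> DiscretizedObservations:
    """Turn a raft dataset into Bernoulli records with candidate-cue lists.

    A record exists for interval ``[k*step, (k+1)*step)`` if the bird has
    been observed at or before the interval start and its track extends at
    least to the interval start.  ``dived`` is 1 for the interval
    containing the bird's dive (its last record).  Candidate cues are all
    *other* birds' dives in the same raft with exact lag in
    ``(0, max_lag]`` and distance at most ``max_dist`` from the focal
    position at the interval start; bounds default to the prior upper
    bounds so any proposal inside the priors can be evaluated.

    Multiple rafts are pooled; raft ids are retained.  Birds listed in
    ``exclude_bird_ids`` (as ``(raft_id, bird_id)`` pairs) contribute no
    records but their dives still act as cues.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    priors = priors or Priors()
    max_lag = priors.lag[1] if max_lag is None else float(max_lag)
    max_dist = priors.distance[1] if max_dist is None else float(max_dist)
    exclude_bird_ids = exclude_bird_ids or set()

    rec_rows: list[np.ndarray] = []
    rec_raft: list = []
    cue_dt_parts, cue_dist_parts, cue_bear_parts = [], [], []
    cue_counts: list[np.ndarray] = []

    for raft_id in dataset.raft_ids:
        tracks = dataset.tracks[dataset.tracks["raft_id"] == raft_id]
        dives = dataset.dives[dataset.dives["raft_id"] == raft_id]
        if tracks.duplicated(["bird_id", "time_s"]).any():
            raise ValueError(f"raft {raft_id!r}: duplicate bird/time rows")

        birds = {}
        for bird_id, g in tracks.groupby("bird_id", sort=True):
            t = g["time_s"].to_numpy(float)
            x = g["x_bl"].to_numpy(float)
            y = g["y_bl"].to_numpy(float)
            birds[bird_id] = (t, x, y, heading_from_displacements(x, y))

        d_order = np.argsort(dives["time_s"].to_numpy(), kind="stable")
        d_t = dives["time_s"].to_numpy(float)[d_order]
        d_x = dives["x_bl"].to_numpy(float)[d_order]
        d_y = dives["y_bl"].to_numpy(float)[d_order]
        d_bird = dives["bird_id"].to_numpy()[d_order]
        dive_time_of = dict(zip(d_bird.tolist(), d_t.tolist()))

        duration = dataset.metadata.get("duration")
        t_max = max((t[-1] for t, *_ in birds.values()), default=0.0)
        if duration is None:
            duration = t_max
        n_intervals = int(np.floor((float(duration) - 1e-9) / step)) + 1 if duration > 0 else 0

        for k in range(n_intervals):
            t_k = k * step
            f_bird, f_x, f_y, f_h, f_div = [], [], [], [], []
            for bird_id, (t, x, y, h) in birds.items():
                if (raft_id, bird_id) in exclude_bird_ids:
                    continue
                if t[0] > t_k or t[-1] < t_k:
                    continue
                idx = int(np.searchsorted(t, t_k, side="right")) - 1
                td = dive_time_of.get(bird_id)
                f_bird.append(bird_id)
                f_x.append(x[idx])
                f_y.append(y[idx])
                f_h.append(h[idx])
                f_div.append(1 if (td is not None and t_k <= td < t_k + step) else 0)
            if not f_bird:
                continue
            f_x = np.array(f_x)
            f_y = np.array(f_y)
            f_h = np.array(f_h)

            lo = int(np.searchsorted(d_t, t_k - max_lag, side="left"))
            hi = int(np.searchsorted(d_t, t_k, side="left"))
            w_t, w_x, w_y, w_b = d_t[lo:hi], d_x[lo:hi], d_y[lo:hi], d_bird[lo:hi]

            n_f = len(f_bird)
            counts = np.zeros(n_f, dtype=np.int64)
            if len(w_t):
                dx = w_x[None, :] - f_x[:, None]
                dy = w_y[None, :] - f_y[:, None]
                dist = np.hypot(dx, dy)
                dt = t_k - w_t
                keep = (dist <= max_dist) & (w_b[None, :] != np.array(f_bird)[:, None])
                bear = abs_bearing(dx, dy, f_h[:, None])
                counts = keep.sum(axis=1)
                if counts.any():
                    # row-major flatten keeps each record's cues contiguous
                    cue_dt_parts.append(np.broadcast_to(dt, keep.shape)[keep])
                    cue_dist_parts.append(dist[keep])
                    cue_bear_parts.append(bear[keep])
            cue_counts.append(counts)
            rec_rows.append(
                np.column_stack(
                    [
                        np.full(n_f, k, dtype=float),
                        np.full(n_f, t_k, dtype=float),
                        f_x,
                        f_y,
                        f_h,
                        np.array(f_div, dtype=float),
                    ]
                )
            )
            rec_raft.extend([(raft_id, b) for b in f_bird])

    if rec_rows:
        block = np.concatenate(rec_rows, axis=0)
        table = pd.DataFrame(
            {
                "raft_id": [rb[0] for rb in rec_raft],
                "bird_id": [rb[1] for rb in rec_raft],
                "interval": block[:, 0].astype(int),
                "t_start": block[:, 1],
                "x_bl": block[:, 2],
                "y_bl": block[:, 3],
                "heading_deg": block[:, 4],
                "dived": block[:, 5].astype(np.uint8),
            }
        )
        counts_all = np.concatenate(cue_counts)
        cue_ptr = np.zeros(len(table) + 1, dtype=np.int64)
        np.cumsum(counts_all, out=cue_ptr[1:])
        cat = lambda parts: (
            np.concatenate(parts) if parts else np.empty(0, dtype=float)
        )
        cue_dt = cat(cue_dt_parts)
        cue_dist = cat(cue_dist_parts)
        cue_bear = cat(cue_bear_parts)
    else:
        table = pd.DataFrame(columns=RECORD_COLUMNS)
        cue_ptr = np.zeros(1, dtype=np.int64)
        cue_dt = cue_dist = cue_bear = np.empty(0, dtype=float)

    return DiscretizedObservations(
        table=table,
        cue_dt=cue_dt,
        cue_dist=cue_dist,
        cue_bearing=cue_bear,
        cue_ptr=cue_ptr,
        step=float(step),
        max_lag=max_lag,
        max_dist=max_dist,
    )
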