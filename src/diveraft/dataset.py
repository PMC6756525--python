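"""Raft datasets: surface trajectories plus dive events, in body lengths.

The on-disk form is two delimited tables:

* tracks:  ``raft_id, bird_id, time_s, x_bl, y_bl``
* dives:   ``raft_id, bird_id, time_s, x_bl, y_bl, heading_deg``

Times are seconds from the start of the clip; positions are ground-plane
coordinates in body lengths (BL).  A bird's trajectory ends at its dive
time if it dives; dive times are continuous (not snapped to frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RaftDataset", "TRACK_COLUMNS", "DIVE_COLUMNS", "heading_from_displacements"]

TRACK_COLUMNS = ["raft_id", "bird_id", "time_s", "x_bl", "y_bl"]
DIVE_COLUMNS = ["raft_id", "bird_id", "time_s", "x_bl", "y_bl", "heading_deg"]


def heading_from_displacements(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Heading (degrees, 0 = +x, counter-clockwise) at each sample.

    Birds are assumed to face their direction of movement: the heading at
    sample i is the direction of the displacement from sample i-1 to i.
    The first sample copies the first defined heading.  A length-1 track
    gets NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    h = np.full(x.shape, np.nan)
    if x.size >= 2:
        h[1:] = np.degrees(np.arctan2(np.diff(y), np.diff(x)))
        h[0] = h[1]
    return h


@dataclass
class RaftDataset:
    """One or more rafts of trajectories and dive events.

    Attributes
    ----------
    tracks : pandas.DataFrame
        Columns :data:`TRACK_COLUMNS`; rows sorted by raft, bird, time.
    dives : pandas.DataFrame
        Columns :data:`DIVE_COLUMNS`; at most one dive per bird.
    metadata : dict
        Free-form; recognised keys include ``duration`` (s), ``fps``,
        ``body_length_m`` and ``labels`` (the simulator's internal
        per-interval social/dive labels, when available).
    """

    tracks: pd.DataFrame
    dives: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tracks = pd.DataFrame(self.tracks, columns=TRACK_COLUMNS)
        self.dives = pd.DataFrame(self.dives, columns=DIVE_COLUMNS)
        self.validate()

    def validate(self) -> None:
        if len(self.tracks):
            xy = self.tracks[["time_s", "x_bl", "y_bl"]].to_numpy()
            if not np.isfinite(xy).all():
                raise ValueError("tracks contain non-finite values")
            t = self.tracks.groupby(["raft_id", "bird_id"], sort=False)["time_s"]
            if not (t.apply(lambda s: bool(np.all(np.diff(s.to_numpy()) > 0)))).all():
                raise ValueError("times must be strictly increasing within a trajectory")
        if len(self.dives):
            if self.dives.duplicated(["raft_id", "bird_id"]).any():
                raise ValueError("at most one dive per bird per raft")

    # -- convenience ---------------------------------------------------
    @property
    def raft_ids(self) -> list:
        ids = set(self.tracks["raft_id"]) | set(self.dives["raft_id"])
        return sorted(ids)

    @property
    def n_birds(self) -> int:
        if not len(self.tracks):
            return 0
        return self.tracks.groupby("raft_id")["bird_id"].nunique().sum()

    @property
    def n_dives(self) -> int:
        return len(self.dives)

    @property
    def duration(self) -> float:
        if "duration" in self.metadata:
            return float(self.metadata["duration"])
        if not len(self.tracks):
            return 0.0
        return float(self.tracks["time_s"].max())

    def raft(self, raft_id) -> "RaftDataset":
        """A view-copy restricted to one raft."""
        return RaftDataset(
            self.tracks[self.tracks["raft_id"] == raft_id].reset_index(drop=True),
            self.dives[self.dives["raft_id"] == raft_id].reset_index(drop=True),
            dict(self.metadata),
        )

    @staticmethod
    def concat(datasets: list["RaftDataset"]) -> "RaftDataset":
        """Pool several datasets; raft ids must already be distinct."""
        if not datasets:
            return RaftDataset(
                pd.DataFrame(columns=TRACK_COLUMNS), pd.DataFrame(columns=DIVE_COLUMNS)
            )
        tracks = pd.concat([d.tracks for d in datasets], ignore_index=True)
        dives = pd.concat([d.dives for d in datasets], ignore_index=True)
        meta: dict = {}
        for d in datasets:
            for k, v in d.metadata.items():
                meta.setdefault(k, v)
        meta.pop("labels", None)  # per-raft tables do not pool meaningfully
        return RaftDataset(tracks, dives, meta)

    # -- IO ------------------------------------------------------------
    def write_tables(self, tracks_path, dives_path) -> None:
        self.tracks.to_csv(tracks_path, index=False)
        self.dives.to_csv(dives_path, index=False)

    @classmethod
    def read_tables(cls, tracks_path, dives_path=None, metadata=None) -> "RaftDataset":
        tracks = pd.read_csv(tracks_path)
        missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        if dives_path is not None and Path(dives_path).exists():
            dives = pd.read_csv(dives_path)
        else:
            dives = pd.DataFrame(columns=DIVE_COLUMNS)
        return cls(tracks[TRACK_COLUMNS], dives[DIVE_COLUMNS], metadata or {})
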