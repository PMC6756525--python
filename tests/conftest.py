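import numpy as np
import pandas as pd
import pytest

import diveraft as dr
from diveraft.dataset import DIVE_COLUMNS, TRACK_COLUMNS


@pytest.fixture(scope="session")
def social_dataset():
    """Three moderately sized rafts under the reference social process."""
    return dr.simulate_rafts(3, dr.RaftConfig(n_birds=60), seed=101)


@pytest.fixture(scope="session")
def social_obs(social_dataset):
    return dr.discretize(social_dataset)


def make_dataset(tracks_rows, dives_rows, metadata=None):
    """Build a RaftDataset from plain tuples."""
    return dr.RaftDataset(
        pd.DataFrame(tracks_rows, columns=TRACK_COLUMNS),
        pd.DataFrame(dives_rows, columns=DIVE_COLUMNS),
        metadata or {},
    )


def straight_track(
    bird_id, t0, t1, x0, y0, heading_deg, speed=1.0, dt=0.04, raft_id=0
):
    """Rows for a constant-velocity track from t0 to t1."""
    t = np.arange(t0, t1 + 1e-9, dt)
    hx = np.cos(np.radians(heading_deg))
    hy = np.sin(np.radians(heading_deg))
    return [
        (raft_id, bird_id, float(ti), x0 + speed * (ti - t0) * hx, y0 + speed * (ti - t0) * hy)
        for ti in t
    ]
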