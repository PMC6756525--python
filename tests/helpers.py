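"""Independent oracles used by the test suite.

Each oracle recomputes a quantity straight from first principles (raw
tables, exhaustive enumeration, two explicit loops) without touching the
accelerated code paths it checks.
"""

from itertools import permutations

import numpy as np


def brute_force_social_labels(obs, dataset, params):
    """Social label per record by scanning every dive in the raw dive
    table - no candidate-cue acceleration."""
    labels = np.zeros(obs.n_records, dtype=bool)
    dives_by_raft = {
        rid: g for rid, g in dataset.dives.groupby("raft_id")
    }
    table = obs.table
    for i in range(obs.n_records):
        row = table.iloc[i]
        g = dives_by_raft.get(row["raft_id"])
        if g is None:
            continue
        for d in g.itertuples():
            if d.bird_id == row["bird_id"]:
                continue
            dt = row["t_start"] - d.time_s
            if not (0.0 < dt <= params.lag):
                continue
            dist = np.hypot(d.x_bl - row["x_bl"], d.y_bl - row["y_bl"])
            if not dist < params.distance:
                continue
            bearing = abs(
                (np.degrees(np.arctan2(d.y_bl - row["y_bl"], d.x_bl - row["x_bl"]))
                 - row["heading_deg"] + 180.0) % 360.0 - 180.0
            )
            if bearing <= params.angle / 2.0:
                labels[i] = True
                break
    return labels


def brute_force_loglik(obs, dataset, params, step=0.5):
    """Per-record Bernoulli log-likelihood summed in a plain loop."""
    labels = brute_force_social_labels(obs, dataset, params)
    ps0 = 1.0 - (1.0 - params.p0) ** step
    ps1 = 1.0 - (1.0 - params.p1) ** step
    total = 0.0
    dived = obs.dived
    for i in range(obs.n_records):
        p = ps1 if labels[i] else ps0
        total += np.log(p) if dived[i] else np.log1p(-p)
    return total, labels


def exhaustive_labels_matrix(obs, dataset, params):
    """Social labels by testing every record against every dive in one
    dense (records x dives) matrix per raft - an exhaustive scan of the
    raw tables with no candidate-list acceleration."""
    table = obs.table.reset_index(drop=True)
    labels = np.zeros(len(table), dtype=bool)
    for rid, g in dataset.dives.groupby("raft_id"):
        rows = table[table.raft_id == rid]
        if not len(rows) or not len(g):
            continue
        dt = rows["t_start"].to_numpy()[:, None] - g["time_s"].to_numpy()[None, :]
        dx = g["x_bl"].to_numpy()[None, :] - rows["x_bl"].to_numpy()[:, None]
        dy = g["y_bl"].to_numpy()[None, :] - rows["y_bl"].to_numpy()[:, None]
        dist = np.hypot(dx, dy)
        bearing = np.abs(
            (np.degrees(np.arctan2(dy, dx)) - rows["heading_deg"].to_numpy()[:, None]
             + 180.0) % 360.0 - 180.0
        )
        other = g["bird_id"].to_numpy()[None, :] != rows["bird_id"].to_numpy()[:, None]
        ok = (
            other
            & (dt > 0.0)
            & (dt <= params.lag)
            & (dist < params.distance)
            & (bearing <= params.angle / 2.0)
        )
        labels[rows.index.to_numpy()] = ok.any(axis=1)
    return labels


def brute_force_assignment(cost):
    """Exhaustive minimum-cost one-to-one matching (rows <= cols)."""
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    best, best_cols = np.inf, None
    for cols in permutations(range(m), n):
        c = cost[np.arange(n), list(cols)].sum()
        if c < best:
            best, best_cols = c, cols
    return best, best_cols


def brute_force_waic(loglik):
    """WAIC by two explicit loops over records and samples."""
    ll = np.asarray(loglik, dtype=float)
    S, N = ll.shape
    lppd = 0.0
    p_waic = 0.0
    for i in range(N):
        lppd += np.log(sum(np.exp(ll[s, i]) for s in range(S)) / S)
        mean = sum(ll[s, i] for s in range(S)) / S
        p_waic += sum((ll[s, i] - mean) ** 2 for s in range(S)) / (S - 1)
    return -2.0 * (lppd - p_waic), lppd, p_waic
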