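"""Spatial structure and dive-following statistics of foraging rafts.

All focal-frame statistics place the focal bird at the origin with its
heading pointing "front" (+y, right = +x): every neighbour or dive
offset is rotated by the focal's heading before binning on a square
grid.  Densities are normalized so the highest cell is 1; heading maps
carry circular means and circular variance (1 minus the mean resultant
length); fraction maps give the share of binned conspecific dives that
the focal followed within a fixed window.  Empty cells are missing
(NaN) in heading and fraction maps - zero is meaningful only for counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import RaftDataset, heading_from_displacements
from .params import DiveModelParams

__all__ = [
    "GridSpec",
    "Heatmap",
    "relative_neighbour_density",
    "relative_heading_field",
    "fraction_followed",
    "randomize_dive_times",
    "RandomizationResult",
    "wave_diagnostic",
    "summary_stats",
    "transmission_speed",
    "quadrant_means",
    "front_back_fractions",
    "plot_heatmap",
]


@dataclass(frozen=True)
class GridSpec:
    """Focal-frame square grid: half-width ``extent`` and cell size in BL."""

    extent: float = 40.0
    cell: float = 2.0

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell must be positive")
        ratio = self.extent / self.cell
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("extent must be an integer number of cells")

    @property
    def edges(self) -> np.ndarray:
        n = int(round(self.extent / self.cell))
        return np.linspace(-self.extent, self.extent, 2 * n + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return (e[:-1] + e[1:]) / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        n = 2 * int(round(self.extent / self.cell))
        return (n, n)


@dataclass
class Heatmap:
    """2-D focal-frame grid; ``values[iy, ix]`` with y (front) increasing
    with iy.  ``norm_max`` records the pre-normalization maximum count."""

    values: np.ndarray
    kind: str
    grid: GridSpec
    norm_max: float | None = None
    counts: np.ndarray | None = None

    def to_csv(self, path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",")
        sidecar = {
            "kind": self.kind,
            "extent_bl": self.grid.extent,
            "cell_bl": self.grid.cell,
            "norm_max": self.norm_max,
            "orientation": "rows = back to front (+y), cols = left to right (+x)",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _rotate_to_focal(dx, dy, heading_deg):
    """World offset -> focal frame (x right, y front) given focal heading."""
    phi = np.radians(heading_deg)
    fwd = dx * np.cos(phi) + dy * np.sin(phi)
    right = dx * np.sin(phi) - dy * np.cos(phi)
    return right, fwd


class _RaftArrays:
    """(bird x frame) position/heading arrays for one raft, NaN off-track."""

    def __init__(self, tracks: pd.DataFrame, dives: pd.DataFrame):
        self.times = np.unique(tracks["time_s"].to_numpy(float))
        self.bird_ids = sorted(tracks["bird_id"].unique().tolist())
        n, F = len(self.bird_ids), len(self.times)
        self.X = np.full((n, F), np.nan)
        self.Y = np.full((n, F), np.nan)
        self.H = np.full((n, F), np.nan)
        index = {b: i for i, b in enumerate(self.bird_ids)}
        for b, g in tracks.groupby("bird_id"):
            i = index[b]
            t = g["time_s"].to_numpy(float)
            x = g["x_bl"].to_numpy(float)
            y = g["y_bl"].to_numpy(float)
            j = np.searchsorted(self.times, t)
            self.X[i, j] = x
            self.Y[i, j] = y
            self.H[i, j] = heading_from_displacements(x, y)
            # carry the last sample forward across other birds' off-grid
            # times ("position at or before t"), but never past track end
            span = (self.times >= t[0]) & (self.times <= t[-1])
            for arr2 in (self.X, self.Y, self.H):
                row = arr2[i]
                good = np.isfinite(row) & span
                fill = np.where(good, np.arange(F), -1)
                fill = np.maximum.accumulate(fill)
                inside = span & (fill >= 0)
                row[inside] = row[fill[inside]]
        self.index = index
        self.dive_time = np.full(n, np.inf)
        for row in dives.itertuples():
            if row.bird_id in index:
                self.dive_time[index[row.bird_id]] = row.time_s

    def sample_frames(self, stride_s: float) -> np.ndarray:
        if stride_s <= 0:
            return np.arange(len(self.times))
        wanted = np.arange(self.times[0], self.times[-1] + 1e-9, stride_s)
        j = np.searchsorted(self.times, wanted + 1e-9) - 1
        return np.unique(j[j >= 0])

    def state_at(self, t: float):
        """Positions and headings at the last sample <= t (NaN if none)."""
        j = int(np.searchsorted(self.times, t + 1e-12)) - 1
        if j < 0:
            n = len(self.bird_ids)
            nanv = np.full(n, np.nan)
            return nanv, nanv, nanv
        return self.X[:, j], self.Y[:, j], self.H[:, j]


def _rafts(dataset: RaftDataset):
    for rid in dataset.raft_ids:
        tracks = dataset.tracks[dataset.tracks["raft_id"] == rid]
        dives = dataset.dives[dataset.dives["raft_id"] == rid]
        if len(tracks):
            yield rid, _RaftArrays(tracks, dives), dives


def relative_neighbour_density(
    dataset: RaftDataset, grid: GridSpec | None = None, stride_s: float = 0.5
) -> Heatmap:
    """Normalized focal-frame neighbour counts over all (focal, neighbour,
    timestep) triples; the densest cell is exactly 1 on non-empty data."""
    grid = grid or GridSpec()
    counts = np.zeros(grid.shape)
    for _, arr, _ in _rafts(dataset):
        for j in arr.sample_frames(stride_s):
            x, y, h = arr.X[:, j], arr.Y[:, j], arr.H[:, j]
            ok = np.isfinite(x) & np.isfinite(h)
            x, y, h = x[ok], y[ok], h[ok]
            m = x.size
            if m < 2:
                continue
            dx = x[None, :] - x[:, None]
            dy = y[None, :] - y[:, None]
            keep = ~np.eye(m, dtype=bool)
            hx = np.broadcast_to(h[:, None], (m, m))[keep]
            gx, gy = _rotate_to_focal(dx[keep], dy[keep], hx)
            hist, _, _ = np.histogram2d(gy, gx, bins=(grid.edges, grid.edges))
            counts += hist
    norm_max = float(counts.max())
    values = counts / norm_max if norm_max > 0 else counts
    return Heatmap(values, "normalized-density", grid, norm_max, counts)


def relative_heading_field(
    dataset: RaftDataset, grid: GridSpec | None = None, stride_s: float = 0.5
) -> tuple[Heatmap, Heatmap]:
    """Per cell: circular mean of (neighbour heading - focal heading) and
    circular variance 1 - Rbar.  Empty cells are NaN."""
    grid = grid or GridSpec()
    n_cells = grid.shape
    cnt = np.zeros(n_cells)
    sc = np.zeros(n_cells)
    ss = np.zeros(n_cells)
    bins = (grid.edges, grid.edges)
    for _, arr, _ in _rafts(dataset):
        for j in arr.sample_frames(stride_s):
            x, y, h = arr.X[:, j], arr.Y[:, j], arr.H[:, j]
            ok = np.isfinite(x) & np.isfinite(h)
            x, y, h = x[ok], y[ok], h[ok]
            m = x.size
            if m < 2:
                continue
            dx = x[None, :] - x[:, None]
            dy = y[None, :] - y[:, None]
            keep = ~np.eye(m, dtype=bool)
            hf = np.broadcast_to(h[:, None], (m, m))[keep]
            hn = np.broadcast_to(h[None, :], (m, m))[keep]
            gx, gy = _rotate_to_focal(dx[keep], dy[keep], hf)
            rel = np.radians(hn - hf)
            cnt += np.histogram2d(gy, gx, bins=bins)[0]
            sc += np.histogram2d(gy, gx, bins=bins, weights=np.cos(rel))[0]
            ss += np.histogram2d(gy, gx, bins=bins, weights=np.sin(rel))[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_h = np.degrees(np.arctan2(ss, sc))
        rbar = np.hypot(sc, ss) / cnt
        circ_var = 1.0 - rbar
    mean_h[cnt == 0] = np.nan
    circ_var[cnt == 0] = np.nan
    return (
        Heatmap(mean_h, "mean-heading", grid, counts=cnt),
        Heatmap(circ_var, "circular-variance", grid, counts=cnt),
    )


def _followed_offsets(arr: _RaftArrays, dives: pd.DataFrame, window: float):
    """Focal-frame offsets of each conspecific dive and whether the focal
    followed within the window.  Vectorized over (dive, focal) pairs."""
    nd = len(dives)
    if nd == 0:
        return (np.empty(0),) * 3
    t_d = dives["time_s"].to_numpy(float)
    x_d = dives["x_bl"].to_numpy(float)
    y_d = dives["y_bl"].to_numpy(float)
    divers = np.array(
        [arr.index.get(b, -1) for b in dives["bird_id"].to_numpy()], dtype=int
    )
    j_d = np.searchsorted(arr.times, t_d + 1e-12) - 1
    j_d = np.clip(j_d, 0, len(arr.times) - 1)
    X = arr.X[:, j_d]  # (n_birds, n_dives)
    Y = arr.Y[:, j_d]
    H = arr.H[:, j_d]
    ok = np.isfinite(X) & np.isfinite(H)
    if np.any(divers >= 0):
        valid = divers >= 0
        ok[divers[valid], np.flatnonzero(valid)] = False  # a dive never cues its diver
    dx = x_d[None, :] - X
    dy = y_d[None, :] - Y
    gx, gy = _rotate_to_focal(dx, dy, H)
    own = arr.dive_time[:, None]
    followed = (own > t_d[None, :]) & (own <= t_d[None, :] + window)
    return gx[ok], gy[ok], followed[ok]


def fraction_followed(
    dataset: RaftDataset, grid: GridSpec | None = None, window: float = 2.0
) -> tuple[Heatmap, Heatmap]:
    """Focal-frame dive density and the fraction of those dives followed
    by the focal diving within ``window`` seconds."""
    grid = grid or GridSpec()
    bins = (grid.edges, grid.edges)
    cnt = np.zeros(grid.shape)
    fol = np.zeros(grid.shape)
    for _, arr, dives in _rafts(dataset):
        gx, gy, followed = _followed_offsets(arr, dives, window)
        if gx.size:
            cnt += np.histogram2d(gy, gx, bins=bins)[0]
            fol += np.histogram2d(gy, gx, bins=bins, weights=followed.astype(float))[0]
    norm_max = float(cnt.max())
    density = Heatmap(
        cnt / norm_max if norm_max > 0 else cnt, "count", grid, norm_max, cnt
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = fol / cnt
    frac[cnt == 0] = np.nan
    return density, Heatmap(frac, "fraction", grid, counts=cnt)


@dataclass
class RandomizationResult:
    """Permutation null for the dive-following map."""

    mean_map: Heatmap
    perm_stats: pd.DataFrame  # per permutation: mean fraction, front/back means
    n_permutations: int
    seed: int | None = None


def front_back_fractions(
    followed: np.ndarray, counts: np.ndarray, grid: GridSpec, split: str = "half"
):
    """Count-weighted followed-fractions pooled front versus back.

    ``split="half"`` pools the +y and -y halves of the grid;
    ``split="quadrant"`` pools the diagonal front and back quadrants,
    which separates the visual-arc geometry more sharply (a wide arc
    reaches slightly past abeam, so the rear half-plane is not entirely
    outside it, whereas the rear quadrant is).
    """
    cy = grid.centers[:, None]
    cx = grid.centers[None, :]
    if split == "half":
        front = np.broadcast_to(cy > 0, counts.shape)
        back = ~front
    elif split == "quadrant":
        front = (cy > 0) & (np.abs(cy) > np.abs(cx))
        back = (cy < 0) & (np.abs(cy) > np.abs(cx))
        front = np.broadcast_to(front, counts.shape)
        back = np.broadcast_to(back, counts.shape)
    else:
        raise ValueError("split must be 'half' or 'quadrant'")
    f_n, b_n = counts[front].sum(), counts[back].sum()
    f = float(followed[front].sum() / f_n) if f_n else np.nan
    b = float(followed[back].sum() / b_n) if b_n else np.nan
    return f, b


def randomize_dive_times(
    dataset: RaftDataset,
    grid: GridSpec | None = None,
    n: int = 1000,
    seed: int | None = None,
    window: float = 2.0,
) -> RandomizationResult:
    """Null dive-following map: dive times are permuted across each raft's
    dive events (positions and orientations preserved) ``n`` times and the
    fraction-followed map averaged over permutations."""
    grid = grid or GridSpec()
    if dataset.n_dives < 2:
        raise ValueError("need at least 2 dives to randomize")
    rng = np.random.default_rng(seed)
    bins = (grid.edges, grid.edges)
    rafts = list(_rafts(dataset))
    sum_frac = np.zeros(grid.shape)
    n_valid = np.zeros(grid.shape)
    stats = []
    for _ in range(n):
        cnt = np.zeros(grid.shape)
        fol = np.zeros(grid.shape)
        for _, arr, dives in rafts:
            perm = dives.copy()
            perm["time_s"] = rng.permutation(perm["time_s"].to_numpy())
            # the events' permuted times are also the birds' new dive times
            arr_perm_dive = arr.dive_time.copy()
            arr.dive_time = np.full_like(arr.dive_time, np.inf)
            for row in perm.itertuples():
                if row.bird_id in arr.index:
                    arr.dive_time[arr.index[row.bird_id]] = row.time_s
            gx, gy, followed = _followed_offsets(arr, perm, window)
            arr.dive_time = arr_perm_dive
            if gx.size:
                cnt += np.histogram2d(gy, gx, bins=bins)[0]
                fol += np.histogram2d(
                    gy, gx, bins=bins, weights=followed.astype(float)
                )[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = fol / cnt
        valid = cnt > 0
        sum_frac[valid] += frac[valid]
        n_valid += valid
        fmean, bmean = front_back_fractions(fol, cnt, grid, split="half")
        fquad, bquad = front_back_fractions(fol, cnt, grid, split="quadrant")
        stats.append(
            (
                float(fol.sum() / cnt.sum()) if cnt.sum() else np.nan,
                fmean,
                bmean,
                fquad,
                bquad,
            )
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum_frac / n_valid
    mean[n_valid == 0] = np.nan
    return RandomizationResult(
        Heatmap(mean, "fraction", grid, counts=n_valid),
        pd.DataFrame(
            stats,
            columns=[
                "mean_fraction",
                "front_mean",
                "back_mean",
                "front_quad_mean",
                "back_quad_mean",
            ],
        ),
        n,
        seed,
    )


def wave_diagnostic(
    dataset: RaftDataset, window: float = 10.0, exclude_lag: float = 2.0
) -> tuple[pd.DataFrame, dict]:
    """Relative time versus along-heading distance for ordered dive pairs.

    For each ordered pair of dives in a raft with |Δt| <= ``window``,
    emits (Δt = t_other - t_focal, signed along-heading offset of the
    other dive in the focal dive's frame).  A dive wave sweeping through
    the raft leaves a coherent negative correlation between Δt and offset
    (dives before and in front, after and behind); social copying at
    short lags does not.  The summary reports quadrant counts and the
    Pearson correlation restricted to |Δt| >= ``exclude_lag`` (outside
    the copy window), which is the wave score.
    """
    rows = []
    for rid in dataset.raft_ids:
        dv = dataset.dives[dataset.dives["raft_id"] == rid]
        nd = len(dv)
        if nd < 2:
            continue
        t = dv["time_s"].to_numpy(float)
        x = dv["x_bl"].to_numpy(float)
        y = dv["y_bl"].to_numpy(float)
        h = dv["heading_deg"].to_numpy(float)
        dt = t[None, :] - t[:, None]
        keep = (np.abs(dt) <= window) & ~np.eye(nd, dtype=bool)
        dx = x[None, :] - x[:, None]
        dy = y[None, :] - y[:, None]
        hf = np.broadcast_to(h[:, None], (nd, nd))
        _, along = _rotate_to_focal(dx[keep], dy[keep], hf[keep])
        for a, b in zip(dt[keep], along):
            rows.append((rid, float(a), float(b)))
    df = pd.DataFrame(rows, columns=["raft_id", "dt_s", "along_bl"])
    dt = df["dt_s"].to_numpy()
    al = df["along_bl"].to_numpy()
    lag_mask = np.abs(dt) >= exclude_lag
    summary = {
        "n_pairs": int(len(df)),
        "n_front_before": int(np.sum((dt < 0) & (al > 0))),
        "n_front_after": int(np.sum((dt > 0) & (al > 0))),
        "n_back_before": int(np.sum((dt < 0) & (al < 0))),
        "n_back_after": int(np.sum((dt > 0) & (al < 0))),
        "corr_all": float(np.corrcoef(dt, al)[0, 1]) if len(df) > 2 else np.nan,
        "corr_long_lag": (
            float(np.corrcoef(dt[lag_mask], al[lag_mask])[0, 1])
            if lag_mask.sum() > 2
            else np.nan
        ),
    }
    return df, summary


def transmission_speed(params: DiveModelParams) -> float:
    """Apparent social transmission speed D/T in BL/s."""
    return params.distance / params.lag


def summary_stats(
    dataset: RaftDataset,
    params: DiveModelParams | None = None,
    stride_s: float = 0.5,
) -> dict:
    """Raft-level summaries: nearest-neighbour distance, speed,
    inter-dive intervals and relative headings (plus the transmission
    speed when interaction parameters are supplied)."""
    nnds, speeds, rel_headings, intervals = [], [], [], []
    for _, arr, dives in _rafts(dataset):
        for j in arr.sample_frames(stride_s):
            x, y, h = arr.X[:, j], arr.Y[:, j], arr.H[:, j]
            ok = np.isfinite(x)
            x, y = x[ok], y[ok]
            m = x.size
            if m >= 2:
                d = np.hypot(x[None, :] - x[:, None], y[None, :] - y[:, None])
                np.fill_diagonal(d, np.inf)
                nnds.append(d.min(axis=1))
                hh = h[ok]
                hok = np.isfinite(hh)
                if hok.sum() >= 2:
                    rel = hh[hok][None, :] - hh[hok][:, None]
                    rel = rel[~np.eye(hok.sum(), dtype=bool)]
                    rel_headings.append((rel + 180.0) % 360.0 - 180.0)
        t_d = np.sort(dives["time_s"].to_numpy(float))
        if t_d.size >= 2:
            intervals.append(np.diff(t_d))
    # speeds over each bird's own samples (not the pooled time grid)
    for _, g in dataset.tracks.groupby(["raft_id", "bird_id"], sort=False):
        t = g["time_s"].to_numpy(float)
        if t.size >= 2:
            d = np.hypot(np.diff(g["x_bl"].to_numpy()), np.diff(g["y_bl"].to_numpy()))
            speeds.append(d / np.diff(t))
    nnds = np.concatenate(nnds) if nnds else np.empty(0)
    speeds = np.concatenate(speeds) if speeds else np.empty(0)
    rel_headings = np.concatenate(rel_headings) if rel_headings else np.empty(0)
    intervals = np.concatenate(intervals) if intervals else np.empty(0)
    out = {
        "nnd_mean": float(nnds.mean()) if nnds.size else np.nan,
        "nnd_sd": float(nnds.std(ddof=1)) if nnds.size > 1 else np.nan,
        "speed_mean": float(speeds.mean()) if speeds.size else np.nan,
        "speed_sd": float(speeds.std(ddof=1)) if speeds.size > 1 else np.nan,
        "dive_intervals_s": intervals,
        "relative_heading_deg": rel_headings,
        "n_dives": int(dataset.n_dives),
    }
    if params is not None:
        out["transmission_speed_bl_s"] = transmission_speed(params)
    return out


def plot_heatmap(hm: Heatmap, ax=None, path=None, **imshow_kwargs):
    """Render a heatmap with the focal bird at the origin facing up.

    Returns the matplotlib Axes; saves a PNG when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    e = hm.grid.extent
    im = ax.imshow(
        hm.values,
        origin="lower",
        extent=(-e, e, -e, e),
        **{"cmap": "viridis", **imshow_kwargs},
    )
    ax.set_xlabel("right offset (BL)")
    ax.set_ylabel("front offset (BL)")
    ax.set_title(hm.kind)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax


def quadrant_means(hm: Heatmap) -> dict[str, float]:
    """Mean map value in the front, back, left and right quadrants
    (diagonal-split, cell centres)."""
    cy = hm.grid.centers[:, None]
    cx = hm.grid.centers[None, :]
    v = hm.values
    out = {}
    with np.errstate(invalid="ignore"):
        for name, mask in (
            ("front", (cy > 0) & (np.abs(cy) > np.abs(cx))),
            ("back", (cy < 0) & (np.abs(cy) > np.abs(cx))),
            ("left", (cx < 0) & (np.abs(cx) > np.abs(cy))),
            ("right", (cx > 0) & (np.abs(cx) > np.abs(cy))),
        ):
            cell = v[np.broadcast_to(mask, v.shape)]
            out[name] = float(np.nanmean(cell)) if np.isfinite(cell).any() else np.nan
    return out
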