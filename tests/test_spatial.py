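import numpy as np
import pandas as pd
import pytest

import diveraft as dr
from conftest import make_dataset, straight_track
from diveraft import GridSpec, transmission_speed
from diveraft.spatial import (
    fraction_followed,
    front_back_fractions,
    randomize_dive_times,
    relative_heading_field,
    relative_neighbour_density,
    summary_stats,
    wave_diagnostic,
)


def test_grid_spec_validation():
    with pytest.raises(ValueError):
        GridSpec(extent=40.0, cell=3.0)
    g = GridSpec(extent=40.0, cell=2.0)
    assert g.shape == (40, 40)
    assert g.edges[0] == -40.0 and g.edges[-1] == 40.0


def test_side_by_side_pair_gives_two_symmetric_unit_cells():
    """Two birds abreast with one heading: each sees the other exactly
    abeam, so the map has two unit cells mirrored left/right."""
    rows = straight_track(0, 0.0, 10.0, 0.0, 0.0, 90.0) + straight_track(
        1, 0.0, 10.0, 5.0, 0.0, 90.0
    )
    ds = make_dataset(rows, [], {"duration": 10.0})
    hm = relative_neighbour_density(ds, GridSpec(10.0, 2.0))
    nz = np.argwhere(hm.values > 0)
    assert len(nz) == 2
    assert hm.values[tuple(nz[0])] == 1.0 and hm.values[tuple(nz[1])] == 1.0
    c = hm.grid.centers
    xs = sorted(c[j] for _, j in nz)
    ys = [c[i] for i, _ in nz]
    assert xs[0] == -xs[1]  # mirrored across the heading axis
    assert all(abs(y) <= 1.0 for y in ys)  # abeam, within one cell of zero


def _rotated(ds, deg):
    r = np.radians(deg)
    R = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
    tracks = ds.tracks.copy()
    xy = tracks[["x_bl", "y_bl"]].to_numpy() @ R.T
    tracks[["x_bl", "y_bl"]] = xy
    dives = ds.dives.copy()
    if len(dives):
        xy = dives[["x_bl", "y_bl"]].to_numpy() @ R.T
        dives[["x_bl", "y_bl"]] = xy
        dives["heading_deg"] = dives["heading_deg"] + deg
    return dr.RaftDataset(tracks, dives, dict(ds.metadata))


def test_focal_frame_maps_invariant_under_global_rotation():
    ds = dr.simulate_raft(dr.RaftConfig(n_birds=25, duration=20.0), seed=33)
    grid = GridSpec(30.0, 2.0)
    base = relative_neighbour_density(ds, grid)
    rot = relative_neighbour_density(_rotated(ds, 90.0), grid)
    assert np.allclose(base.values, rot.values, atol=1e-12)
    d0, f0 = fraction_followed(ds, grid)
    d1, f1 = fraction_followed(_rotated(ds, 90.0), grid)
    assert np.allclose(d0.counts, d1.counts, atol=1e-12)
    assert np.allclose(
        np.nan_to_num(f0.values, nan=-1), np.nan_to_num(f1.values, nan=-1), atol=1e-12
    )


def _co_located_neighbours(starts_headings):
    """A straight focal plus neighbours that stay inside one focal-frame
    cell (~10 BL ahead, right offsets within [1, 1.4]) while moving along
    their own headings."""
    rows = straight_track(0, 0.0, 1.0, 0.0, 0.0, 90.0)
    for k, (x0, h) in enumerate(starts_headings, start=1):
        rows += straight_track(k, 0.0, 1.0, x0, 10.0, h, speed=0.4)
    return make_dataset(rows, [], {"duration": 1.0})


def test_circular_variance_closed_forms():
    grid = GridSpec(20.0, 4.0)
    # neighbours sit ~10 BL ahead, slightly to the right of the focal
    cell = (np.abs(grid.centers - 10.0).argmin(), np.abs(grid.centers - 2.0).argmin())

    aligned = _co_located_neighbours([(1.0, 90.0), (1.2, 90.0), (1.4, 90.0)])
    _, cv = relative_heading_field(aligned, grid, stride_s=0.1)
    assert cv.values[cell] == pytest.approx(0.0, abs=1e-12)

    antipodal = _co_located_neighbours([(1.0, 0.0), (1.4, 180.0)])
    _, cv = relative_heading_field(antipodal, grid, stride_s=0.1)
    assert cv.values[cell] == pytest.approx(1.0, abs=1e-12)

    # diagonal headings keep the focal out of this cell in every
    # neighbour's own frame (a reversed heading would mirror it back in)
    orthogonal = _co_located_neighbours(
        [(1.0, 45.0), (1.4, 135.0), (1.2, 225.0), (1.2, 315.0)]
    )
    _, cv = relative_heading_field(orthogonal, grid, stride_s=0.1)
    assert cv.values[cell] == pytest.approx(1.0, abs=1e-12)

    empty_cells = ~np.isfinite(cv.values)
    assert empty_cells.any()  # unpopulated cells are missing, not zero


def test_followed_dive_within_window_gives_unit_fraction():
    focal = straight_track(0, 0.0, 12.0, 0.0, 0.0, 90.0)
    other = straight_track(1, 0.0, 11.0, 0.0, 10.0, 90.0)
    dives = [
        (0, 1, 11.0, other[-1][3], other[-1][4], 90.0),
        (0, 0, 12.0, focal[-1][3], focal[-1][4], 90.0),
    ]
    ds = make_dataset(focal + other, dives, {"duration": 15.0})
    _, frac = fraction_followed(ds, GridSpec(20.0, 2.0), window=2.0)
    vals = frac.values[np.isfinite(frac.values)]
    assert 1.0 in vals  # the focal followed the dive ahead within 1 s


def test_never_following_focal_gives_zero_fractions():
    focal = straight_track(0, 0.0, 30.0, 0.0, 0.0, 90.0)
    other = straight_track(1, 0.0, 11.0, 0.0, 10.0, 90.0)
    dives = [(0, 1, 11.0, other[-1][3], other[-1][4], 90.0)]
    ds = make_dataset(focal + other, dives, {"duration": 30.0})
    _, frac = fraction_followed(ds, GridSpec(20.0, 2.0))
    vals = frac.values[np.isfinite(frac.values)]
    assert len(vals) and np.all(vals == 0.0)


def test_randomization_preserves_counts_and_is_deterministic(social_dataset):
    grid = GridSpec(40.0, 4.0)
    a = randomize_dive_times(social_dataset, grid, n=20, seed=4)
    b = randomize_dive_times(social_dataset, grid, n=20, seed=4)
    assert np.allclose(
        np.nan_to_num(a.mean_map.values, nan=-1),
        np.nan_to_num(b.mean_map.values, nan=-1),
    )
    pd.testing.assert_frame_equal(a.perm_stats, b.perm_stats)
    c = randomize_dive_times(social_dataset, grid, n=20, seed=5)
    assert not a.perm_stats.equals(c.perm_stats)
    assert len(a.perm_stats) == 20


def test_observed_following_exceeds_randomized_null(social_dataset):
    grid = GridSpec(40.0, 2.0)
    _, frac = fraction_followed(social_dataset, grid)
    observed = np.nansum(frac.values * frac.counts) / frac.counts.sum()
    null = randomize_dive_times(social_dataset, grid, n=50, seed=2)
    assert observed > null.perm_stats["mean_fraction"].mean()


def test_wave_diagnostic_single_pair_geometry():
    """Second dive 1 s later, 5 BL behind the first bird's heading: the
    ordered pairs are (+1, -5) and its mirror."""
    a = straight_track(0, 0.0, 2.0, 0.0, 0.0, 0.0)
    b = straight_track(1, 0.0, 3.0, -5.0, 0.0, 0.0)
    dives = [(0, 0, 2.0, 2.0, 0.0, 0.0), (0, 1, 3.0, -3.0, 0.0, 0.0)]
    ds = make_dataset(a + b, dives, {"duration": 3.0})
    df, _ = wave_diagnostic(ds)
    pts = set(zip(df.dt_s.round(6), df.along_bl.round(6)))
    assert (1.0, -5.0) in pts
    assert (-1.0, 5.0) in pts


def test_wave_data_shows_front_before_signature_social_does_not():
    wave = dr.simulate_wave_raft(dr.RaftConfig(n_birds=60), seed=6, wave_speed=5.0)
    _, sw = wave_diagnostic(wave)
    assert sw["corr_long_lag"] < -0.4
    social = dr.simulate_rafts(2, dr.RaftConfig(n_birds=60), seed=44)
    _, ss = wave_diagnostic(social)
    assert abs(ss["corr_long_lag"]) < 0.2


def test_nnd_hand_computation():
    rows = []
    for k, x in enumerate((0.0, 5.0, 12.0)):
        rows += straight_track(k, 0.0, 0.2, x, 0.0, 90.0, speed=0.0, dt=0.1)
    ds = make_dataset(rows, [], {"duration": 0.2})
    st = summary_stats(ds, stride_s=0.1)
    assert st["nnd_mean"] == pytest.approx(17.0 / 3.0, rel=1e-12)
    assert st["speed_mean"] == pytest.approx(0.0, abs=1e-12)


def test_transmission_speed_ratio():
    assert transmission_speed(dr.SHAG_RAFT_PARAMS) == pytest.approx(
        70.28 / 1.67, rel=1e-12
    )
    assert transmission_speed(dr.SHAG_RAFT_PARAMS) == pytest.approx(42.08, abs=0.01)


def test_heatmap_csv_round_trip(tmp_path, social_dataset):
    hm = relative_neighbour_density(social_dataset, GridSpec(20.0, 4.0))
    path = tmp_path / "density.csv"
    hm.to_csv(path)
    back = np.loadtxt(path, delimiter=",")
    assert np.allclose(back, hm.values)
    assert path.with_suffix(".csv.json").exists()
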