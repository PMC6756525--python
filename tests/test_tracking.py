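import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from helpers import brute_force_assignment
from diveraft.tracking import (
    Track,
    TrackingConfig,
    auction_assignment,
    average_frames,
    correct_coordinates,
    detect_blobs,
    detect_dives,
    filter_speed_outliers,
    link_detections,
)


# ---------------------------------------------------------------------
# frame averaging
# ---------------------------------------------------------------------

def test_average_of_constant_stack_is_identity():
    frames = np.full((20, 8, 8), 37.0)
    out = average_frames(frames, 6)
    assert np.allclose(out, 37.0)


def test_averaging_suppresses_alternating_flicker():
    """A pixel flickering on/off every frame is flattened by a window-6
    mean (interior frames see exactly 3 on-frames out of 6)."""
    frames = np.zeros((30, 4, 4))
    frames[::2, 2, 2] = 1.0
    out = average_frames(frames, 6)
    interior = out[4:-4, 2, 2]
    assert np.ptp(interior) < 1e-12
    assert np.allclose(interior, 0.5)
    assert np.ptp(frames[4:-4, 2, 2]) == 1.0


def test_default_window_matches_typical_field_setting():
    assert TrackingConfig().window == 6


def test_window_below_one_rejected():
    with pytest.raises(ValueError):
        average_frames(np.zeros((4, 2, 2)), 0)


# ---------------------------------------------------------------------
# blob detection
# ---------------------------------------------------------------------

def _disk_frame(shape, centers, radius=2.5, value=200.0):
    frame = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cx, cy in centers:
        frame += value * np.clip(radius + 0.5 - np.hypot(xx - cx, yy - cy), 0, 1)
    return np.clip(frame, 0, 255)


def test_blank_frame_gives_no_detections():
    assert detect_blobs(np.zeros((50, 50)), 50.0) == []


def test_single_bird_sized_blob_detected_at_centroid():
    frame = _disk_frame((60, 80), [(40.0, 30.0)])
    dets = detect_blobs(frame, 100.0, (8, 60))
    assert len(dets) == 1
    assert dets[0].x_px == pytest.approx(40.0, abs=0.1)
    assert dets[0].y_px == pytest.approx(30.0, abs=0.1)
    assert 8 <= dets[0].area_px <= 60


def test_too_small_blob_filtered_out():
    frame = _disk_frame((60, 80), [(20.0, 20.0)])
    frame[45, 60] = 250.0  # a few-pixel speck
    frame[45, 61] = 250.0
    dets = detect_blobs(frame, 100.0, (8, 60))
    assert len(dets) == 1
    assert dets[0].x_px == pytest.approx(20.0, abs=0.1)


# ---------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------

@settings(max_examples=120, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.booleans())
def test_auction_equals_exhaustive_minimum_cost_matching(seed, gated):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 7))
    m = int(rng.integers(n, 7))
    cost = rng.uniform(0.0, 3.0, (n, m))
    if gated:
        cost[rng.random((n, m)) < 0.4] = 30.0
    assign = auction_assignment(cost)
    best, _ = brute_force_assignment(cost)
    assert sorted(assign.tolist()) == sorted(set(assign.tolist()))  # one-to-one
    assert cost[np.arange(n), assign].sum() == pytest.approx(best, abs=1e-6)
    r, c = linear_sum_assignment(cost)  # independent library oracle
    assert cost[r, c].sum() == pytest.approx(best, abs=1e-9)


# ---------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------

def _det_frame_df(rows):
    return pd.DataFrame(rows, columns=["frame", "x_bl", "y_bl", "area_px"])


def test_single_smooth_target_yields_one_track():
    rows = [(f, 0.05 * f, 1.0, 20.0) for f in range(50)]
    tracks = link_detections(_det_frame_df(rows), dt=0.04)
    assert len(tracks) == 1
    assert tracks[0].n_samples == 50


def test_crossing_targets_keep_their_identities():
    """Two constant-velocity targets crossing: with optimal assignment
    each track stays on its own straight line through the crossing."""
    rows = []
    for f in range(80):
        t = f * 0.04
        rows.append((f, -2.0 + 1.3 * t, 0.5 * t, 20.0))
        rows.append((f, 2.0 - 1.3 * t, 0.5 * t, 20.0))
    tracks = link_detections(_det_frame_df(rows), dt=0.04)
    assert len(tracks) == 2
    for tr in tracks:
        x = np.asarray(tr.x_bl)
        t = np.asarray(tr.times)
        slope = np.polyfit(t, x, 1)[0]
        resid = x - np.polyval(np.polyfit(t, x, 1), t)
        assert abs(abs(slope) - 1.3) < 0.05
        assert np.max(np.abs(resid)) < 0.1


def test_isolated_detection_becomes_short_closed_track():
    rows = [(0, 0.0, 0.0, 20.0)] + [(f, 50.0 + 0.05 * f, 50.0, 20.0) for f in range(40)]
    tracks = link_detections(_det_frame_df(rows), dt=0.04)
    lengths = sorted(t.n_samples for t in tracks)
    assert lengths == [1, 40]


# ---------------------------------------------------------------------
# speed filter and dive detection
# ---------------------------------------------------------------------

def _track_with_speed(speed, track_id=0, n=50, dt=0.04):
    t = Track(track_id=track_id)
    for f in range(n):
        t.frames.append(f)
        t.times.append(f * dt)
        t.x_bl.append(speed * f * dt)
        t.y_bl.append(0.0)
        t.x_px.append(100.0 + f)
        t.y_px.append(100.0)
        t.areas.append(20.0)
    return t

@pytest.mark.parametrize(
    "speed, kept", [(1.1, True), (3.0, False), (0.0, False), (0.21, True), (2.49, True)]
)
def test_speed_filter_bounds(speed, kept):
    tracks = filter_speed_outliers([_track_with_speed(speed)])
    assert (len(tracks) == 1) is kept


def _areas_profile(kind, n):
    base = np.full(n, 20.0)
    if kind == "splash":
        base[-30:-15] = np.linspace(20, 51, 15)  # swell
        base[-15:] = np.linspace(51, 8, 15)  # collapse
    return base


def _track_with_areas(areas, end_px=(300.0, 200.0)):
    n = len(areas)
    t = Track(track_id=0)
    for f in range(n):
        t.frames.append(f)
        t.times.append(f * 0.04)
        t.x_bl.append(1.0 * f * 0.04)
        t.y_bl.append(0.0)
        t.x_px.append(end_px[0] - (n - 1 - f) * 0.5)
        t.y_px.append(end_px[1])
        t.areas.append(float(areas[f]))
    return t


def test_splash_profile_detected_as_dive_at_track_end():
    tr = _track_with_areas(_areas_profile("splash", 100))
    dives = detect_dives([tr], (480, 640))
    assert len(dives) == 1
    assert dives["time_s"].iloc[0] == pytest.approx(tr.times[-1], abs=0.04)
    assert dives["heading_deg"].iloc[0] == pytest.approx(0.0, abs=1e-6)


def test_track_ending_at_frame_edge_is_not_a_dive():
    tr = _track_with_areas(_areas_profile("splash", 100), end_px=(635.0, 200.0))
    assert len(detect_dives([tr], (480, 640))) == 0


def test_constant_area_track_end_is_not_a_dive():
    tr = _track_with_areas(_areas_profile("flat", 100))
    assert len(detect_dives([tr], (480, 640))) == 0


def test_correct_coordinates_adds_ground_bl_columns():
    from diveraft import CameraModel

    cam = CameraModel(elevation=100.0, inclination=5.0, width=640, height=480, hfov=60.0)
    det = pd.DataFrame({"x_px": [cam.cx], "y_px": [cam.cy], "area_px": [20.0]})
    out = correct_coordinates(det, cam, body_length_m=0.7)
    gx, gy = cam.ground_center()
    assert out["x_bl"].iloc[0] == pytest.approx(gx / 0.7, abs=1e-9)
    assert out["y_bl"].iloc[0] == pytest.approx(gy / 0.7, abs=1e-9)
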