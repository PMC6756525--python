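import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diveraft as dr
from diveraft import DiveModelParams, RaftConfig, simulate_raft
from diveraft.params import per_step_probability
from diveraft.spatial import quadrant_means, relative_neighbour_density


def test_identical_config_and_seed_give_identical_datasets():
    cfg = RaftConfig(n_birds=25, duration=20.0)
    a = simulate_raft(cfg, seed=3)
    b = simulate_raft(cfg, seed=3)
    pd.testing.assert_frame_equal(a.tracks, b.tracks)
    pd.testing.assert_frame_equal(a.dives, b.dives)
    c = simulate_raft(cfg, seed=4)
    assert not a.tracks.equals(c.tracks)


def test_empty_raft():
    ds = simulate_raft(RaftConfig(n_birds=0), seed=0)
    assert len(ds.tracks) == 0 and len(ds.dives) == 0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        RaftConfig(n_birds=-1)
    with pytest.raises(ValueError):
        RaftConfig(sim_step=0.7)
    with pytest.raises(ValueError):
        RaftConfig(duration=60.01, sim_step=0.04)


def test_trajectories_end_at_dive_times():
    ds = simulate_raft(RaftConfig(n_birds=40), seed=8)
    ends = ds.tracks.groupby("bird_id")["time_s"].max()
    for d in ds.dives.itertuples():
        assert ends[d.bird_id] == pytest.approx(d.time_s, abs=1e-12)


def test_constant_hazard_dive_count_in_binomial_envelope():
    """With p1 = p0 the dive count must match the constant-hazard
    Bernoulli expectation (99% binomial envelope on the realized trials)."""
    p = DiveModelParams(p0=0.06, p1=0.06, lag=1.67, distance=70.28, angle=216.06)
    ds = simulate_raft(RaftConfig(n_birds=100, dive_params=p), seed=12)
    labels = ds.metadata["labels"]
    n_trials = len(labels)
    p_step = per_step_probability(0.06, 0.5)
    lo, hi = stats.binom.ppf([0.005, 0.995], n_trials, p_step)
    assert lo <= ds.n_dives <= hi


def test_two_rate_process_rates_match_generating_values():
    """Labelling each trial with the generating parameters: the social
    dive frequency exceeds the non-social one and each sits inside its
    own 99% binomial envelope."""
    ds = simulate_raft(RaftConfig(n_birds=120), seed=13)
    lab = ds.metadata["labels"]
    for social, p_sec in ((True, 0.1484), (False, 0.0634)):
        sub = lab[lab.social == social]
        p_step = per_step_probability(p_sec, 0.5)
        lo, hi = stats.binom.ppf([0.005, 0.995], len(sub), p_step)
        assert lo <= sub.dived.sum() <= hi
    rate = lab.groupby("social")["dived"].mean()
    assert rate[True] > rate[False]


def test_hazard_calibration_over_1e5_nonsocial_bird_seconds():
    """Empirical non-social dive rate within 3 MC standard errors of p0."""
    # a short detection range keeps nearly all exposure non-social
    p = DiveModelParams(p0=0.01, p1=0.01, lag=1.67, distance=5.0, angle=216.06)
    cfg = RaftConfig(
        n_birds=900, dive_params=p, attraction_weight=0.0, follow_weight=0.0
    )
    labs = []
    for seed in (21, 22, 23):
        labs.append(simulate_raft(cfg, seed=seed).metadata["labels"])
    lab = pd.concat(labs)
    ns = lab[~lab.social]
    assert len(ns) * 0.5 >= 1e5  # bird-seconds of non-social exposure
    p_step = per_step_probability(p.p0, 0.5)
    se = np.sqrt(p_step * (1 - p_step) / len(ns))
    assert abs(ns.dived.mean() - p_step) <= 3 * se


def test_generator_labels_equal_inference_labels_exactly():
    """The simulator's internal social/dive labels must be reproduced
    exactly by discretize + is_social with the generating parameters."""
    for seed in (31, 32):
        raft = dr.simulate_raft(dr.RaftConfig(n_birds=60), seed=seed)
        obs = dr.discretize(raft)
        lab = obs.social_labels(raft.metadata["config"].dive_params)
        inf = pd.DataFrame(
            {
                "bird_id": obs.table.bird_id,
                "interval": obs.table.interval,
                "social_inf": lab,
                "dived_inf": obs.table.dived.astype(bool),
            }
        )
        gen = raft.metadata["labels"]
        m = gen.merge(inf, on=["bird_id", "interval"], how="outer", indicator=True)
        assert (m["_merge"] == "both").all()
        assert (m.social == m.social_inf).all()
        assert (m.dived == m.dived_inf).all()


def test_follow_weight_produces_front_back_anisotropy(social_dataset):
    hm = relative_neighbour_density(social_dataset)
    q = quadrant_means(hm)
    assert (q["front"] + q["back"]) / 2 > (q["left"] + q["right"]) / 2


def test_wave_raft_generates_sweeping_dives():
    ds = dr.simulate_wave_raft(RaftConfig(n_birds=50), seed=5, wave_speed=5.0)
    assert ds.n_dives > 25
    ends = ds.tracks.groupby("bird_id")["time_s"].max()
    for d in ds.dives.itertuples():
        assert ends[d.bird_id] <= d.time_s + 1e-9
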