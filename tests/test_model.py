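import math

import numpy as np
import pandas as pd
import pytest

import diveraft as dr
from diveraft import (
    DiveModelParams,
    ModelVariant,
    Priors,
    SocialDiveModel,
    cohens_d,
    waic_from_pointwise,
)
from diveraft._kernels import _counts_numpy, _labels_numpy, social_counts_kernel
from diveraft.observations import DiscretizedObservations
from helpers import brute_force_waic


def _obs(records, cues_per_record, step=0.5):
    """records: list of dived flags; cues_per_record: list of cue triples."""
    n = len(records)
    table = pd.DataFrame(
        {
            "raft_id": 0,
            "bird_id": np.arange(n),
            "interval": 0,
            "t_start": 0.0,
            "x_bl": 0.0,
            "y_bl": 0.0,
            "heading_deg": 0.0,
            "dived": np.asarray(records, dtype=np.uint8),
        }
    )
    flat = [c for cues in cues_per_record for c in cues]
    arr = np.asarray(flat, dtype=float).reshape(-1, 3)
    ptr = np.zeros(n + 1, dtype=np.int64)
    if cues_per_record:
        np.cumsum([len(c) for c in cues_per_record], out=ptr[1:])
    return DiscretizedObservations(
        table, arr[:, 0], arr[:, 1], arr[:, 2], ptr, step, 2.0, 100.0
    )


def _p_sec(p_step, dt=0.5):
    return 1.0 - (1.0 - p_step) ** (1.0 / dt)


def test_loglike_single_nonsocial_survival_record():
    obs = _obs([0], [[]])
    m = SocialDiveModel(obs)
    params = DiveModelParams(_p_sec(0.1), _p_sec(0.2), 1.0, 50.0, 216.0)
    assert m.loglike(params) == pytest.approx(math.log(0.9), rel=1e-12)


def test_loglike_single_social_dive_record():
    obs = _obs([1], [[(0.5, 10.0, 0.0)]])
    m = SocialDiveModel(obs)
    params = DiveModelParams(_p_sec(0.1), _p_sec(0.2), 1.0, 50.0, 216.0)
    assert m.loglike(params) == pytest.approx(math.log(0.2), rel=1e-12)


def test_null_variant_ignores_cues():
    obs = _obs([1, 0], [[(0.5, 10.0, 0.0)], [(0.5, 10.0, 0.0)]])
    m = SocialDiveModel(obs, variant="null")
    params = m._to_params(np.array([_p_sec(0.1)]))
    assert m.loglike(params) == pytest.approx(math.log(0.1) + math.log(0.9), rel=1e-12)


def test_noangle_variant_equals_full_with_360_arc(social_obs):
    p = DiveModelParams(0.06, 0.15, 1.5, 60.0, 360.0)
    full = SocialDiveModel(social_obs, variant="full")
    noang = SocialDiveModel(social_obs, variant="noangle")
    assert full.loglike(p) == noang.loglike(np.array([0.06, 0.15, 1.5, 60.0]))


def test_numba_and_numpy_kernels_agree(social_obs):
    o = social_obs
    d = o.dived
    for lag, dist, half in [(1.67, 70.28, 108.03), (0.5, 10.0, 30.0), (2.0, 100.0, 180.0)]:
        jit = social_counts_kernel(
            o.cue_dt, o.cue_dist, o.cue_bearing, o.cue_ptr, d, lag, dist, half
        )
        ref = _counts_numpy(
            o.cue_dt, o.cue_dist, o.cue_bearing, o.cue_ptr, d, lag, dist, half
        )
        assert tuple(jit) == ref
        lab_np = _labels_numpy(o.cue_dt, o.cue_dist, o.cue_bearing, o.cue_ptr, lag, dist, half)
        params = DiveModelParams(0.05, 0.1, lag, dist, 2 * half)
        assert np.array_equal(lab_np.astype(bool), o.social_labels(params))


def test_pointwise_loglik_sums_to_total(social_obs):
    m = SocialDiveModel(social_obs)
    p = dr.SHAG_RAFT_PARAMS
    assert m.loglike_pointwise(p).sum() == pytest.approx(m.loglike(p), rel=1e-10)


# ---------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------

def test_point_mass_posterior_has_zero_penalty():
    ll = np.tile(np.array([-0.3, -1.2, -0.7]), (10, 1))
    w = waic_from_pointwise(ll)
    assert w.p_waic == pytest.approx(0.0, abs=1e-12)
    assert w.waic == pytest.approx(-2 * ll[0].sum(), rel=1e-12)


def test_waic_matches_two_loop_computation():
    rng = np.random.default_rng(7)
    ll = -rng.exponential(1.0, size=(10, 5))
    w = waic_from_pointwise(ll)
    waic_b, lppd_b, p_b = brute_force_waic(ll)
    assert w.waic == pytest.approx(waic_b, rel=1e-10)
    assert w.lppd == pytest.approx(lppd_b, rel=1e-10)
    assert w.p_waic == pytest.approx(p_b, rel=1e-10)


def test_waic_agrees_with_arviz():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(11)
    ll = -rng.exponential(1.0, size=(200, 40))
    mine = waic_from_pointwise(ll)
    idata = az.from_dict(log_likelihood={"y": ll[None, :, :]})
    ref = az.waic(idata, scale="deviance")
    # arviz computes the penalty with the population variance (ddof=0);
    # this implementation uses the sample variance (ddof=1)
    S = ll.shape[0]
    assert mine.p_waic * (S - 1) / S == pytest.approx(float(ref.p_waic), rel=1e-6)
    adj = -2.0 * (mine.lppd - mine.p_waic * (S - 1) / S)
    assert adj == pytest.approx(float(ref.elpd_waic), rel=1e-6)


def test_streaming_waic_equals_matrix_waic_on_fit():
    ds = dr.simulate_raft(dr.RaftConfig(n_birds=25, duration=30.0), seed=17)
    m = SocialDiveModel.from_dataset(ds)
    res = m.fit(burn=100, draws=200, seed=2)
    streamed = res.waic()
    mat = np.stack(
        [
            m.loglike_pointwise(m._to_params(row.to_numpy()))
            for _, row in res.samples[m.param_names].iterrows()
        ]
    )
    direct = waic_from_pointwise(mat)
    assert streamed.waic == pytest.approx(direct.waic, rel=1e-8)


def test_waic_needs_at_least_two_samples():
    with pytest.raises(ValueError):
        waic_from_pointwise(np.zeros((1, 4)))


# ---------------------------------------------------------------------
# Cohen's d
# ---------------------------------------------------------------------

def _vector_with_moments(mean, sd, n=1000, seed=0):
    x = np.random.default_rng(seed).normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x

def test_cohens_d_identical_vectors_is_zero():
    x = _vector_with_moments(0.5, 0.1)
    assert cohens_d(x, x) == pytest.approx(0.0, abs=1e-12)


def test_cohens_d_one_pooled_sd_apart_is_one():
    a = _vector_with_moments(1.0, 0.3, seed=1)
    b = _vector_with_moments(0.7, 0.3, seed=2)
    assert cohens_d(a, b) == pytest.approx(1.0, rel=1e-9)


def test_cohens_d_zero_spread_raises():
    with pytest.raises(ZeroDivisionError):
        cohens_d(np.ones(5), np.ones(5))


# ---------------------------------------------------------------------
# MCMC behaviour
# ---------------------------------------------------------------------

def test_same_seed_reproduces_chain_exactly():
    ds = dr.simulate_raft(dr.RaftConfig(n_birds=20, duration=30.0), seed=19)
    m = SocialDiveModel.from_dataset(ds)
    a = m.fit(burn=100, draws=300, seed=5)
    b = m.fit(burn=100, draws=300, seed=5)
    pd.testing.assert_frame_equal(a.samples, b.samples)
    c = m.fit(burn=100, draws=300, seed=6)
    assert not a.samples.equals(c.samples)


def test_zero_dives_pushes_intrinsic_rate_to_zero():
    quiet = DiveModelParams(p0=0.0, p1=0.0, lag=1.67, distance=70.0, angle=216.0)
    ds = dr.simulate_raft(dr.RaftConfig(n_birds=10, dive_params=quiet), seed=23)
    m = SocialDiveModel.from_dataset(ds, variant="null")
    res = m.fit(burn=300, draws=1000, seed=3)
    assert res.params["p0"] < 0.01
    assert res.conf_int().loc["p0", "lower"] < 1e-4


def test_null_model_coverage_over_seeded_repeats():
    """95% interval for p0 under the NULL variant covers the generating
    value in at least 90% of 20 seeded repeats."""
    truth = 0.08
    quiet = DiveModelParams(p0=truth, p1=truth, lag=1.67, distance=0.1, angle=1.0)
    hits = 0
    for seed in range(20):
        ds = dr.simulate_raft(
            dr.RaftConfig(n_birds=40, duration=30.0, dive_params=quiet), seed=100 + seed
        )
        m = SocialDiveModel.from_dataset(ds, variant="null")
        res = m.fit(burn=200, draws=600, seed=seed)
        lo, hi = res.conf_int().loc["p0"]
        hits += lo <= truth <= hi
    assert hits >= 18


def test_results_surface(social_obs):
    m = SocialDiveModel(social_obs)
    res = m.fit(burn=150, draws=400, seed=9)
    assert set(res.params.index) == {"p0", "p1", "lag", "distance", "angle"}
    ci = res.conf_int()
    for n in res.param_names:
        lo, hi = Priors().bounds(n)
        assert lo <= ci.loc[n, "lower"] <= ci.loc[n, "upper"] <= hi
    assert res.n_draws == 400
    assert "posterior summary" in res.summary()
    assert res.samples["loglik"].idxmax() is not None
    assert res.cohens_d() > 0


def test_empty_observations_rejected():
    empty = _obs([], [])
    with pytest.raises(ValueError):
        SocialDiveModel(empty)
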