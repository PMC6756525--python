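# diveraft

Social-information use in collectively foraging diving birds: simulation,
video tracking, Bayesian interaction-rule inference and spatial statistics
for surface "foraging rafts" — cohesive flocks of pursuit-diving seabirds
(European shags and similar species) that swim along the surface and dive
together.

The central question the package addresses is whether a bird's decision
to dive is influenced by the dives it has just seen, and over what lag,
distance and visual angle.  It is intended for movement ecologists who
have (or can extract) surface trajectories and dive times from overhead
video of diving flocks, and for anyone who wants a fully synthetic,
self-consistent test bed for event-triggered interaction inference.

## The model

Trajectories are discretized into 0.5-s intervals.  Within each interval
a surfaced bird's dive indicator `X_t` is Bernoulli:

```
P(X_t = 1) = p0   if no conspecific dived within the previous T seconds,
                  closer than D body lengths, inside the visual arc θ
P(X_t = 1) = p1   if such a qualifying dive (a "social cue") exists
```

Conspecific dives keep their exact (continuous) times; only the focal
bird's exposure is discretized.  `p0` and `p1` are probabilities per
second (converted to per-interval via `1 - (1 - p)^Δt`), `T` is the lag
window, `D` the detection distance in body lengths (BL), and `θ` the
total visual arc centred on the heading (a cue qualifies when its
absolute bearing is at most `θ/2`).  All five parameters carry uniform
priors (`T`: 0.5–2 s, `D`: 0–100 BL, `θ`: 0–360°, rates: 0–1) and are
sampled by component-wise random-walk Metropolis with reflecting
proposals — the likelihood is a step function of `T`, `D`, `θ`, so
gradient samplers do not apply.  Model variants (full; `θ` fixed at 360°;
intrinsic-rate-only null) are compared by WAIC,
`-2(lppd - p_waic)`, from pointwise posterior log-likelihoods.

The package contains:

- `diveraft.synthetic` — an agent-based raft simulator whose dive process
  is the generative twin of the model above (plus a moving-front "wave"
  variant for diagnostics);
- `diveraft.camera` / `diveraft.render` — a pinhole camera model for an
  elevated oblique shore camera, and a renderer that turns datasets into
  grayscale frame stacks (splash swell-and-collapse included);
- `diveraft.tracking` — frame averaging, blob detection, perspective
  correction, Kalman + auction-assignment track linking, speed filtering
  and splash-profile dive detection;
- `diveraft.model` — `SocialDiveModel` / `SocialDiveResults`
  (statsmodels-style fit/results objects) with the Metropolis sampler,
  WAIC and Cohen's d;
- `diveraft.spatial` — focal-frame neighbour-density, relative-heading
  (circular variance) and dive-following heatmaps, the dive-time
  randomization null, the wave diagnostic and raft summary statistics;
- `diveraft.pipeline` / `diveraft.cli` — an end-to-end recovery
  experiment and the `diveraft` command-line tool
  (`simulate | render | track | infer | compare | spatial | recover`).

## Worked example

Simulate four rafts of 103 birds under the reference shag parameters
(`p0 = 0.0634/s`, `p1 = 0.1484/s`, `T = 1.67 s`, `D = 70.28 BL`,
`θ = 216.06°`) and infer the rule back from the trajectories and dives:

```python
import diveraft as dr

ds = dr.simulate_rafts(4, dr.RaftConfig(n_birds=103), seed=0)
model = dr.SocialDiveModel.from_dataset(ds)     # FULL variant, 0.5-s steps
res = model.fit(burn=1000, draws=4000, seed=0)
print(res.summary())
```

```
Social dive model - posterior summary
================================================================
variant: full        records: 7005  dives: 410
draws: 4000  burn-in: 1000  seed: 0
----------------------------------------------------------------
param           mean        sd      2.5%     97.5%       MLE
p0            0.0726    0.0070    0.0587    0.0868    0.0699
p1            0.1392    0.0074    0.1247    0.1533    0.1446
lag           1.6508    0.0868    1.4402    1.8342    1.6620
distance     68.5425    3.2149   62.5433   74.6713   70.0897
angle       232.3771   17.6724  207.6810  277.0525  217.4623
----------------------------------------------------------------
Cohen's d (p1 vs p0): 9.24
```

Every 95% interval covers its generating value: the social rate is about
twice the intrinsic rate, the lag about 1.65 s, the detection distance
about 69 BL and the visual arc about 232° (the arc posterior is the
widest — it is only informed by cues near the arc boundary).  Cohen's d
here separates the two **posterior rate distributions**; it grows with
data volume (at the full 26-raft scale it exceeds 30).  Continuing,

```python
w = res.waic()
st = dr.summary_stats(ds, params=res.mean_params())
print(f"WAIC: {w.waic:.2f}  (lppd {w.lppd:.2f}, p_waic {w.p_waic:.2f})")
print(f"speed {st['speed_mean']:.2f} +/- {st['speed_sd']:.2f} BL/s, "
      f"transmission {st['transmission_speed_bl_s']:.1f} BL/s")
```

```
WAIC: 3088.90  (lppd -1539.87, p_waic 4.58)
speed 1.09 +/- 0.32 BL/s, transmission 41.5 BL/s
```

The implied social transmission speed `D/T ≈ 41.5 BL/s` is some forty
times the surface swimming speed — information travels through the raft
far faster than the birds do, the signature of visual cue use rather
than shared reaction to the same prey.

The same analysis from the shell:

```bash
diveraft simulate --n-rafts 4 --seed 0 --out run/
diveraft infer --tracks run/tracks.csv --dives run/dives.csv \
               --burn 1000 --draws 4000 --seed 0 --out run/fit/
diveraft spatial --tracks run/tracks.csv --dives run/dives.csv --out run/maps/
```

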