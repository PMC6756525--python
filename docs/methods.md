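# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `diveraft`, in the spirit of a statistical software
methods appendix.  Everything quantitative claimed here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory.

## 1. The two-rate social dive process

A surfaced bird's diving is a discrete-time Bernoulli process on 0.5-s
intervals.  The per-interval dive probability takes one of two values:
the intrinsic per-second rate `p0` converted to the interval length, or
the social rate `p1` when a *qualifying cue* exists at the interval
start.  A qualifying cue is a conspecific dive with

- exact lag `0 < Δt ≤ T` (measured from the interval start to the
  continuous dive time — conspecific dives are never discretized),
- distance strictly less than `D` body lengths from the focal's position
  at the interval start,
- absolute bearing at most `θ/2` from the focal's heading (the arc is
  inclusive at its boundary; `θ` is the total arc and may reach 360°).

Per-second rates convert to per-interval probabilities by the
complementary-hazard form `p_step = 1 − (1 − p_sec)^Δt`, which is exact
for Bernoulli thinning and is used identically by the simulator and the
likelihood, so parameter recovery is self-consistent by construction.
Headings are the direction of displacement between consecutive track
samples (birds are assumed to face their direction of movement); the
heading at a track's first sample copies the next displacement.  A bird
never cues itself: its trajectory ends at its own dive.

Boundary conventions worth stating: the lag window is open at zero (a
dive exactly at the evaluation instant is not yet visible), the lag and
arc bounds are inclusive, and the distance bound is strict.  These
choices are arbitrary at measure zero but are applied identically in
generation and inference.

## 2. The synthetic raft generator

The generator is the study-condition twin of the inference model plus a
deliberately simple movement layer.  Dive decisions run on the analysis
lattice (0.5 s): at each interval start every surfaced bird is labelled
social or non-social by the exact predicate above, then draws its
Bernoulli trial; a diving bird gets a dive instant uniform in the
interval, its trajectory is truncated there (position linearly
interpolated), and it does not resurface — resurfacing birds in real
footage appear as fresh track ids, which the optional `respawn` mode
emulates by inserting new ids after exponential delays.  The generator
stores its internal per-trial labels, and the test suite checks that
discretization plus the social predicate reproduces them *exactly*
(bit-level agreement of labels and outcomes), which pins down every
boundary convention.

Movement is a correlated walk integrated at 25 steps/s: per-bird speeds
are drawn once from a clipped normal (mean 1.1 BL/s, sd 0.3), and each
step the heading relaxes toward a shared travel direction
(`alignment_weight`, 0.5 s⁻¹), toward the flock centroid
(`attraction_weight`, 0.15 s⁻¹) and toward the nearest bird ahead
(`follow_weight`, 0.5 s⁻¹), plus a 3°/step Gaussian kick.  The follow
term produces the front–back neighbour anisotropy seen in real rafts.
Initial positions are uniform in a square sized so the Poisson
nearest-neighbour distance matches the 9.3 BL target.  No movement
equations are claimed for the real birds: the walk exists to carry the
dive process and to reproduce the qualitative spatial structure
(polarized, loosely aligned, denser fore and aft).  Realized statistics
at the defaults: surface speed 1.09 ± 0.32 BL/s; nearest-neighbour
distance ≈ 11 BL early in a clip, inflating over the clip (≈ 18 BL
time-averaged) because dived birds leave the surface and the survivors
thin out — real rafts are replenished by resurfacing birds, so their
time-averaged NND stays near the early-clip value.

What the generator does **not** emulate: hydrodynamic interactions, prey
fields, kleptoparasites, underwater movement, detection noise in real
video (unless rendered and re-tracked), and surface-density equilibrium
(without `respawn` the raft depletes).  Passing recovery tests on this
generator therefore demonstrates correctness of the inference machinery
under the stated model, not the truth of the model for field data.

A second generator (`simulate_wave_raft`) triggers dives with a front
sweeping through the flock at a configurable speed instead of social
cues; it exists solely to give the wave diagnostic a positive control.

## 3. Inference

Component-wise random-walk Metropolis with reflecting proposals at the
prior bounds.  The likelihood is a step function of `T`, `D`, `θ`
(records flip between social and non-social as thresholds cross cue
values), so gradient-based samplers are inapplicable; reflection keeps
proposals symmetric and hence the acceptance ratio plain.  Proposal
scales start at 1/20 of each prior width and adapt every 50 iterations
during burn-in only (multiplicative update toward 30% acceptance);
the recorded chain is a valid fixed-kernel Metropolis chain.  The chain
starts at the prior midpoint, making runs reproducible from the seed
alone.  Defaults follow the standard protocol for this analysis: 5000
burn-in iterations and 20000 recorded draws.  Mild meta-stability in the
visual-arc component (plateaus of ~10°) is expected — the likelihood is
piecewise constant in `θ` — and is absorbed by the wide posterior for
that parameter.  "MLE" is reported as the highest-likelihood posterior
sample (with uniform priors, also the highest-posterior sample), and
intervals are central 2.5–97.5% quantiles.

Each record carries a precomputed candidate-cue list (all dives within
the prior upper bounds: lag ≤ 2 s, distance ≤ 100 BL), so any proposal
can be evaluated without returning to the raw tables.  The label scan is
numba-jitted with early exit and a pure-numpy fallback; the test suite
proves both equal an exhaustive all-dives scan, exactly, across random
proposals.  Likelihood evaluation reduces to four counts (social /
non-social × dived / survived), so rate-only proposals are O(1).

WAIC is computed by streaming over posterior draws (per-draw label scan,
running sums of the pointwise mass, log-likelihood and its square) —
the full pointwise matrix at scale (20000 × ~45000) would not fit in
memory.  The penalty uses the sample variance (ddof = 1); arviz, which
uses the population variance, is reconciled in a cross-check test.
Differences are reported as `waic_full − waic_other` (negative favours
the full model).  Cohen's d between the two rate posteriors is
`(mean₁ − mean₀)/√((sd₁² + sd₀²)/2)`.

## 4. Tracking

The video stage mirrors the classic overhead-flock pipeline.  Frames are
averaged over a centred window (default 6; truncated at stack edges) to
suppress water flicker.  Blobs are connected components above an
intensity threshold (Otsu on the mid-stack frame unless configured),
filtered to plausible bird areas (default 8–60 px around the nominal
~20 px body), with intensity-weighted centroids for sub-pixel accuracy.

Perspective correction is an exact pinhole inversion: the camera sits at
a known elevation with a known inclination from the vertical to the
bottom sensor edge; pixel rays are intersected with the sea-surface
plane.  Forward and inverse projections are exact inverses (round-trip
error < 1e-6 on the footprint; at nadir the map degenerates to a pure
similarity, which is tested).  The BL scale comes from a configured
body length in metres, or from the median blob major-axis length
converted to metres at each blob's ground position.

Linking runs in corrected ground coordinates: each open track carries a
constant-velocity Kalman (linear quadratic) estimator; predictions are
matched to detections by a forward auction algorithm minimizing total
prediction–observation distance.  The auction starts from uniform zero
prices (required for exactness in the asymmetric case), uses an epsilon
of 1e-9 of the cost scale, and restarts with a coarser epsilon if a
price war between near-tied bidders exceeds its iteration budget; rows
and columns with nothing inside the match gate (default 3 BL) are
removed before bidding so sentinel costs never dominate the price scale.
Optimality against exhaustive enumeration is property-tested.  Tracks
unmatched beyond 0.5 s close; tracks with mean speed outside
0.2–2.5 BL/s (implausible for a swimming bird) are discarded.

A track end inside the frame's bounding box (inset 10 px) is labelled a
dive when its final 2 s of blob area swells at least 30% over the
preceding baseline and then falls at least 60% from the peak — the
splash growing and collapsing.  The thresholds are configuration
parameters; the defaults were chosen against the renderer's splash
profile and validated by recall/precision ≥ 90% on rendered ground
truth.  A dive in the last ~2 s of a clip leaves no complete splash and
cannot be classified, so round-trip evaluations stop the truth set 2 s
before the clip end.  Manual track/dive correction, underwater tracking
and re-identifying resurfacing birds are out of scope.

## 5. Spatial statistics

All focal-frame maps rotate offsets so the focal's heading points "up"
(+y front, +x right) and bin them on a square grid (default half-width
40 BL, cell 2 BL — the bin geometry is a package choice).  Neighbour
density is normalized to a maximum of exactly 1; relative-heading cells
carry the circular mean and the circular variance `1 − R̄`; empty cells
are missing (NaN), never zero, in heading and fraction maps.  The
dive-following map bins every (conspecific dive, surfaced focal) pair by
the dive's offset in the focal's frame at the dive time and reports the
share followed by a focal dive within 2 s.  The randomization null
permutes dive times across each raft's dive events (positions and
orientations intact, per-raft dive counts preserved) and averages the
fraction map over permutations (default 1000).

Two notes on power, established while designing the acceptance suite
and documented so nobody mistakes them for tuning: (i) at ~100 birds per
raft the synthetic process is socially saturated — some qualifying cue
almost always exists — so the *directional* effect of a single dive on
the following fraction washes out; the following-bias analyses therefore
use 26 rafts of 30 birds, where cue density is comparable to the
effective density in field data.  (ii) the front-vs-back contrast is
pooled over diagonal quadrants, not half-planes, because a 216° arc
reaches 18° behind abeam: the rear half-plane is partly inside the arc,
the rear quadrant is entirely outside it.

The wave diagnostic emits, for every ordered within-raft dive pair with
|Δt| ≤ 10 s, the pair (Δt, signed along-heading offset).  Because both
orderings of each pair are emitted, the quadrant table is symmetric by
construction; the discriminating summary is the Pearson correlation
between Δt and offset restricted to |Δt| ≥ 2 s (outside the social-copy
lag).  A dive front sweeping through the flock leaves a coherent
negative correlation at long lags (dives before-and-in-front /
after-and-behind); social copying leaves none.

## 6. Degenerate inputs and edge handling

Zero-bird configurations yield empty datasets, not errors.  Empty
observation sets are rejected at model construction.  A chain that
accepts nothing during burn-in raises with guidance rather than
returning a frozen posterior.  Records require at least one track sample
at or before the interval start and a track end at or after it; under
`respawn` a new bird's trials are deferred one interval so its heading
is defined, which is the one case where generator labels and re-derived
labels can differ (they are exactly equal for the default,
no-respawn setting).  Pixel rays at or above the horizon raise;
out-of-footprint birds are clipped from renders with a logged count.

## 7. Problem sizes

The recovery experiment (also the acceptance run) uses the study scale:
26 rafts, sizes drawn once per seed from a clipped normal (mean 103,
sd 35, range 25–210), 60-s clips, ~45000 Bernoulli records, 5000 + 20000
Metropolis iterations.  Model-comparison fits for the WAIC table use
shorter chains (1500 + 6000) — WAIC is a data-scale quantity and is
insensitive to chain length at these sizes, which a point-mass and a
brute-force test pin down.  Tracking round-trips render 30 birds for
16 s at 640×480; the camera there is chosen steep and wide so the whole
raft stays in the footprint at ~3.4 px per body length.
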