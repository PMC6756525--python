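"""Bayesian inference for the two-rate social dive process.

The observation model: within each 0.5-s interval a surfaced bird's dive
indicator is Bernoulli with per-step probability converted from the
intrinsic rate p0 - or from the social rate p1 when a conspecific dived
within the previous T seconds, closer than D body lengths, inside the
focal's visual arc theta.  All parameters carry independent uniform
priors, so the posterior is explored with a component-wise random-walk
Metropolis sampler with reflecting proposals at the prior bounds; a
gradient sampler would be inappropriate because the likelihood is a step
function of T, D and theta (records flip between social and non-social
as the thresholds cross cue values).  Proposal scales adapt during
burn-in only, leaving the recorded chain a valid Metropolis chain.

Model variants:

* ``FULL``     - p0, p1, T, D, theta
* ``NO_ANGLE`` - theta fixed at 360 degrees (cues visible all around)
* ``NULL``     - intrinsic rate only (no social effect)

Variants are compared by WAIC computed from pointwise posterior
log-likelihoods; lower is better and differences are reported as
``waic_full - waic_other``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import social_counts_kernel, waic_accumulate_kernel
from .dataset import RaftDataset
from .observations import DiscretizedObservations, discretize, social_labels
from .params import DiveModelParams, Priors, per_step_probability

__all__ = [
    "ModelVariant",
    "SocialDiveModel",
    "SocialDiveResults",
    "WAICResult",
    "waic_from_pointwise",
    "cohens_d",
]

_PARAM_ORDER = ["p0", "p1", "lag", "distance", "angle"]


class ModelVariant(enum.Enum):
    FULL = "full"
    NO_ANGLE = "noangle"
    NULL = "null"

    @property
    def free_params(self) -> list[str]:
        return {
            ModelVariant.FULL: ["p0", "p1", "lag", "distance", "angle"],
            ModelVariant.NO_ANGLE: ["p0", "p1", "lag", "distance"],
            ModelVariant.NULL: ["p0"],
        }[self]


@dataclass(frozen=True)
class WAICResult:
    waic: float
    lppd: float
    p_waic: float
    n_records: int


def waic_from_pointwise(loglik: np.ndarray) -> WAICResult:
    """WAIC from an (n_samples, n_records) pointwise log-likelihood matrix:
    lppd = sum_i log mean_s exp(ll_is), p_waic = sum_i var_s(ll_is),
    waic = -2 (lppd - p_waic)."""
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 posterior samples")
    lppd = float(np.sum(np.log(np.mean(np.exp(ll), axis=0))))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WAICResult(-2.0 * (lppd - p_waic), lppd, p_waic, ll.shape[1])


def cohens_d(samples_a, samples_b) -> float:
    """(mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample vectors must be non-empty")
    pooled = math.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0)
    if pooled == 0.0:
        raise ZeroDivisionError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


class SocialDiveModel:
    """Two-rate social dive model over discretized raft observations.

    Build from a :class:`DiscretizedObservations` (or via
    :meth:`from_dataset`), then call :meth:`fit` to sample the posterior.
    """

    def __init__(
        self,
        observations: DiscretizedObservations,
        variant: ModelVariant | str = ModelVariant.FULL,
        priors: Priors | None = None,
    ):
        if observations.n_records == 0:
            raise ValueError("observations are empty")
        self.obs = observations
        self.variant = ModelVariant(variant)
        self.priors = priors or Priors()
        self._dived = observations.dived
        self._n = observations.n_records
        self._n_dived = int(self._dived.sum())
        self._step = observations.step

    @classmethod
    def from_dataset(
        cls,
        dataset: RaftDataset,
        variant: ModelVariant | str = ModelVariant.FULL,
        step: float = 0.5,
        priors: Priors | None = None,
        exclude_bird_ids: set | None = None,
    ) -> "SocialDiveModel":
        priors = priors or Priors()
        obs = discretize(
            dataset, step=step, priors=priors, exclude_bird_ids=exclude_bird_ids
        )
        return cls(obs, variant=variant, priors=priors)

    # -- parameter plumbing -------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return self.variant.free_params

    def _to_params(self, theta: np.ndarray) -> DiveModelParams:
        d = dict(zip(self.param_names, np.asarray(theta, dtype=float)))
        if self.variant is ModelVariant.NO_ANGLE:
            d["angle"] = 360.0
        elif self.variant is ModelVariant.NULL:
            d.setdefault("p1", d["p0"])
            d.setdefault("lag", 1.0)
            d.setdefault("distance", 1.0)
            d.setdefault("angle", 360.0)
        return DiveModelParams(**d)

    # -- likelihood ----------------------------------------------------
    def _counts(self, params: DiveModelParams) -> tuple[int, int]:
        if self.variant is ModelVariant.NULL:
            return 0, 0
        o = self.obs
        return social_counts_kernel(
            o.cue_dt,
            o.cue_dist,
            o.cue_bearing,
            o.cue_ptr,
            self._dived,
            params.lag,
            params.distance,
            params.half_angle,
        )

    def _loglike_from_counts(self, p0: float, p1: float, n_s: int, n_s_d: int) -> float:
        ps0 = per_step_probability(p0, self._step)
        ps1 = per_step_probability(p1, self._step)
        n_ns = self._n - n_s
        n_ns_d = self._n_dived - n_s_d
        ll = 0.0
        for k, q, p in ((n_s_d, n_s - n_s_d, ps1), (n_ns_d, n_ns - n_ns_d, ps0)):
            if k > 0:
                if p <= 0.0:
                    return -np.inf
                ll += k * math.log(p)
            if q > 0:
                if p >= 1.0:
                    return -np.inf
                ll += q * math.log1p(-p)
        return ll

    def loglike(self, params: DiveModelParams | np.ndarray) -> float:
        """Total Bernoulli log-likelihood at ``params``."""
        if not isinstance(params, DiveModelParams):
            params = self._to_params(params)
        n_s, n_s_d = self._counts(params)
        return self._loglike_from_counts(params.p0, params.p1, n_s, n_s_d)

    def loglike_pointwise(self, params: DiveModelParams) -> np.ndarray:
        """Per-record log-likelihood (used by WAIC and the oracle tests)."""
        if self.variant is ModelVariant.NULL:
            social = np.zeros(self._n, dtype=bool)
            p1 = params.p0
        else:
            social = social_labels(self.obs, params)
            p1 = params.p1
        ps0 = per_step_probability(params.p0, self._step)
        ps1 = per_step_probability(p1, self._step)
        p = np.where(social, ps1, ps0)
        d = self._dived.astype(bool)
        with np.errstate(divide="ignore"):
            return np.where(d, np.log(p), np.log1p(-p))

    # -- sampling ------------------------------------------------------
    def fit(
        self,
        burn: int = 5000,
        draws: int = 20000,
        seed: int | None = None,
        step_scales: dict | None = None,
        adapt: bool = True,
        target_accept: float = 0.3,
    ) -> "SocialDiveResults":
        """Component-wise random-walk Metropolis with reflecting proposals.

        Proposal standard deviations start at 1/20 of each prior width
        (overridable via ``step_scales``) and adapt toward
        ``target_accept`` during burn-in only.  The same seed reproduces
        the chain exactly.
        """
        rng = np.random.default_rng(seed)
        names = self.param_names
        bounds = [self.priors.bounds(n) for n in names]
        x = np.array([(lo + hi) / 2.0 for lo, hi in bounds])
        sigma = np.array(
            [
                (step_scales or {}).get(n, (hi - lo) / 20.0)
                for n, (lo, hi) in zip(names, bounds)
            ]
        )
        geom = [n in ("lag", "distance", "angle") for n in names]

        params = self._to_params(x)
        counts = self._counts(params)
        ll = self._loglike_from_counts(params.p0, params.p1, *counts)
        n_params = len(names)
        acc = np.zeros(n_params, dtype=int)  # window counters (adaptation)
        prop = np.zeros(n_params, dtype=int)
        acc_burn_total = 0
        out = np.empty((draws, n_params))
        out_ll = np.empty(draws)

        for it in range(burn + draws):
            for j in range(n_params):
                lo, hi = bounds[j]
                xp = x[j] + sigma[j] * rng.standard_normal()
                # reflect back into the prior support
                span = hi - lo
                while xp < lo or xp > hi:
                    if xp < lo:
                        xp = 2 * lo - xp
                    else:
                        xp = 2 * hi - xp
                    if not np.isfinite(xp) or abs(xp) > abs(lo) + abs(hi) + 10 * span:
                        xp = lo + rng.random() * span
                        break
                x_new = x.copy()
                x_new[j] = xp
                params_new = self._to_params(x_new)
                counts_new = self._counts(params_new) if geom[j] else counts
                ll_new = self._loglike_from_counts(
                    params_new.p0, params_new.p1, *counts_new
                )
                prop[j] += 1
                if math.log(rng.random()) < ll_new - ll:
                    x = x_new
                    counts = counts_new
                    ll = ll_new
                    acc[j] += 1
                    if it < burn:
                        acc_burn_total += 1
            if adapt and it < burn and (it + 1) % 50 == 0:
                rate = acc / np.maximum(prop, 1)
                sigma = sigma * np.exp(1.2 * (rate - target_accept))
                widths = np.array([hi - lo for lo, hi in bounds])
                sigma = np.clip(sigma, 1e-6 * widths, widths)
                acc[:] = 0
                prop[:] = 0
            if it == burn - 1:
                if burn > 0 and acc_burn_total == 0:
                    raise RuntimeError(
                        "Metropolis chain accepted no proposals during burn-in; "
                        "check the data scale or supply smaller step_scales"
                    )
                acc[:] = 0
                prop[:] = 0
            if it >= burn:
                out[it - burn] = x
                out_ll[it - burn] = ll
        post_rate = acc / np.maximum(prop, 1)

        samples = pd.DataFrame(out, columns=names)
        for name in _PARAM_ORDER:
            if name not in samples.columns:
                if name == "angle" and self.variant is ModelVariant.NO_ANGLE:
                    samples[name] = 360.0
                elif self.variant is ModelVariant.NULL and name != "p0":
                    samples[name] = np.nan
        samples["loglik"] = out_ll
        return SocialDiveResults(
            model=self,
            samples=samples,
            burn=burn,
            seed=seed,
            accept_rates=dict(zip(names, post_rate)),
        )


class SocialDiveResults:
    """Posterior summary for a fitted :class:`SocialDiveModel`.

    Carries the post-burn-in sample table (one row per draw, columns the
    five parameters plus the total log-likelihood), and exposes
    statsmodels-style accessors: ``params`` (posterior means), ``bse``
    (posterior sds), ``conf_int`` (central 95% interval), ``mle``
    (highest-likelihood sample), ``waic()`` and ``summary()``.
    """

    def __init__(self, model, samples, burn, seed, accept_rates):
        self.model = model
        self.samples = samples
        self.burn = burn
        self.seed = seed
        self.accept_rates = accept_rates

    @property
    def variant(self) -> ModelVariant:
        return self.model.variant

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    @property
    def params(self) -> pd.Series:
        return self.samples[self.param_names].mean()

    @property
    def bse(self) -> pd.Series:
        return self.samples[self.param_names].std(ddof=1)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = self.samples[self.param_names].quantile([alpha / 2, 1 - alpha / 2]).T
        q.columns = ["lower", "upper"]
        return q

    @property
    def mle(self) -> pd.Series:
        """The highest-likelihood posterior sample (with uniform priors,
        also the highest-posterior sample)."""
        i = int(self.samples["loglik"].idxmax())
        return self.samples.loc[i, self.param_names]

    def mean_params(self) -> DiveModelParams:
        return self.model._to_params(self.params.to_numpy())

    def covers(self, truth: DiveModelParams, alpha: float = 0.05) -> dict[str, bool]:
        ci = self.conf_int(alpha)
        return {
            n: bool(ci.loc[n, "lower"] <= getattr(truth, n) <= ci.loc[n, "upper"])
            for n in self.param_names
        }

    def cohens_d(self) -> float:
        """Effect size separating the social and intrinsic rate posteriors."""
        if "p1" not in self.param_names:
            raise ValueError("NULL variant has a single rate")
        return cohens_d(self.samples["p1"], self.samples["p0"])

    def waic(self, thin: int = 1) -> WAICResult:
        """Streaming WAIC over the posterior draws (optionally thinned)."""
        s = self.samples.iloc[::thin]
        if len(s) < 2:
            raise ValueError("need at least 2 posterior samples for WAIC")
        m = self.model
        o = m.obs
        step = m._step
        if m.variant is ModelVariant.NULL:
            lag_v = np.full(len(s), -1.0)  # no cue can qualify
            dist_v = np.zeros(len(s))
            half_v = np.zeros(len(s))
            ps1_v = per_step_probability(s["p0"].to_numpy(), step)
        else:
            lag_v = s["lag"].to_numpy(float)
            dist_v = s["distance"].to_numpy(float)
            half_v = s["angle"].to_numpy(float) / 2.0
            ps1_v = per_step_probability(s["p1"].to_numpy(), step)
        ps0_v = per_step_probability(s["p0"].to_numpy(), step)
        n = m._n
        sum_mass = np.zeros(n)
        sum_ll = np.zeros(n)
        sum_ll2 = np.zeros(n)
        waic_accumulate_kernel(
            o.cue_dt,
            o.cue_dist,
            o.cue_bearing,
            o.cue_ptr,
            m._dived,
            lag_v,
            dist_v,
            half_v,
            ps0_v,
            ps1_v,
            sum_mass,
            sum_ll,
            sum_ll2,
        )
        S = len(s)
        lppd = float(np.sum(np.log(sum_mass / S)))
        var = (sum_ll2 - sum_ll**2 / S) / (S - 1)
        p_waic = float(np.sum(np.maximum(var, 0.0)))
        return WAICResult(-2.0 * (lppd - p_waic), lppd, p_waic, n)

    def summary(self) -> str:
        lines = [
            "Social dive model - posterior summary",
            "=" * 64,
            f"variant: {self.variant.value:<10s}  records: {self.model._n}"
            f"  dives: {self.model._n_dived}",
            f"draws: {self.n_draws}  burn-in: {self.burn}  seed: {self.seed}",
            "-" * 64,
            f"{'param':<10s}{'mean':>10s}{'sd':>10s}{'2.5%':>10s}{'97.5%':>10s}"
            f"{'MLE':>10s}",
        ]
        ci = self.conf_int()
        mle = self.mle
        for n in self.param_names:
            lines.append(
                f"{n:<10s}{self.params[n]:>10.4f}{self.bse[n]:>10.4f}"
                f"{ci.loc[n, 'lower']:>10.4f}{ci.loc[n, 'upper']:>10.4f}"
                f"{mle[n]:>10.4f}"
            )
        lines.append("-" * 64)
        if "p1" in self.param_names:
            lines.append(f"Cohen's d (p1 vs p0): {self.cohens_d():.2f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        df = self.samples.copy()
        df.insert(0, "iteration", np.arange(self.burn, self.burn + len(df)))
        df.to_csv(path, index=False)
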