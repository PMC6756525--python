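"""Interaction-rule parameters and priors for the two-rate social dive process.

A surfaced bird's dive hazard takes one of two values: an intrinsic
per-second probability ``p0`` when no social cue is present, and a social
per-second probability ``p1`` when a conspecific dived within the last
``lag`` seconds, closer than ``distance`` body lengths, inside the bird's
visual arc of ``angle`` degrees (centred on its heading, half-angle each
side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "DiveModelParams",
    "Priors",
    "SHAG_RAFT_PARAMS",
    "per_step_probability",
    "per_second_probability",
]


@dataclass(frozen=True)
class DiveModelParams:
    """The five quantities that define the social dive process.

    Parameters
    ----------
    p0 : float
        Intrinsic dive probability per second, in [0, 1].
    p1 : float
        Social dive probability per second, in [0, 1].  ``p1 < p0`` is
        permitted (inference must be able to explore it).
    lag : float
        Look-back window T in seconds within which a conspecific dive
        counts as a cue; must be positive.
    distance : float
        Detection distance D in body lengths; a cue must be strictly
        closer than this.
    angle : float
        Total visual arc theta in degrees, in [0, 360]; a cue's absolute
        bearing from the heading must not exceed ``angle / 2``.
    """

    p0: float
    p1: float
    lag: float
    distance: float
    angle: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError(f"p1 must be in [0, 1], got {self.p1}")
        if not self.lag > 0.0:
            raise ValueError(f"lag must be positive, got {self.lag}")
        if not self.distance > 0.0:
            raise ValueError(f"distance must be positive, got {self.distance}")
        if not 0.0 <= self.angle <= 360.0:
            raise ValueError(f"angle must be in [0, 360], got {self.angle}")

    @property
    def half_angle(self) -> float:
        return self.angle / 2.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Reference posterior-mean estimates of the interaction rule for European
#: shag (*Phalacrocorax aristotelis*) foraging rafts; used as the default
#: generating truth for synthetic rafts.
SHAG_RAFT_PARAMS = DiveModelParams(
    p0=0.0634, p1=0.1484, lag=1.67, distance=70.28, angle=216.06
)


def per_step_probability(p_sec: float, dt: float):
    """Convert a per-second dive probability to a per-step probability.

    Uses the complementary-hazard form ``1 - (1 - p)**dt``, which is exact
    for Bernoulli thinning and makes the simulator and the likelihood share
    one convention.
    """
    return 1.0 - (1.0 - p_sec) ** dt


def per_second_probability(p_step: float, dt: float):
    """Inverse of :func:`per_step_probability`."""
    return 1.0 - (1.0 - p_step) ** (1.0 / dt)


@dataclass(frozen=True)
class Priors:
    """Independent uniform priors, stored as (lower, upper) bounds.

    Defaults: T in [0.5, 2] s, D in [0, 100] BL, theta in [0, 360] degrees
    and both dive probabilities in [0, 1].
    """

    p0: tuple[float, float] = (0.0, 1.0)
    p1: tuple[float, float] = (0.0, 1.0)
    lag: tuple[float, float] = (0.5, 2.0)
    distance: tuple[float, float] = (0.0, 100.0)
    angle: tuple[float, float] = (0.0, 360.0)

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = getattr(self, f.name)
            if not lo < hi:
                raise ValueError(f"prior {f.name}: need lower < upper, got {(lo, hi)}")

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def contains(self, params: DiveModelParams) -> bool:
        return all(
            lo <= getattr(params, f.name) <= hi
            for f in fields(self)
            for lo, hi in [getattr(self, f.name)]
        )
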