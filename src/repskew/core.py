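"""Closed-form concession game with quality-dependent group productivity.

Two players, a dominant and one potential subordinate, decide whether to
breed together for one season. The subordinate's quality x in [0, b] is both
its outside option (direct fitness if it breeds alone) and, through the
quality-productivity coefficient a, a determinant of how much it helps:
the helping effect is h = a*x + m and group productivity is
G = b*(1 + m + a*x). The dominant controls the share y of G conceded to the
subordinate and, for relatedness r < 1, maximizes its inclusive fitness
G*[1 - y*(1 - r)] by offering the smallest share that retains the
subordinate — the critical concession

    y_c = (x - b*r*(m + a*x)) / (b*(1 - r)*(m + a*x + 1)).

Shares below 0 clamp to 0 (low-quality subordinates stay for the indirect
benefit alone); y_c > 1 means no feasible share retains the subordinate.
The dominant accepts the subordinate only if its inclusive fitness with the
group at the offered share is at least its solitary value d_A = b + r*x.
Ties (exact indifference) resolve toward the group for both parties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

__all__ = [
    "InvalidScenarioError",
    "DegenerateRelatednessError",
    "ModelParams",
    "PartyFitness",
    "SoloFitness",
    "Offer",
    "helping_effect",
    "group_productivity",
    "solo_fitness",
    "expected_dominant_fitness_alone",
    "cooperative_fitness",
    "critical_concession",
    "subordinate_stays",
    "perfect_info_offer",
    "STAY_ATOL",
]

ArrayLike = Union[float, np.ndarray]

#: Absolute tolerance used when comparing a subordinate's cooperative
#: inclusive fitness to its outside option. Exact indifference counts as
#: staying; the tolerance only absorbs float rounding when the share is the
#: algebraic critical concession.
STAY_ATOL = 1e-12


class InvalidScenarioError(ValueError):
    """A parameter combination outside the model's domain."""


class DegenerateRelatednessError(InvalidScenarioError):
    """r = 1 requested in concession solving: no conflict, any share optimal."""


@dataclass(frozen=True)
class ModelParams:
    """Biological parameters of the concession game.

    Attributes
    ----------
    b : float
        Solitary productivity of the dominant (offspring-equivalents, > 0).
        Also the upper end of the quality range; by default b = 1 and
        quality is uniform on [0, 1].
    r : float
        Symmetric coefficient of relatedness between dominant and
        subordinate, in [0, 1].
    a : float
        Quality-productivity coefficient (QPC): slope of the helping effect
        in subordinate quality. Negative values mean high-quality
        subordinates are poorer helpers.
    m : float
        Minimal helping effect (benefit of cooperation at x = 0).
    """

    b: float = 1.0
    r: float = 0.25
    a: float = 0.5
    m: float = 0.35

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise InvalidScenarioError(f"b must be positive, got {self.b}")
        if not 0.0 <= self.r <= 1.0:
            raise InvalidScenarioError(f"r must lie in [0, 1], got {self.r}")
        # productivity 1 + m + a*x is linear in x, so positivity on [0, b]
        # reduces to the endpoints
        for x_end in (0.0, self.b):
            if 1.0 + self.m + self.a * x_end <= 0.0:
                raise InvalidScenarioError(
                    "non-positive group productivity at quality "
                    f"x={x_end}: 1 + m + a*x = {1.0 + self.m + self.a * x_end}"
                )


@dataclass(frozen=True)
class PartyFitness:
    """Direct and indirect fitness components of one party.

    ``inclusive`` is direct + indirect by construction, where the indirect
    component is relatedness times the partner's direct fitness.
    """

    direct: float
    indirect: float

    @property
    def inclusive(self) -> float:
        return self.direct + self.indirect


@dataclass(frozen=True)
class SoloFitness:
    """Inclusive fitness of both parties if they breed apart."""

    dominant_inclusive: float
    subordinate_inclusive: float


@dataclass(frozen=True)
class Offer:
    """A dominant's offered share together with its accept/evict decision.

    ``expected_dominant_inclusive`` is the dominant's (expected) inclusive
    fitness under the decision taken: the cooperative value when it accepts,
    the solitary value when it evicts or cannot retain the subordinate.
    ``perceived`` records the observation z the offer conditions on; None
    marks the no-information case, where there is nothing to condition on.
    """

    share: float
    dominant_accepts: bool
    expected_dominant_inclusive: float
    perceived: float | None = None


def helping_effect(x: ArrayLike, params: ModelParams) -> ArrayLike:
    """Helping effect h = a*x + m of a subordinate of quality x."""
    return params.a * np.asarray(x, dtype=float) + params.m


def group_productivity(x: ArrayLike, params: ModelParams) -> ArrayLike:
    """Group productivity G = b*(1 + m + a*x); raises if non-positive."""
    x = np.asarray(x, dtype=float)
    g = params.b * (1.0 + helping_effect(x, params))
    bad = np.asarray(g <= 0.0)
    if bad.any():
        offending = np.atleast_1d(x)[np.atleast_1d(bad)][0]
        raise InvalidScenarioError(
            f"non-positive group productivity at quality x={offending}"
        )
    return g if g.ndim else float(g)


def solo_fitness(x: float, params: ModelParams) -> SoloFitness:
    """Inclusive fitness of each party breeding apart: (b + r*x, r*b + x)."""
    if not 0.0 <= x <= params.b:
        raise InvalidScenarioError(
            f"quality x={x} outside the admissible range [0, b={params.b}]"
        )
    return SoloFitness(
        dominant_inclusive=params.b + params.r * x,
        subordinate_inclusive=params.r * params.b + x,
    )


def expected_dominant_fitness_alone(params: ModelParams) -> float:
    """Dominant's expected solitary inclusive fitness, D_A = b + r/2.

    The expectation is over subordinate quality, uniform on [0, 1] — the
    model's standing prior.
    """
    return params.b + params.r / 2.0


def cooperative_fitness(
    x: float, y: float, params: ModelParams
) -> Tuple[PartyFitness, PartyFitness]:
    """Fitness of (dominant, subordinate) if they breed together at share y.

    The dominant keeps (1 - y)*G and the subordinate gets y*G; each party's
    indirect component is r times the other's direct share, so inclusive
    fitness is G*[1 - y*(1 - r)] for the dominant and G*[y*(1 - r) + r] for
    the subordinate.
    """
    if not 0.0 <= y <= 1.0:
        raise InvalidScenarioError(f"share y={y} outside [0, 1]")
    g = group_productivity(x, params)
    dominant = PartyFitness(direct=(1.0 - y) * g, indirect=params.r * y * g)
    subordinate = PartyFitness(direct=y * g, indirect=params.r * (1.0 - y) * g)
    return dominant, subordinate


def critical_concession(x: ArrayLike, params: ModelParams) -> ArrayLike:
    """Raw critical share y_c at which the subordinate is exactly indifferent.

    y_c = (x - b*r*(m + a*x)) / (b*(1 - r)*(m + a*x + 1)). The value is not
    clamped: y_c < 0 signals a subordinate that stays even at zero share,
    y_c > 1 one that cannot be retained by any feasible share.
    """
    if params.r >= 1.0:
        raise DegenerateRelatednessError(
            "critical concession undefined at r = 1 (no conflict of interest)"
        )
    x = np.asarray(x, dtype=float)
    h = params.m + params.a * x
    y_c = (x - params.b * params.r * h) / (params.b * (1.0 - params.r) * (h + 1.0))
    return y_c if y_c.ndim else float(y_c)


def subordinate_stays(x: ArrayLike, y: ArrayLike, params: ModelParams) -> ArrayLike:
    """True iff the subordinate's cooperative inclusive fitness >= its outside option.

    Ties count as staying. Valid for any r in [0, 1], including r = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = group_productivity(x, params)
    coop = g * (y * (1.0 - params.r) + params.r)
    alone = params.r * params.b + x
    stays = coop >= alone - STAY_ATOL
    return stays if stays.ndim else bool(stays)


def perfect_info_offer(x: float, params: ModelParams) -> Offer:
    """Optimal offer of a dominant that observes quality x exactly.

    The share is the critical concession clamped to [0, 1]. The dominant
    accepts iff its cooperative inclusive fitness at that share weakly beats
    breeding alone; if the raw critical share exceeds 1 no feasible share
    retains the subordinate, so the decision is evict (no group).
    """
    y_raw = critical_concession(x, params)
    y_star = min(max(y_raw, 0.0), 1.0)
    d_alone = params.b + params.r * x
    if y_raw > 1.0:
        return Offer(share=y_star, dominant_accepts=False,
                     expected_dominant_inclusive=d_alone, perceived=x)
    g = group_productivity(x, params)
    coop = g * (1.0 - y_star * (1.0 - params.r))
    accepts = bool(coop >= d_alone)
    return Offer(
        share=y_star,
        dominant_accepts=accepts,
        expected_dominant_inclusive=coop if accepts else d_alone,
        perceived=x,
    )
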