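"""Population-level consequences of the dominant's information level.

Averages decision-table outcomes over the joint distribution of true and
perceived quality, P(z | x) * P(x) with a uniform quality prior: mean
offered concession, mean dominant inclusive fitness (the v_N ... v_P range
between the uninformed and perfectly informed analytic cases) and mean
subordinate inclusive fitness (s_N ... s_P). On top of the sweep sit the
two "optimal information" questions: the omega maximizing the dominant's
mean fitness net of a linear information cost, and — with no cost, since
the subordinate does not pay for the dominant's information — the omega a
subordinate of given quality would prefer the dominant to have.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .belief import InformationLevel, OmegaLike, as_information, perception_density
from .core import STAY_ATOL, ModelParams
from .grids import Grids
from .offers import ScenarioArrays, offer_curve

__all__ = [
    "DEFAULT_OMEGA_SEARCH",
    "InfoCost",
    "PopulationSummary",
    "SweepResult",
    "population_summary",
    "information_sweep",
    "optimal_information_dominant",
    "optimal_information_subordinate",
]

#: Default search set for information optima: 0, the powers of two up to
#: 1024, and infinity.
DEFAULT_OMEGA_SEARCH: tuple[float, ...] = (
    (0.0,) + tuple(float(2 ** k) for k in range(11)) + (math.inf,)
)


@dataclass(frozen=True)
class InfoCost:
    """Cost of acquiring information, an illustrative 0.003 per unit.

    Two readings of "unit" are supported. The default, ``scale="log2"``,
    charges per doubling of information — total cost
    cost_per_unit * log2(1 + omega) — i.e. per step along the explored
    information ladder (0, 1, 2, 4, ..., 1024), which is the scale on
    which dominant fitness actually accrues (asymptotically, with
    diminishing returns per doubling). ``scale="linear"`` charges
    cost_per_unit * omega literally; on that scale the cost of even
    omega = 16 exceeds the dominant's entire fitness gain from perfect
    information in most scenarios, so the optimum degenerates to 0.
    Infinite information has infinite cost unless the rate is zero.
    """

    cost_per_unit: float = 0.003
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.cost_per_unit < 0:
            raise ValueError("information cost must be non-negative")
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown cost scale {self.scale!r}")

    def total(self, omega: OmegaLike) -> float:
        info = as_information(omega)
        if self.cost_per_unit == 0.0:
            return 0.0
        if info.is_perfect:
            return math.inf
        if self.scale == "linear":
            return self.cost_per_unit * info.omega
        return self.cost_per_unit * math.log2(1.0 + info.omega)


@dataclass(frozen=True)
class PopulationSummary:
    """Joint-weighted population means at one information level."""

    omega: InformationLevel
    mean_share: float
    dominant_mean_inclusive: float
    subordinate_mean_inclusive: float
    alone_baseline: float
    group_formation_rate: float


@dataclass(frozen=True, eq=False)
class SweepResult:
    """Per-omega population summaries across an information sweep."""

    omegas: tuple[InformationLevel, ...]
    mean_share: np.ndarray
    dominant_mean_inclusive: np.ndarray
    subordinate_mean_inclusive: np.ndarray
    alone_baseline: float
    group_formation_rate: np.ndarray
    per_x_curves: dict | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "omega": [w.omega for w in self.omegas],
                "mean_share": self.mean_share,
                "dominant_mean": self.dominant_mean_inclusive,
                "subordinate_mean": self.subordinate_mean_inclusive,
                "alone_baseline": self.alone_baseline,
                "group_formation_rate": self.group_formation_rate,
            }
        )


def population_summary(omega: OmegaLike, params: ModelParams,
                       grids: Grids | None = None,
                       include_leavers: bool = True) -> PopulationSummary:
    """Population means of share and realized fitness at one omega.

    Every (x, z) cell is weighted by P(z | x) * P(x). The subordinate mean
    covers ALL subordinates by default — stayers at their cooperative
    payoff, leavers (and evictees) at their outside option s_A; with
    ``include_leavers=False`` it instead averages over formed groups only
    (NaN when no group forms), a sensitivity switch on what "average
    subordinate fitness" means.
    """
    grids = grids or Grids.default()
    curve = offer_curve(omega, params, grids)
    arr = ScenarioArrays.build(params, grids.x)
    share = curve.share[None, :]
    stays = share >= arr.y_c[:, None] - STAY_ATOL
    forms = stays & curve.accepts[None, :]
    coop_dom = arr.G[:, None] * (1.0 - share * (1.0 - params.r))
    coop_sub = arr.G[:, None] * (share * (1.0 - params.r) + params.r)
    dom_fit = np.where(forms, coop_dom, arr.d_alone[:, None])
    sub_fit = np.where(forms, coop_sub, arr.s_alone[:, None])
    weight = curve.kernel / grids.nx

    if include_leavers:
        sub_mean = float((weight * sub_fit).sum())
    else:
        formed_weight = float((weight * forms).sum())
        sub_mean = (
            float((weight * forms * coop_sub).sum()) / formed_weight
            if formed_weight > 0 else math.nan
        )
    return PopulationSummary(
        omega=curve.omega,
        mean_share=float((weight * share).sum()),
        dominant_mean_inclusive=float((weight * dom_fit).sum()),
        subordinate_mean_inclusive=sub_mean,
        alone_baseline=float(arr.d_alone.mean()),
        group_formation_rate=float((weight * forms).sum()),
    )


def information_sweep(omega_list, params: ModelParams,
                      grids: Grids | None = None,
                      include_leavers: bool = True) -> SweepResult:
    """One population summary per omega, in the given (sorted) order."""
    omegas = [as_information(w) for w in omega_list]
    if not omegas:
        raise ValueError("omega_list must be non-empty")
    summaries = [
        population_summary(w, params, grids, include_leavers) for w in omegas
    ]
    return SweepResult(
        omegas=tuple(omegas),
        mean_share=np.array([s.mean_share for s in summaries]),
        dominant_mean_inclusive=np.array(
            [s.dominant_mean_inclusive for s in summaries]
        ),
        subordinate_mean_inclusive=np.array(
            [s.subordinate_mean_inclusive for s in summaries]
        ),
        alone_baseline=summaries[0].alone_baseline,
        group_formation_rate=np.array(
            [s.group_formation_rate for s in summaries]
        ),
    )


def optimal_information_dominant(params: ModelParams,
                                 grids: Grids | None = None,
                                 cost: InfoCost | None = None,
                                 search=DEFAULT_OMEGA_SEARCH) -> InformationLevel:
    """The omega maximizing dominant mean fitness net of the linear cost.

    Infinite omega is excluded whenever the cost rate is positive (its net
    value is minus infinity); ties break toward the smaller omega.
    """
    cost = cost or InfoCost()
    omegas = sorted(as_information(w).omega for w in search)
    if cost.cost_per_unit > 0:
        omegas = [w for w in omegas if not math.isinf(w)]
    if not omegas:
        raise ValueError("empty information search set")
    best_w, best_net = None, -math.inf
    for w in omegas:
        summary = population_summary(w, params, grids)
        net = summary.dominant_mean_inclusive - cost.total(w)
        if net > best_net:  # strict: earlier (smaller) omega wins ties
            best_w, best_net = w, net
    return InformationLevel(best_w)


def _perception_row(x: float, z_grid: np.ndarray,
                    omega: InformationLevel) -> np.ndarray:
    """P(z | x) masses over the z grid for one true value x."""
    from .belief import quad_weights

    if omega.is_perfect:
        row = np.zeros(z_grid.size)
        row[int(np.argmin(np.abs(z_grid - x)))] = 1.0
        return row
    if omega.is_none:
        dens = np.ones(z_grid.size)
    else:
        dens = np.asarray(perception_density(z_grid, x, omega))
    masses = dens * quad_weights(z_grid)
    return masses / masses.sum()


def optimal_information_subordinate(x: float, params: ModelParams,
                                    grids: Grids | None = None,
                                    search=DEFAULT_OMEGA_SEARCH) -> InformationLevel:
    """The dominant information level a subordinate of quality x prefers.

    For each candidate omega the dominant plays its optimal offer per
    perception; the subordinate's expected inclusive fitness is averaged
    over its own perception distribution P(z | x), counting both outcomes
    (cooperative payoff when the group forms, outside option otherwise).
    No information cost is charged. Ties break toward the smaller omega.
    """
    grids = grids or Grids.default()
    if not 0.0 <= x <= params.b:
        raise ValueError(f"quality x={x} outside [0, b={params.b}]")
    omegas = sorted(as_information(w).omega for w in search)
    if not omegas:
        raise ValueError("empty information search set")
    arr = ScenarioArrays.build(params, np.array([x]))
    y_c, g = float(arr.y_c[0]), float(arr.G[0])
    s_alone = params.r * params.b + x
    best_w, best_val = None, -math.inf
    for w in omegas:
        info = InformationLevel(w)
        curve = offer_curve(info, params, grids)
        stays = curve.share >= y_c - STAY_ATOL
        forms = stays & curve.accepts
        fit = np.where(
            forms, g * (curve.share * (1.0 - params.r) + params.r), s_alone
        )
        val = float(_perception_row(x, grids.z, info) @ fit)
        if val > best_val:
            best_w, best_val = w, val
    return InformationLevel(best_w)
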