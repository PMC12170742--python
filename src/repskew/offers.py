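"""Optimal concessions under uncertainty and group-formation regions.

The dominant observes a perception z of subordinate quality, forms the
posterior P(x | z), and picks the share y maximizing its expected inclusive
fitness, accounting for the fact that a subordinate of quality x stays only
if y reaches its critical concession. The expected objective

    E(y | z) = sum_x P(x | z) * [ G(x)*(1 - y*(1 - r))  if the subordinate stays
                                  b + r*x               otherwise ]

is piecewise linear in y with upward jumps at each quality's staying
threshold, so the maximum sits at one of those thresholds (or at 0); it is
found exactly by evaluating the objective on that candidate set. Ties break
toward the smaller share — the smallest concession that induces staying.

The dominant's accept/evict decision uses EXPECTED payoffs (it cannot
condition on the true x); region labels over the (x, z) plane compare
REALIZED payoffs of each party at the offered share against breeding alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .belief import (
    InformationLevel,
    OmegaLike,
    as_information,
    bayes_invert,
    perception_kernel,
    posterior,
)
from .core import (
    STAY_ATOL,
    ModelParams,
    Offer,
    critical_concession,
    group_productivity,
)
from .grids import Grids

__all__ = [
    "REGION_LABELS",
    "DecisionRecord",
    "candidate_shares",
    "optimal_offer_under_uncertainty",
    "no_info_offer",
    "classify_region",
    "region_map",
    "average_preference",
]

REGION_LABELS = (
    "both_prefer_group",
    "dominant_only",
    "subordinate_only",
    "neither",
)


@dataclass(frozen=True)
class DecisionRecord:
    """Realized outcome of one (true quality, perceived quality) cell."""

    x: float
    z: float
    weight: float
    share: float
    subordinate_stays: bool
    dominant_accepts: bool
    group_forms: bool
    region: str
    dominant_fitness: float
    subordinate_fitness: float


@dataclass(frozen=True, eq=False)
class ScenarioArrays:
    """Per-quality quantities precomputed on the x grid."""

    x: np.ndarray
    y_c: np.ndarray
    G: np.ndarray
    d_alone: np.ndarray
    s_alone: np.ndarray

    @classmethod
    def build(cls, params: ModelParams, x_grid: np.ndarray) -> "ScenarioArrays":
        x = np.asarray(x_grid, dtype=float)
        return cls(
            x=x,
            y_c=np.asarray(critical_concession(x, params)),
            G=np.asarray(group_productivity(x, params)),
            d_alone=params.b + params.r * x,
            s_alone=params.r * params.b + x,
        )


def _payoff_matrix(y: np.ndarray, arr: ScenarioArrays, params: ModelParams) -> np.ndarray:
    """Dominant inclusive payoff for each (share, quality) pair."""
    stays = y[:, None] >= arr.y_c[None, :] - STAY_ATOL
    coop = arr.G[None, :] * (1.0 - y[:, None] * (1.0 - params.r))
    return np.where(stays, coop, arr.d_alone[None, :])


def candidate_shares(y_c: np.ndarray) -> np.ndarray:
    """The exhaustive candidate set for the optimal share, sorted ascending.

    The expected objective is piecewise linear and decreasing in y between
    staying thresholds, with an upward jump exactly at each y_c, so its
    maximum over [0, 1] is attained either at 0 or at one of the feasible
    critical concessions. Optimizing over this set is exact — no share
    grid is involved.
    """
    feasible = y_c[(y_c >= 0.0) & (y_c <= 1.0)]
    return np.unique(np.concatenate((np.array([0.0]), feasible)))


def _optimize_share(weights: np.ndarray, arr: ScenarioArrays,
                    params: ModelParams, grids: Grids) -> tuple[float, float, float]:
    """Best share for one posterior; returns (share, expected, expected_alone).

    First argmax over the ascending candidate set implements the
    smallest-concession tie-break.
    """
    cands = candidate_shares(arr.y_c)
    expected = _payoff_matrix(cands, arr, params) @ weights
    j = int(np.argmax(expected))
    e_alone = float(arr.d_alone @ weights)
    return float(cands[j]), float(expected[j]), e_alone




@dataclass(frozen=True, eq=False)
class OfferCurve:
    """Solved offers for every perception on the z grid at one omega."""

    omega: InformationLevel
    share: np.ndarray          # y*(z)
    accepts: np.ndarray        # dominant accept/evict per z (expected payoffs)
    expected: np.ndarray       # expected dominant inclusive at y*(z)
    expected_alone: np.ndarray
    kernel: np.ndarray         # P(z | x) masses, rows = x
    posterior: np.ndarray      # P(x | z), columns = z


def offer_curve(omega: OmegaLike, params: ModelParams, grids: Grids) -> OfferCurve:
    """Solve the dominant's offer for every perceived quality on the z grid."""
    info = as_information(omega)
    if params.r >= 1.0:
        # surfaces the degenerate-relatedness error before any numerics
        critical_concession(0.0, params)
    arr = ScenarioArrays.build(params, grids.x)
    kernel_obj = perception_kernel(grids.x, grids.z, info)
    kernel = kernel_obj.matrix
    # the decision posterior is the exact Bayes inversion of the same
    # tabulated kernel that weights the outcomes; this self-consistency is
    # what makes information (weakly) valuable to the dominant
    w_post, _ = bayes_invert(kernel_obj)
    cands = candidate_shares(arr.y_c)
    expected = _payoff_matrix(cands, arr, params) @ w_post  # (ncand, nz)
    best = np.argmax(expected, axis=0)  # first max: smallest share
    share = cands[best]
    e_star = expected[best, np.arange(grids.nz)]
    e_alone = arr.d_alone @ w_post
    accepts = e_star >= e_alone
    return OfferCurve(omega=info, share=share, accepts=accepts,
                      expected=e_star, expected_alone=e_alone,
                      kernel=kernel, posterior=w_post)


def optimal_offer_under_uncertainty(z: float, omega: OmegaLike,
                                    params: ModelParams,
                                    grids: Grids | None = None) -> Offer:
    """The dominant's optimal offer given one perceived quality z.

    Maximizes posterior-expected inclusive fitness exactly over the
    staying-threshold candidate shares; accepts iff the maximum weakly
    beats the expected solitary value. At
    omega = infinity the posterior is a point mass and the solution
    coincides with the perfect-information closed form wherever the group
    forms.
    """
    grids = grids or Grids.default()
    belief = posterior(z, omega, grids.x, z_grid=grids.z)
    arr = ScenarioArrays.build(params, grids.x)
    share, e_star, e_alone = _optimize_share(belief.weights, arr, params, grids)
    accepts = bool(e_star >= e_alone)
    return Offer(share=share, dominant_accepts=accepts,
                 expected_dominant_inclusive=e_star if accepts else e_alone,
                 perceived=float(z))


def no_info_offer(params: ModelParams, grids: Grids | None = None) -> Offer:
    """Optimal offer of a dominant with no information (uniform belief).

    Identical to ``optimal_offer_under_uncertainty`` at omega = 0 for any
    z; exposed as a named entry point because the uninformed game has an
    analytic character of its own (a single z-independent share).
    """
    grids = grids or Grids.default()
    arr = ScenarioArrays.build(params, grids.x)
    weights = np.full(grids.nx, 1.0 / grids.nx)
    share, e_star, e_alone = _optimize_share(weights, arr, params, grids)
    accepts = bool(e_star >= e_alone)
    return Offer(share=share, dominant_accepts=accepts,
                 expected_dominant_inclusive=e_star if accepts else e_alone,
                 perceived=None)


def _region_label(dom_prefers: bool, sub_prefers: bool) -> str:
    if dom_prefers and sub_prefers:
        return "both_prefer_group"
    if dom_prefers:
        return "dominant_only"
    if sub_prefers:
        return "subordinate_only"
    return "neither"


def classify_region(x: float, z: float, omega: OmegaLike, params: ModelParams,
                    grids: Grids | None = None) -> str:
    """Which party would realize higher fitness in the group at y*(z).

    Compares each party's realized payoff at the offered share against its
    solitary value; ties side with the group.
    """
    grids = grids or Grids.default()
    offer = optimal_offer_under_uncertainty(z, omega, params, grids)
    g = group_productivity(x, params)
    dom_group = g * (1.0 - offer.share * (1.0 - params.r))
    sub_group = g * (offer.share * (1.0 - params.r) + params.r)
    dom_prefers = bool(dom_group >= params.b + params.r * x - STAY_ATOL)
    sub_prefers = bool(sub_group >= params.r * params.b + x - STAY_ATOL)
    return _region_label(dom_prefers, sub_prefers)


def region_map(omega: OmegaLike, params: ModelParams,
               grids: Grids | None = None) -> pd.DataFrame:
    """Full decision table over the (x, z) plane at one information level.

    One row per (true quality, perceived quality) cell with the joint
    weight P(z | x) * P(x) (uniform quality prior), the offered share, both
    parties' stay/accept decisions, the realized fitness of each party and
    the four-way preference region. Cell weights sum to 1 over the table.
    """
    grids = grids or Grids.default()
    curve = offer_curve(omega, params, grids)
    arr = ScenarioArrays.build(params, grids.x)
    share = curve.share[None, :]                      # (1, nz)
    stays = share >= arr.y_c[:, None] - STAY_ATOL     # (nx, nz)
    accepts = np.broadcast_to(curve.accepts[None, :], stays.shape)
    forms = stays & accepts
    coop_dom = arr.G[:, None] * (1.0 - share * (1.0 - params.r))
    coop_sub = arr.G[:, None] * (share * (1.0 - params.r) + params.r)
    dom_fit = np.where(forms, coop_dom, arr.d_alone[:, None])
    sub_fit = np.where(forms, coop_sub, arr.s_alone[:, None])
    dom_prefers = coop_dom >= arr.d_alone[:, None] - STAY_ATOL
    sub_prefers = coop_sub >= arr.s_alone[:, None] - STAY_ATOL
    weight = curve.kernel / grids.nx

    xx, zz = np.meshgrid(grids.x, grids.z, indexing="ij")
    region = np.where(
        dom_prefers & sub_prefers, "both_prefer_group",
        np.where(dom_prefers, "dominant_only",
                 np.where(sub_prefers, "subordinate_only", "neither")),
    )
    return pd.DataFrame(
        {
            "x": xx.ravel(),
            "z": zz.ravel(),
            "weight": weight.ravel(),
            "share": np.broadcast_to(share, stays.shape).ravel(),
            "subordinate_stays": stays.ravel(),
            "dominant_accepts": accepts.ravel(),
            "group_forms": forms.ravel(),
            "region": region.ravel(),
            "dominant_fitness": dom_fit.ravel(),
            "subordinate_fitness": sub_fit.ravel(),
        }
    )


def average_preference(omega: OmegaLike, params: ModelParams,
                       grids: Grids | None = None,
                       rule: str = "weighted_mean") -> pd.DataFrame:
    """Per-quality group preference averaged over perceptions.

    For each true quality x, each party's in-group payoff at y*(z) is
    averaged over z with weight P(z | x) and compared to its solitary
    value ("weighted_mean" rule); the "majority" rule instead asks whether
    the perception-weighted fraction of z at which the party prefers the
    group is at least one half. Returns one row per x with boolean
    preferences and the four-way region label.
    """
    if rule not in ("weighted_mean", "majority"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    grids = grids or Grids.default()
    curve = offer_curve(omega, params, grids)
    arr = ScenarioArrays.build(params, grids.x)
    share = curve.share[None, :]
    coop_dom = arr.G[:, None] * (1.0 - share * (1.0 - params.r))
    coop_sub = arr.G[:, None] * (share * (1.0 - params.r) + params.r)
    if rule == "weighted_mean":
        dom_wants = (curve.kernel * coop_dom).sum(axis=1) >= arr.d_alone - STAY_ATOL
        sub_wants = (curve.kernel * coop_sub).sum(axis=1) >= arr.s_alone - STAY_ATOL
    else:
        dom_pref = coop_dom >= arr.d_alone[:, None] - STAY_ATOL
        sub_pref = coop_sub >= arr.s_alone[:, None] - STAY_ATOL
        dom_wants = (curve.kernel * dom_pref).sum(axis=1) >= 0.5
        sub_wants = (curve.kernel * sub_pref).sum(axis=1) >= 0.5
    labels = [
        _region_label(bool(d), bool(s)) for d, s in zip(dom_wants, sub_wants)
    ]
    return pd.DataFrame(
        {
            "x": grids.x,
            "dominant_wants_group": dom_wants,
            "subordinate_wants_group": sub_wants,
            "region": labels,
        }
    )
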