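"""The parallel game where quality is known but relatedness is uncertain.

Here the dominant observes subordinate quality x perfectly but perceives
relatedness through the same beta kernel, with information level Omega and
a uniform prior over candidate relatedness values on [0, 1). The
subordinate knows its own relatedness, so its stay rule always uses the
TRUE r, while the dominant's expected objective integrates over its
posterior. The value of information about relatedness is the difference in
realized inclusive fitness between the Omega = infinity (r known) and
Omega = 0 (r could be anything) versions of the same game — computed for
the dominant (averaged over the relatedness prior) and for a related and an
unrelated subordinate.

Functions here take a ModelParams for the productivity side (b, a, m); its
``r`` field is ignored, since relatedness is the uncertain variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .belief import OmegaLike, as_information, posterior
from .core import STAY_ATOL, ModelParams, Offer
from .grids import Grids, default_relatedness_grid
from .offers import candidate_shares

__all__ = [
    "KinBelief",
    "InfoValueRecord",
    "optimal_offer_uncertain_r",
    "offer_curve_uncertain_r",
    "mean_offer_given_relatedness",
    "value_of_information_relatedness",
    "relatedness_value_table",
]


@dataclass(frozen=True, eq=False)
class KinBelief:
    """Posterior over candidate relatedness values given one perception."""

    grid: np.ndarray
    weights: np.ndarray
    perceived: float | None


@dataclass(frozen=True)
class InfoValueRecord:
    """Value of relatedness information for each party at one (x, a).

    Deltas are realized inclusive fitness under perfect information about r
    minus under no information, at the respective optimal offers.
    """

    x: float
    a: float
    delta_dominant: float
    delta_related_subordinate: float
    delta_unrelated_subordinate: float


@dataclass(frozen=True, eq=False)
class _KinArrays:
    """Per-candidate-relatedness quantities at one known quality x."""

    r: np.ndarray
    y_c: np.ndarray
    d_alone: np.ndarray
    s_alone: np.ndarray
    G: float

    @classmethod
    def build(cls, x: float, params: ModelParams,
              r_grid: np.ndarray) -> "_KinArrays":
        h = params.m + params.a * x
        g = params.b * (1.0 + h)
        if g <= 0:
            raise ValueError(f"non-positive group productivity at x={x}")
        r = np.asarray(r_grid, dtype=float)
        if np.any(r >= 1.0):
            raise ValueError("relatedness grid must stay strictly below 1")
        y_c = (x - params.b * r * h) / (params.b * (1.0 - r) * (h + 1.0))
        return cls(r=r, y_c=y_c, d_alone=params.b + r * x,
                   s_alone=r * params.b + x, G=float(g))


def _kin_payoff(y: np.ndarray, arr: _KinArrays) -> np.ndarray:
    """Dominant inclusive payoff for each (share, true relatedness) pair.

    The subordinate's stay rule uses the true r (it knows its own
    relatedness); the dominant's cooperative inclusive fitness also depends
    on the true r through the indirect component.
    """
    stays = y[:, None] >= arr.y_c[None, :] - STAY_ATOL
    coop = arr.G * (1.0 - y[:, None] * (1.0 - arr.r[None, :]))
    return np.where(stays, coop, arr.d_alone[None, :])


def _optimize_kin_share(weights: np.ndarray, arr: _KinArrays,
                        grids: Grids) -> tuple[float, float, float]:
    # exact optimization over the jump points of the piecewise objective;
    # first argmax over the ascending candidates = smallest-share tie-break
    cands = candidate_shares(arr.y_c)
    expected = _kin_payoff(cands, arr) @ weights
    j = int(np.argmax(expected))
    return float(cands[j]), float(expected[j]), float(arr.d_alone @ weights)


def optimal_offer_uncertain_r(x: float, perceived_r: float, omega: OmegaLike,
                              params: ModelParams,
                              grids: Grids | None = None,
                              r_grid: np.ndarray | None = None,
                              prior: np.ndarray | None = None) -> Offer:
    """Optimal offer when relatedness is perceived with information Omega.

    The posterior over candidate relatedness reuses the beta perception
    kernel; at Omega = infinity it collapses to the grid point nearest the
    perceived value and the offer reduces to the perfect-information
    closed form at that relatedness.
    """
    grids = grids or Grids.default()
    r_grid = default_relatedness_grid() if r_grid is None else np.asarray(r_grid)
    arr = _KinArrays.build(x, params, r_grid)
    belief = posterior(perceived_r, omega, r_grid, prior)
    share, e_star, e_alone = _optimize_kin_share(belief.weights, arr, grids)
    accepts = bool(e_star >= e_alone)
    return Offer(share=share, dominant_accepts=accepts,
                 expected_dominant_inclusive=e_star if accepts else e_alone,
                 perceived=float(perceived_r))


def offer_curve_uncertain_r(x: float, omega: OmegaLike, params: ModelParams,
                            grids: Grids | None = None,
                            r_grid: np.ndarray | None = None,
                            perceived_grid: np.ndarray | None = None):
    """Offers and accept decisions for every perceived relatedness value.

    Returns (perceived_grid, share, accepts) arrays.
    """
    grids = grids or Grids.default()
    r_grid = default_relatedness_grid() if r_grid is None else np.asarray(r_grid)
    perceived = grids.z if perceived_grid is None else np.asarray(perceived_grid)
    share = np.empty(perceived.size)
    accepts = np.empty(perceived.size, dtype=bool)
    arr = _KinArrays.build(x, params, r_grid)
    for j, zeta in enumerate(perceived):
        belief = posterior(float(zeta), omega, r_grid, z_grid=perceived)
        s, e_star, e_alone = _optimize_kin_share(belief.weights, arr, grids)
        share[j] = s
        accepts[j] = e_star >= e_alone
    return perceived, share, accepts


def mean_offer_given_relatedness(x: float, true_r: float, omega: OmegaLike,
                                 params: ModelParams,
                                 grids: Grids | None = None,
                                 r_grid: np.ndarray | None = None) -> float:
    """Expected offered share to a subordinate of true relatedness true_r.

    Averages y*(perceived r) over the dominant's perception distribution
    P(perceived | true_r) at information Omega.
    """
    from .population import _perception_row  # shared kernel-row helper

    grids = grids or Grids.default()
    info = as_information(omega)
    perceived, share, _ = offer_curve_uncertain_r(x, info, params, grids, r_grid)
    row = _perception_row(true_r, perceived, info)
    return float(row @ share)


def _perfect_info_outcomes(arr: _KinArrays) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Realized (share, dominant fitness, subordinate fitness) per true r
    when the dominant knows r exactly (closed-form offer at each r)."""
    y_star = np.clip(arr.y_c, 0.0, 1.0)
    retainable = arr.y_c <= 1.0 + STAY_ATOL
    coop_dom = arr.G * (1.0 - y_star * (1.0 - arr.r))
    coop_sub = arr.G * (y_star * (1.0 - arr.r) + arr.r)
    forms = retainable & (coop_dom >= arr.d_alone - STAY_ATOL)
    dom = np.where(forms, coop_dom, arr.d_alone)
    sub = np.where(forms, coop_sub, arr.s_alone)
    return np.where(forms, y_star, 0.0), dom, sub


def value_of_information_relatedness(x: float, a: float,
                                     params: ModelParams | None = None,
                                     grids: Grids | None = None,
                                     r_grid: np.ndarray | None = None,
                                     related_r: float = 0.5,
                                     unrelated_r: float = 0.0) -> InfoValueRecord:
    """Fitness difference between knowing and not knowing relatedness.

    ``params`` carries (b, m); when omitted, b = 1 and m is tied to the
    quality-productivity coefficient by the productivity-balancing
    constraint m = 0.6 - a/2, the same calibration used throughout the
    quality scenarios. The dominant's delta averages realized inclusive
    fitness over the uniform relatedness prior; the subordinate deltas are
    evaluated at the reference relatedness values (default: full sibling
    r = 0.5, non-kin r = 0).
    """
    if params is None:
        params = ModelParams(b=1.0, r=0.0, a=a, m=0.6 - a / 2.0)
    else:
        params = ModelParams(b=params.b, r=0.0, a=a, m=params.m)
    grids = grids or Grids.default()
    r_grid = default_relatedness_grid() if r_grid is None else np.asarray(r_grid)
    arr = _KinArrays.build(x, params, r_grid)
    prior = np.full(r_grid.size, 1.0 / r_grid.size)

    # no information: one share offered to all, best against the prior
    y0, e0_star, e0_alone = _optimize_kin_share(prior, arr, grids)
    accepts0 = e0_star >= e0_alone
    stays0 = y0 >= arr.y_c - STAY_ATOL
    forms0 = accepts0 & stays0
    dom0 = np.where(forms0, arr.G * (1.0 - y0 * (1.0 - arr.r)), arr.d_alone)
    sub0 = np.where(forms0, arr.G * (y0 * (1.0 - arr.r) + arr.r), arr.s_alone)

    # perfect information: closed-form offer at each true r
    _, dom_inf, sub_inf = _perfect_info_outcomes(arr)

    delta_dominant = float(prior @ (dom_inf - dom0))

    def subordinate_delta(ref_r: float) -> float:
        i = int(np.argmin(np.abs(r_grid - ref_r)))
        return float(sub_inf[i] - sub0[i])

    return InfoValueRecord(
        x=float(x),
        a=float(a),
        delta_dominant=delta_dominant,
        delta_related_subordinate=subordinate_delta(related_r),
        delta_unrelated_subordinate=subordinate_delta(unrelated_r),
    )


def relatedness_value_table(x_values, a_values,
                            grids: Grids | None = None,
                            r_grid: np.ndarray | None = None,
                            related_r: float = 0.5,
                            unrelated_r: float = 0.0) -> pd.DataFrame:
    """InfoValueRecord sweep over qualities and QPC values, as a table."""
    rows = []
    for a in a_values:
        for x in x_values:
            rec = value_of_information_relatedness(
                x, a, grids=grids, r_grid=r_grid,
                related_r=related_r, unrelated_r=unrelated_r,
            )
            rows.append(
                {
                    "x": rec.x,
                    "a": rec.a,
                    "delta_dominant": rec.delta_dominant,
                    "delta_related": rec.delta_related_subordinate,
                    "delta_unrelated": rec.delta_unrelated_subordinate,
                }
            )
    return pd.DataFrame(rows)
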