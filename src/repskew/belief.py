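"""Perception kernel and Bayesian belief over a discretized latent grid.

A dominant with information level omega observing a true value x in [0, 1]
perceives z drawn from a beta density

    P(z | x)  proportional to  z**(x*omega) * (1 - z)**((1 - x)*omega),

i.e. Beta(1 + x*omega, 1 + (1 - x)*omega). The mode of the density is
exactly x for every omega > 0; omega = 0 gives the uniform density (no
information) and omega = infinity a point mass at z = x (perfect
information). The infinite case is handled as a symbolic branch — one-hot
weight vectors on the grid — never as a large finite omega.

The dominant then forms the posterior P(x | z) by Bayes' rule on the grid,
against a (by default uniform) prior over true values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

__all__ = [
    "InformationLevel",
    "as_information",
    "BeliefState",
    "PerceptionKernel",
    "perception_density",
    "perception_kernel",
    "posterior",
    "bayes_invert",
    "quad_weights",
    "log_unnormalized_density",
]


@dataclass(frozen=True)
class InformationLevel:
    """Amount of information omega: a non-negative real, or infinity.

    ``math.inf`` is the perfect-information value and is treated as a
    distinct symbolic branch throughout, never approximated by a large
    float.
    """

    omega: float

    def __post_init__(self) -> None:
        w = float(self.omega)
        if math.isnan(w) or w < 0.0:
            raise InvalidInformationError(
                f"information level must be >= 0 or infinity, got {self.omega}"
            )
        object.__setattr__(self, "omega", w)

    @property
    def is_none(self) -> bool:
        return self.omega == 0.0

    @property
    def is_perfect(self) -> bool:
        return math.isinf(self.omega)

    @classmethod
    def none(cls) -> "InformationLevel":
        return cls(0.0)

    @classmethod
    def perfect(cls) -> "InformationLevel":
        return cls(math.inf)

    def __float__(self) -> float:
        return self.omega


class InvalidInformationError(ValueError):
    """Negative or undefined information level."""


OmegaLike = Union[InformationLevel, float, int, str]


def as_information(omega: OmegaLike) -> InformationLevel:
    """Coerce a float, int, "inf" string or InformationLevel to InformationLevel."""
    if isinstance(omega, InformationLevel):
        return omega
    if isinstance(omega, str):
        return InformationLevel(float(omega))
    return InformationLevel(float(omega))


@dataclass(frozen=True, eq=False)
class BeliefState:
    """Posterior over a latent grid, conditioned on one perception.

    ``weights`` are probabilities (non-negative, summing to 1) over
    ``grid``; ``perceived`` is the observation z this posterior conditions
    on (None for the no-information belief, which conditions on nothing).
    """

    grid: np.ndarray
    weights: np.ndarray
    perceived: float | None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0.0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("belief weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))

    def mean(self) -> float:
        return float(self.weights @ self.grid)


@dataclass(frozen=True, eq=False)
class PerceptionKernel:
    """Tabulated P(z | x) over the z grid.

    ``density[i, j]`` is the beta density of perceiving ``z_grid[j]`` given
    true value ``x_grid[i]``; ``matrix[i, j]`` is the corresponding cell
    probability mass (density times trapezoid cell weight, renormalized so
    each row sums to 1 exactly). At omega = infinity both hold the symbolic
    one-hot rows.
    """

    matrix: np.ndarray
    density: np.ndarray
    omega: InformationLevel
    x_grid: np.ndarray
    z_grid: np.ndarray


def perception_density(z, x, omega: OmegaLike):
    """Beta perception density P(z | x) at information level omega.

    Vectorized over ``z`` and ``x`` (broadcast). omega = 0 returns 1
    everywhere; omega = infinity returns the symbolic point mass — infinity
    where z == x exactly, 0 elsewhere.
    """
    info = as_information(omega)
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any((z < 0) | (z > 1)) or np.any((x < 0) | (x > 1)):
        raise ValueError("perception density defined for z, x in [0, 1] only")
    if info.is_none:
        out = np.ones(np.broadcast(z, x).shape)
        return out if out.ndim else float(out)
    if info.is_perfect:
        out = np.where(z == x, math.inf, 0.0)
        return out if out.ndim else float(out)
    w = info.omega
    out = stats.beta.pdf(z, 1.0 + x * w, 1.0 + (1.0 - x) * w)
    return out if out.ndim else float(out)


def _nearest_index(grid: np.ndarray, value: float) -> int:
    # ties resolve to the lower grid point
    return int(np.argmin(np.abs(grid - value)))


def quad_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid cell widths of a sorted grid (endpoints get half cells)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 1:
        return np.ones(1)
    d = np.diff(grid)
    w = np.empty(grid.size)
    w[0] = d[0] / 2.0
    w[-1] = d[-1] / 2.0
    w[1:-1] = (d[:-1] + d[1:]) / 2.0
    return w


def log_unnormalized_density(z: float, x: np.ndarray, omega: float) -> np.ndarray:
    """log of z**(x*omega) * (1-z)**((1-x)*omega), with 0*log(0) := 0.

    This is the perception likelihood up to a z-only constant; working with
    it in log space keeps posteriors exact where the shared factors cancel
    (e.g. z = 0.5 is uninformative for every omega) and stable at large
    omega where the direct powers underflow.
    """
    x = np.asarray(x, dtype=float)
    ln_z = math.log(z) if z > 0.0 else -math.inf
    ln_1z = math.log1p(-z) if z < 1.0 else -math.inf
    e1 = x * omega
    e2 = (1.0 - x) * omega
    t1 = np.where(e1 == 0.0, 0.0, e1 * ln_z)
    t2 = np.where(e2 == 0.0, 0.0, e2 * ln_1z)
    return t1 + t2


def perception_kernel(x_grid: np.ndarray, z_grid: np.ndarray,
                      omega: OmegaLike) -> PerceptionKernel:
    """Tabulate the perception kernel: densities and row-stochastic masses.

    Masses are trapezoid cell weights times the density, renormalized per
    row. At omega = infinity each row is one-hot at the z grid point
    nearest the true value (exact when the grids coincide).
    """
    info = as_information(omega)
    x_grid = np.asarray(x_grid, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    if x_grid.size == 0 or z_grid.size == 0:
        raise ValueError("perception kernel requires non-empty grids")
    if info.is_perfect:
        matrix = np.zeros((x_grid.size, z_grid.size))
        for i, x in enumerate(x_grid):
            matrix[i, _nearest_index(z_grid, x)] = 1.0
        density = matrix.copy()
    else:
        if info.is_none:
            density = np.ones((x_grid.size, z_grid.size))
        else:
            w = info.omega
            density = stats.beta.pdf(
                z_grid[None, :], 1.0 + x_grid[:, None] * w,
                1.0 + (1.0 - x_grid[:, None]) * w,
            )
        masses = density * quad_weights(z_grid)[None, :]
        matrix = masses / masses.sum(axis=1, keepdims=True)
    return PerceptionKernel(matrix=matrix, density=density, omega=info,
                            x_grid=x_grid, z_grid=z_grid)


def bayes_invert(kernel: PerceptionKernel,
                 prior: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Exact Bayes inversion of a tabulated kernel against a prior.

    Returns ``(posterior, evidence)`` where ``posterior[:, j]`` is
    P(x | z_j) and ``evidence[j]`` is P(z_j). Because the kernel rows are
    probability masses summing to 1, the law of total probability
    sum_j evidence[j] * posterior[x, j] = prior[x] holds to machine
    precision. Evidence-free columns (possible only at omega = infinity
    with mismatched grids) fall back to the x grid point nearest z.
    """
    k = kernel.matrix
    nx = k.shape[0]
    if prior is None:
        prior = np.full(nx, 1.0 / nx)
    else:
        prior = np.asarray(prior, dtype=float)
        prior = prior / prior.sum()
    joint = k * prior[:, None]
    evidence = joint.sum(axis=0)
    safe = np.where(evidence == 0.0, 1.0, evidence)
    post = joint / safe[None, :]
    for j in np.flatnonzero(evidence == 0.0):
        post[_nearest_index(kernel.x_grid, kernel.z_grid[j]), j] = 1.0
    return post, evidence


def posterior(z: float, omega: OmegaLike, x_grid: np.ndarray,
              prior: np.ndarray | None = None,
              z_grid: np.ndarray | None = None) -> BeliefState:
    """Posterior belief P(x | z) over the grid by Bayes' rule.

    Weights are proportional to the discretized perception likelihood
    times the prior, using exactly the same row normalization as
    :func:`perception_kernel` over ``z_grid`` (which defaults to the
    latent grid itself). This self-consistency is what makes the law of
    total probability hold exactly on the grid and — downstream — the
    value of information non-negative: decisions optimized under these
    posteriors are scored with the matching joint weights. When z lies on
    ``z_grid`` the result coincides with the corresponding column of
    :func:`bayes_invert`.

    ``prior`` defaults to uniform over the grid. omega = 0 returns the
    prior unchanged; omega = infinity puts all mass on the grid point
    nearest z (which also resolves the all-zero-numerator corner where an
    off-grid z is observed under perfect information).
    """
    info = as_information(omega)
    x_grid = np.asarray(x_grid, dtype=float)
    if prior is None:
        prior = np.full(x_grid.size, 1.0 / x_grid.size)
    else:
        prior = np.asarray(prior, dtype=float)
        total = prior.sum()
        if total <= 0 or np.any(prior < 0):
            raise ValueError("prior must be non-negative with positive mass")
        prior = prior / total
    if info.is_none:
        return BeliefState(grid=x_grid, weights=prior.copy(), perceived=float(z))
    if info.is_perfect:
        weights = np.zeros(x_grid.size)
        weights[_nearest_index(x_grid, float(z))] = 1.0
        return BeliefState(grid=x_grid, weights=weights, perceived=float(z))
    z_grid = x_grid if z_grid is None else np.asarray(z_grid, dtype=float)
    w = info.omega
    dens = stats.beta.pdf(float(z), 1.0 + x_grid * w, 1.0 + (1.0 - x_grid) * w)
    row_norm = (
        stats.beta.pdf(z_grid[None, :], 1.0 + x_grid[:, None] * w,
                       1.0 + (1.0 - x_grid[:, None]) * w)
        @ quad_weights(z_grid)
    )
    numerator = dens / row_norm * prior
    evidence = numerator.sum()
    if evidence <= 0.0:
        weights = np.zeros(x_grid.size)
        weights[_nearest_index(x_grid, float(z))] = 1.0
    else:
        weights = numerator / evidence
    return BeliefState(grid=x_grid, weights=weights, perceived=float(z))
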