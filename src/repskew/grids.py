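"""Discretization grids for quality, perception and share spaces.

All state variables of the game live on [0, 1]: true subordinate quality x,
perceived quality z (or perceived relatedness), and the reproductive share y.
Expectations over x and z are taken on evenly spaced grids; the share is
optimized exactly over the staying thresholds of the grid qualities,
because the dominant's objective is piecewise linear in y with upward
jumps exactly there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grids", "default_relatedness_grid"]


def _unit_grid(n: int = 201) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


@dataclass(frozen=True, eq=False)
class Grids:
    """Grid resolutions used by the numerical solver.

    Parameters
    ----------
    x : ndarray
        True-quality grid, strictly increasing, within [0, 1]. Default 201
        points (step 0.005). Also used as the candidate-relatedness grid in
        the kinship variant (with the r = 1 endpoint dropped there).
    z : ndarray
        Perceived-value grid, same conventions as ``x``. Must equal ``x``
        when the perfect-information limit is evaluated on a map, so that
        the delta kernel is an identity.
    y_coarse : int
        Number of points of the reference share grid on [0, 1] (default
        1001, step 1e-3). The solver itself optimizes the share exactly
        over the staying-threshold candidates; this grid is used by
        brute-force validation scans and exported offer tables.
    y_refine_step : float
        Historical refinement step retained as a configuration knob for
        grid-based scans (default 1e-5).
    """

    x: np.ndarray = field(default_factory=_unit_grid)
    z: np.ndarray = field(default_factory=_unit_grid)
    y_coarse: int = 1001
    y_refine_step: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("x", "z"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.ndim != 1 or g.size == 0:
                raise ValueError(f"{name} grid must be a non-empty 1-D array")
            if np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} grid must be strictly increasing")
            if g[0] < 0.0 or g[-1] > 1.0:
                raise ValueError(f"{name} grid must lie within [0, 1]")
            object.__setattr__(self, name, g)
        if self.y_coarse < 2:
            raise ValueError("y_coarse must be at least 2")
        if not 0.0 < self.y_refine_step <= 1.0:
            raise ValueError("y_refine_step must be in (0, 1]")

    @classmethod
    def default(cls, n: int = 201, y_coarse: int = 1001,
                y_refine_step: float = 1e-5) -> "Grids":
        """Evenly spaced n-point grids on [0, 1] for both x and z."""
        return cls(x=_unit_grid(n), z=_unit_grid(n), y_coarse=y_coarse,
                   y_refine_step=y_refine_step)

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def nz(self) -> int:
        return self.z.size

    def y_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.y_coarse)


def default_relatedness_grid(n: int = 201) -> np.ndarray:
    """Candidate-relatedness grid on [0, 1) for the kinship-uncertainty model.

    The r = 1 endpoint is excluded: at r = 1 dominant and subordinate are
    genetically identical, the concession problem degenerates (any share is
    optimal) and the closed-form threshold divides by 1 - r.
    """
    return np.linspace(0.0, 1.0, n)[:-1]
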