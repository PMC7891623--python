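"""P-spline building blocks: B-spline bases on equally spaced knots and
difference penalties.

A basis is described by a :class:`SplineBasisSpec` holding the *full* knot
vector (inner knots plus boundary extension), the spline degree and the
order of the difference penalty.  The basis forms a partition of unity on
``inner_range``; evaluation outside that interval is rejected — callers are
expected to clamp predictor values first (see :mod:`bayesnorm.norming`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasisSpec",
    "PenaltyMatrix",
    "make_knots",
    "bspline_design",
    "difference_penalty",
]


@dataclass(frozen=True)
class SplineBasisSpec:
    """B-spline basis with a difference penalty on adjacent coefficients.

    Parameters
    ----------
    knots
        Full, strictly increasing knot vector (boundary knots included).
    degree
        Spline degree (3 = cubic).
    penalty_order
        Order of the forward-difference penalty on the coefficients.
    """

    knots: tuple[float, ...]
    degree: int
    penalty_order: int

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", tuple(knots.tolist()))
        if knots.ndim != 1 or knots.size < self.degree + 2:
            raise ValueError("knot vector too short for the requested degree")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.degree < 0:
            raise ValueError("degree must be non-negative")
        if self.penalty_order < 1:
            raise ValueError("penalty_order must be positive")
        # n_basis > penalty_order is required for a usable penalty; it is
        # enforced in difference_penalty so that degenerate single-basis
        # specs remain constructible.

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def inner_range(self) -> tuple[float, float]:
        """Interval on which the basis is a partition of unity."""
        k = np.asarray(self.knots)
        return float(k[self.degree]), float(k[len(k) - self.degree - 1])

    @property
    def inner_knots(self) -> np.ndarray:
        k = np.asarray(self.knots)
        return k[self.degree : len(k) - self.degree]

    def penalty(self) -> "PenaltyMatrix":
        return difference_penalty(self.n_basis, self.penalty_order)

    # -- serialization (plain JSON-able dict, bit-exact knots) -------------

    def to_dict(self) -> dict:
        return {
            "knots": list(self.knots),
            "degree": self.degree,
            "penalty_order": self.penalty_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasisSpec":
        return cls(
            knots=tuple(d["knots"]),
            degree=int(d["degree"]),
            penalty_order=int(d["penalty_order"]),
        )


@dataclass(frozen=True)
class PenaltyMatrix:
    """``D'D`` for an order-``order`` forward-difference operator ``D``."""

    matrix: np.ndarray
    order: int
    rank: int

    def quadratic_form(self, beta: np.ndarray) -> float:
        beta = np.asarray(beta, dtype=float)
        return float(beta @ self.matrix @ beta)


def make_knots(
    x_min: float,
    x_max: float,
    n_knots: int,
    degree: int,
    penalty_order: int = 2,
) -> SplineBasisSpec:
    """Equally spaced inner knots on ``[x_min, x_max]`` with equal-spacing
    boundary extension (``degree`` extra knots on each side).

    The extension keeps the difference penalty meaningful at the boundary;
    the resulting basis has ``n_knots + degree - 1`` functions.
    """
    if not x_min < x_max:
        raise ValueError(f"need x_min < x_max, got ({x_min}, {x_max})")
    if n_knots < degree + 2:
        raise ValueError(
            f"n_knots={n_knots} too small: need at least degree + 2 = {degree + 2}"
        )
    inner = np.linspace(x_min, x_max, n_knots)
    h = (x_max - x_min) / (n_knots - 1)
    left = x_min - h * np.arange(degree, 0, -1)
    right = x_max + h * np.arange(1, degree + 1)
    knots = np.concatenate([left, inner, right])
    return SplineBasisSpec(
        knots=tuple(knots.tolist()), degree=degree, penalty_order=penalty_order
    )


def bspline_design(x: np.ndarray, spec: SplineBasisSpec) -> np.ndarray:
    """Dense design matrix of B-spline basis values, one row per ``x``.

    Rows sum to one and have at most ``degree + 1`` nonzero entries.
    ``x`` must lie within ``spec.inner_range``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = spec.inner_range
    tol = 1e-12 * max(1.0, abs(lo), abs(hi))
    bad = (x < lo - tol) | (x > hi + tol)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValueError(
            f"x[{idx}]={x[idx]} outside basis inner range ({lo}, {hi}); "
            "clamp predictor values before evaluating the basis"
        )
    x = np.clip(x, lo, hi)  # absorb float fuzz at the boundaries
    t = np.asarray(spec.knots)
    return BSpline.design_matrix(x, t, spec.degree, extrapolate=False).toarray()


def difference_penalty(n_basis: int, order: int) -> PenaltyMatrix:
    """Penalty matrix ``K = D'D`` with ``D`` the order-th forward-difference
    operator on ``n_basis`` coefficients; rank ``n_basis - order``."""
    if not 0 < order < n_basis:
        raise ValueError(f"need 0 < order < n_basis, got order={order}, n_basis={n_basis}")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    K = D.T @ D
    return PenaltyMatrix(matrix=K, order=order, rank=n_basis - order)
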