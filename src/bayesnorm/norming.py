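"""From fitted models to norms: percentiles, centile curves, credible bands
and normed-score transforms."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .inference import DistributionalFit

__all__ = [
    "PercentileGrid",
    "clamp_ages",
    "percentile_of_score",
    "centile_curve",
    "credible_band",
    "normed_transforms",
    "DEFAULT_CENTILE_LEVELS",
]

logger = logging.getLogger(__name__)

#: Default centile levels for norm tables (probability scale).
DEFAULT_CENTILE_LEVELS = (0.004, 0.02, 0.10, 0.25, 0.50, 0.75, 0.90, 0.98, 0.996)


@dataclass(frozen=True)
class PercentileGrid:
    """Centile-curve table: ``scores[i, j]`` is the score at ``ages[i]``
    achieving percentile ``levels[j]``."""

    ages: np.ndarray
    levels: tuple[float, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (ages.size, len(self.levels)):
            raise ValueError("scores must be (n_ages, n_levels)")
        if np.any(np.diff(scores, axis=1) <= 0):
            raise ValueError(
                "centile scores must increase strictly in level at every age"
            )
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "scores", scores)


def clamp_ages(ages: np.ndarray, inner_range: tuple[float, float]) -> np.ndarray:
    """Force ages onto the basis inner range; out-of-range counts are logged."""
    ages = np.asarray(ages, dtype=float)
    lo, hi = inner_range
    n_clamped = int(np.sum((ages < lo) | (ages > hi)))
    if n_clamped:
        logger.info("clamped %d age value(s) to [%g, %g]", n_clamped, lo, hi)
    return np.clip(ages, lo, hi)


def percentile_of_score(y, age, mu_fn, sigma_fn):
    """Percentile (probability scale) of raw score ``y`` at ``age``:
    Phi((y - mu(age)) / sigma(age))."""
    mu = np.asarray(mu_fn(age), dtype=float)
    sigma = np.asarray(sigma_fn(age), dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma_fn must be strictly positive")
    return ndtr((np.asarray(y, dtype=float) - mu) / sigma)


def centile_curve(level: float, ages, mu_fn, sigma_fn) -> np.ndarray:
    """Score achieving ``level`` at each age:
    mu(age) + sigma(age) * Phi^-1(level)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"centile level must lie in (0, 1), got {level}")
    mu = np.asarray(mu_fn(ages), dtype=float)
    sigma = np.asarray(sigma_fn(ages), dtype=float)
    return mu + sigma * ndtri(level)


def credible_band(
    fit: DistributionalFit,
    level: float,
    ages,
    n_draws: int = 1001,
    seed: int = 0,
    interval: float = 0.95,
):
    """Pointwise posterior mean and equal-tailed credible interval of the
    ``level`` centile curve, from ``n_draws`` posterior samples of the
    coefficient vectors.

    Returns ``(lower, mean, upper)`` arrays over ``ages``.
    """
    from .basis import bspline_design

    if not fit.is_mcmc:
        raise ValueError("credible bands require an MCMC fit with posterior draws")
    if not 0.0 < level < 1.0:
        raise ValueError(f"centile level must lie in (0, 1), got {level}")
    bm = fit.pooled("beta_mu")
    bs = fit.pooled("beta_sigma")
    total = bm.shape[0]
    rng = np.random.default_rng(seed)
    if total >= n_draws:
        idx = rng.choice(total, size=n_draws, replace=False)
    else:
        idx = rng.choice(total, size=n_draws, replace=True)
    ages_c = clamp_ages(np.atleast_1d(np.asarray(ages, dtype=float)), fit.model.inner_range)
    D_mu = bspline_design(ages_c, fit.model.term_mu)
    D_s = bspline_design(ages_c, fit.model.term_sigma)
    mu_draws = bm[idx] @ D_mu.T  # (n_draws, n_ages)
    sigma_draws = np.exp(bs[idx] @ D_s.T)
    curves = mu_draws + sigma_draws * ndtri(level)
    alpha = (1.0 - interval) / 2.0
    lower = np.quantile(curves, alpha, axis=0)
    upper = np.quantile(curves, 1.0 - alpha, axis=0)
    return lower, curves.mean(axis=0), upper


def normed_transforms(percentile: float) -> dict:
    """Normed-score representations of a percentile: z-score and IQ
    (100 + 15 z)."""
    p = np.asarray(percentile, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("percentile must lie strictly inside (0, 1)")
    z = ndtri(p)
    return {"z": z if z.ndim else float(z), "iq": (100.0 + 15.0 * z) if z.ndim else float(100.0 + 15.0 * z)}


def percentile_grid(
    ages, levels, mu_fn, sigma_fn
) -> PercentileGrid:
    """Centile curves at several levels bundled into a validated grid."""
    levels = tuple(float(v) for v in levels)
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    scores = np.column_stack(
        [centile_curve(lv, ages, mu_fn, sigma_fn) for lv in levels]
    )
    return PercentileGrid(ages=ages, levels=levels, scores=scores)
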