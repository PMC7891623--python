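"""Synthetic population models and normative-sample generation.

The canonical prior population is an analytic stand-in for a fitted
intelligence-test norming model on ages 5-21: the mean score rises steeply
in childhood and flattens toward adulthood, the standard deviation varies
smoothly (mildly U-shaped) over age.  All constants live in
``DEFAULT_POPULATION_CONFIG``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "PopulationModel",
    "MisspecificationSpec",
    "MISSPECIFICATION_LEVELS",
    "DEFAULT_POPULATION_CONFIG",
    "default_prior_population",
    "default_misspecification",
    "apply_misspecification",
    "generate_sample",
]

AGE_RANGE = (5.0, 21.0)

#: All constants of the canonical prior population and the default
#: misspecification magnitudes (score units are raw test points).
#: The SD profile is log-linear in age — smoothly varying yet maximally
#: smooth on the log-link scale the model uses.
DEFAULT_POPULATION_CONFIG = {
    "age_range": AGE_RANGE,
    "mu_offset": 40.0,  # raw-score floor of the growth curve
    "mu_scale": 60.0,  # raw-score rise to the asymptote
    "mu_onset": 4.0,  # age at which the growth curve starts
    "mu_rate": 6.0,  # growth time-constant in years
    "sigma_level": 11.0,  # SD at the reference age
    "sigma_slope": 0.012,  # log-SD change per year
    "sigma_ref_age": 13.0,
    # misspecification magnitudes, expressed via the age-average SD below
    "delta_mu_factor": 0.3,
    "factor_sigma": 1.2,
    "mu_age_ramp_factor": 0.6,
}


def _mean_sigma(cfg: dict) -> float:
    """Age-average of the SD profile over the age range (closed form for the
    log-linear profile)."""
    lo, hi = cfg["age_range"]
    s, v, L = cfg["sigma_slope"], cfg["sigma_ref_age"], cfg["sigma_level"]
    return L * (np.exp(s * (hi - v)) - np.exp(s * (lo - v))) / (s * (hi - lo))


@dataclass(frozen=True)
class PopulationModel:
    """True conditional score distribution: N(mu_fn(age), sigma_fn(age)^2)."""

    mu_fn: Callable[[np.ndarray], np.ndarray]
    sigma_fn: Callable[[np.ndarray], np.ndarray]
    label: str = ""

    def percentile_surface(self, ages: np.ndarray, scores: np.ndarray) -> np.ndarray:
        """True percentile of each (age, score) pair (broadcasting inputs)."""
        from scipy.special import ndtr

        mu = np.asarray(self.mu_fn(ages), dtype=float)
        sigma = np.asarray(self.sigma_fn(ages), dtype=float)
        return ndtr((np.asarray(scores, dtype=float) - mu) / sigma)


MISSPECIFICATION_LEVELS = ("zero", "mu", "sigma", "mu_sigma", "mu_age")


@dataclass(frozen=True)
class MisspecificationSpec:
    """How the norming population deviates from the prior population.

    ``delta_mu`` shifts the mean uniformly, ``factor_sigma`` scales the SD,
    ``delta_mu_age_fn`` adds an age-dependent mean shift (must be
    non-constant for the ``mu_age`` level).
    """

    level: str
    delta_mu: float = 0.0
    factor_sigma: float = 1.0
    delta_mu_age_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.level not in MISSPECIFICATION_LEVELS:
            raise ValueError(f"unknown misspecification level {self.level!r}")
        if self.factor_sigma <= 0:
            raise ValueError("factor_sigma must be positive")
        if self.level == "mu_age":
            if self.delta_mu_age_fn is None:
                raise ValueError("mu_age level requires delta_mu_age_fn")
            lo, hi = AGE_RANGE
            grid = np.linspace(lo, hi, 64)
            vals = np.asarray(self.delta_mu_age_fn(grid), dtype=float)
            if np.ptp(vals) == 0:
                raise ValueError("delta_mu_age_fn must be non-constant over the age range")


def default_prior_population(config: dict | None = None) -> PopulationModel:
    """The package's canonical prior-stage population model."""
    cfg = dict(DEFAULT_POPULATION_CONFIG)
    if config:
        cfg.update(config)

    off, scale, onset, rate = cfg["mu_offset"], cfg["mu_scale"], cfg["mu_onset"], cfg["mu_rate"]
    level, slope, ref = cfg["sigma_level"], cfg["sigma_slope"], cfg["sigma_ref_age"]

    def mu_fn(age):
        age = np.asarray(age, dtype=float)
        return off + scale * (1.0 - np.exp(-(age - onset) / rate))

    def sigma_fn(age):
        age = np.asarray(age, dtype=float)
        return level * np.exp(slope * (age - ref))

    return PopulationModel(mu_fn=mu_fn, sigma_fn=sigma_fn, label="prior_population")


def default_misspecification(level: str, config: dict | None = None) -> MisspecificationSpec:
    """Default-magnitude misspecification at one of the five levels.

    Magnitudes are tied to the age-average SD of the prior population:
    a constant mean shift of 0.3 SD, an SD inflation of 20%, and for the
    age-dependent level a linear mean shift ramping from 0 at the lowest
    age to 0.6 SD at the highest age.
    """
    cfg = dict(DEFAULT_POPULATION_CONFIG)
    if config:
        cfg.update(config)
    sbar = _mean_sigma(cfg)
    lo, hi = cfg["age_range"]
    d_mu = cfg["delta_mu_factor"] * sbar
    f_sigma = cfg["factor_sigma"]
    ramp_top = cfg["mu_age_ramp_factor"] * sbar

    if level == "zero":
        return MisspecificationSpec(level="zero")
    if level == "mu":
        return MisspecificationSpec(level="mu", delta_mu=d_mu)
    if level == "sigma":
        return MisspecificationSpec(level="sigma", factor_sigma=f_sigma)
    if level == "mu_sigma":
        return MisspecificationSpec(level="mu_sigma", delta_mu=d_mu, factor_sigma=f_sigma)
    if level == "mu_age":

        def ramp(age):
            age = np.asarray(age, dtype=float)
            return ramp_top * (age - lo) / (hi - lo)

        return MisspecificationSpec(level="mu_age", delta_mu_age_fn=ramp)
    raise ValueError(f"unknown misspecification level {level!r}")


def apply_misspecification(
    pop: PopulationModel, spec: MisspecificationSpec
) -> PopulationModel:
    """Norming population implied by a prior population and a
    misspecification: shift mu, scale sigma, or shift mu age-dependently."""
    mu0, sigma0 = pop.mu_fn, pop.sigma_fn
    label = f"{pop.label}+{spec.level}"
    if spec.level == "zero":
        return PopulationModel(mu_fn=mu0, sigma_fn=sigma0, label=label)
    if spec.level == "mu":
        return PopulationModel(
            mu_fn=lambda a: mu0(a) + spec.delta_mu, sigma_fn=sigma0, label=label
        )
    if spec.level == "sigma":
        return PopulationModel(
            mu_fn=mu0, sigma_fn=lambda a: sigma0(a) * spec.factor_sigma, label=label
        )
    if spec.level == "mu_sigma":
        return PopulationModel(
            mu_fn=lambda a: mu0(a) + spec.delta_mu,
            sigma_fn=lambda a: sigma0(a) * spec.factor_sigma,
            label=label,
        )
    if spec.level == "mu_age":
        return PopulationModel(
            mu_fn=lambda a: mu0(a) + spec.delta_mu_age_fn(np.asarray(a, dtype=float)),
            sigma_fn=sigma0,
            label=label,
        )
    raise ValueError(f"unknown misspecification level {spec.level!r}")


def generate_sample(
    pop: PopulationModel, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normative sample of size ``n``: ages are equally spaced design points
    on the age range (both endpoints included), scores drawn independently
    from the conditional Gaussian.  Deterministic given ``seed``."""
    if n < 2:
        raise ValueError("need at least n = 2 observations")
    lo, hi = AGE_RANGE
    ages = np.linspace(lo, hi, int(n))
    rng = np.random.default_rng(seed)
    mu = np.asarray(pop.mu_fn(ages), dtype=float)
    sigma = np.asarray(pop.sigma_fn(ages), dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("population sigma must be positive over the age range")
    scores = rng.normal(mu, sigma)
    return ages, scores
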