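"""Gaussian location-scale distributional model.

The response is modelled as ``y_i ~ N(mu(x_i), sigma(x_i)^2)`` with the mean
on the identity scale and the standard deviation on the log scale, each
driven by one P-spline term in the predictor.  Both terms share knot count
and knot locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .basis import SplineBasisSpec

__all__ = [
    "ModelSpec",
    "CoefficientState",
    "additive_predictor",
    "invert_links",
    "gaussian_loglik",
]

#: Soft bound on the log-sigma predictor used inside optimizers/samplers to
#: avoid numeric collapse of the scale term.
ETA_SIGMA_BOUND = 20.0


@dataclass(frozen=True)
class ModelSpec:
    """Gaussian model with identity link for mu and log link for sigma."""

    term_mu: SplineBasisSpec
    term_sigma: SplineBasisSpec

    parameters: tuple[str, str] = ("mu", "sigma")
    link_mu: str = "identity"
    link_sigma: str = "log"

    def __post_init__(self) -> None:
        if self.term_mu.knots != self.term_sigma.knots:
            raise ValueError(
                "mu and sigma terms must share knot locations and count"
            )

    @property
    def inner_range(self) -> tuple[float, float]:
        return self.term_mu.inner_range

    def to_dict(self) -> dict:
        return {
            "term_mu": self.term_mu.to_dict(),
            "term_sigma": self.term_sigma.to_dict(),
            "link_mu": self.link_mu,
            "link_sigma": self.link_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            term_mu=SplineBasisSpec.from_dict(d["term_mu"]),
            term_sigma=SplineBasisSpec.from_dict(d["term_sigma"]),
        )


@dataclass
class CoefficientState:
    """Coefficients and smoothing variances for both distributional terms.

    ``tau_sq_*`` are the smoothing *variances* (tau squared) that scale the
    coefficient priors.
    """

    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    tau_sq_mu: float
    tau_sq_sigma: float

    def __post_init__(self) -> None:
        self.beta_mu = np.asarray(self.beta_mu, dtype=float)
        self.beta_sigma = np.asarray(self.beta_sigma, dtype=float)
        if self.tau_sq_mu <= 0 or self.tau_sq_sigma <= 0:
            raise ValueError("smoothing variances must be positive")

    def copy(self) -> "CoefficientState":
        return CoefficientState(
            self.beta_mu.copy(),
            self.beta_sigma.copy(),
            float(self.tau_sq_mu),
            float(self.tau_sq_sigma),
        )


def additive_predictor(beta: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Linear predictor ``design @ beta`` for one distributional parameter."""
    beta = np.asarray(beta, dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[1] != beta.shape[0]:
        raise ValueError(
            f"design {design.shape} does not conform with beta of length {beta.shape[0]}"
        )
    return design @ beta


def invert_links(
    eta_mu: np.ndarray, eta_sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map predictors to distributional parameters: mu = eta_mu,
    sigma = exp(eta_sigma)."""
    eta_mu = np.asarray(eta_mu, dtype=float)
    eta_sigma = np.asarray(eta_sigma, dtype=float)
    with np.errstate(over="raise"):
        try:
            sigma = np.exp(eta_sigma)
        except FloatingPointError:
            idx = int(np.argmax(eta_sigma))
            raise OverflowError(
                f"exp overflow inverting the sigma link at index {idx} "
                f"(eta_sigma={eta_sigma.flat[idx]})"
            ) from None
    return eta_mu, sigma


def gaussian_loglik(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Gaussian log-likelihood summed over observations."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), y.shape)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(np.sum(stats.norm.logpdf(y, loc=mu, scale=sigma)))
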