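"""Coefficient priors and the smoothing-variance hyperprior.

Three Gaussian prior laws on a coefficient vector are supported:

``weakly_informative``
    zero mean, precision ``K / tau^2`` with ``K`` the difference-penalty
    matrix — encodes smoothness only;
``fixed_effects``
    mean and precision transferred from a first-stage posterior, *not*
    scaled by ``tau`` — usable with MCMC;
``posterior_mode``
    transferred mean with precision ``P_hat / tau^2`` — usable only with
    posterior-mode estimation.

The smoothing variance ``tau^2`` carries an inverse-gamma hyperprior with
vague defaults ``a = b = 1e-4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

from .basis import PenaltyMatrix, SplineBasisSpec

if TYPE_CHECKING:  # pragma: no cover
    from .inference import DistributionalFit

__all__ = [
    "TermPrior",
    "PriorBundle",
    "DEFAULT_IG_A",
    "DEFAULT_IG_B",
    "weakly_informative_prior",
    "fixed_effects_prior",
    "posterior_mode_prior",
    "ig_log_density",
    "extract_prior_from_fit",
]

DEFAULT_IG_A = 1e-4
DEFAULT_IG_B = 1e-4

#: Relative ridge added to near-singular draw covariances before inversion.
COV_RIDGE_REL = 1e-8

_KINDS = ("weakly_informative", "fixed_effects", "posterior_mode")


@dataclass(frozen=True)
class TermPrior:
    """Gaussian prior on one coefficient vector plus its IG hyperprior.

    ``precision_core`` is the tau-free part of the precision: the penalty
    matrix ``K`` for the weakly informative kind, the transferred posterior
    precision ``P_hat`` otherwise.  When ``scaled_by_tau`` the effective
    precision is ``precision_core / tau^2``.
    """

    kind: str
    mean: np.ndarray
    precision_core: np.ndarray
    scaled_by_tau: bool
    ig_a: float = DEFAULT_IG_A
    ig_b: float = DEFAULT_IG_B
    core_rank: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.ig_a <= 0 or self.ig_b <= 0:
            raise ValueError("IG hyperparameters must be positive")
        m = np.asarray(self.mean, dtype=float)
        P = np.asarray(self.precision_core, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("precision_core must be square")
        if m.shape != (P.shape[0],):
            raise ValueError("mean length must match precision_core dimension")
        if not np.allclose(P, P.T, atol=1e-8 * max(1.0, float(np.abs(P).max()))):
            raise ValueError("precision_core must be symmetric")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "precision_core", 0.5 * (P + P.T))
        if self.core_rank < 0:
            ev = np.linalg.eigvalsh(self.precision_core)
            if ev[0] < -1e-8 * max(1.0, ev[-1]):
                raise ValueError("precision_core must be positive semi-definite")
            rank = int(np.sum(ev > 1e-8 * max(1.0, ev[-1])))
            object.__setattr__(self, "core_rank", rank)
        if self.kind == "fixed_effects":
            try:
                np.linalg.cholesky(self.precision_core)
            except np.linalg.LinAlgError:
                raise ValueError(
                    "fixed_effects prior requires a strictly positive-definite "
                    "precision matrix"
                ) from None

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def effective_precision(self, tau_sq: float) -> np.ndarray:
        """Precision of the coefficient prior at smoothing variance tau^2."""
        if self.scaled_by_tau:
            return self.precision_core / tau_sq
        return self.precision_core

    def quadratic_form(self, beta: np.ndarray) -> float:
        d = np.asarray(beta, dtype=float) - self.mean
        return float(d @ self.precision_core @ d)

    def log_density(self, beta: np.ndarray, tau_sq: float) -> float:
        """Log prior density of ``beta`` given ``tau_sq``, up to an additive
        constant not depending on ``beta`` or ``tau_sq``.

        Includes the ``-(rank/2) log tau^2`` normalization so that the
        conjugate tau^2 update follows from this very expression.
        """
        q = self.quadratic_form(beta)
        if self.scaled_by_tau:
            if tau_sq <= 0:
                raise ValueError("tau_sq must be positive")
            return -0.5 * self.core_rank * np.log(tau_sq) - 0.5 * q / tau_sq
        return -0.5 * q

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mean": self.mean.tolist(),
            "precision_core": self.precision_core.tolist(),
            "scaled_by_tau": self.scaled_by_tau,
            "ig_a": self.ig_a,
            "ig_b": self.ig_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TermPrior":
        return cls(
            kind=d["kind"],
            mean=np.asarray(d["mean"], dtype=float),
            precision_core=np.asarray(d["precision_core"], dtype=float),
            scaled_by_tau=bool(d["scaled_by_tau"]),
            ig_a=float(d["ig_a"]),
            ig_b=float(d["ig_b"]),
        )


def weakly_informative_prior(
    penalty: PenaltyMatrix, ig_a: float = DEFAULT_IG_A, ig_b: float = DEFAULT_IG_B
) -> TermPrior:
    """Zero-mean smoothness prior N(0, tau^2 K^-1) from a penalty matrix."""
    n = penalty.matrix.shape[0]
    return TermPrior(
        kind="weakly_informative",
        mean=np.zeros(n),
        precision_core=penalty.matrix,
        scaled_by_tau=True,
        ig_a=ig_a,
        ig_b=ig_b,
        core_rank=penalty.rank,
    )


def fixed_effects_prior(
    m: np.ndarray,
    P_hat: np.ndarray,
    ig_a: float = DEFAULT_IG_A,
    ig_b: float = DEFAULT_IG_B,
) -> TermPrior:
    """Transferred prior N(m, P_hat^-1); no tau scaling, MCMC-compatible."""
    return TermPrior(
        kind="fixed_effects",
        mean=np.asarray(m, dtype=float),
        precision_core=np.asarray(P_hat, dtype=float),
        scaled_by_tau=False,
        ig_a=ig_a,
        ig_b=ig_b,
    )


def posterior_mode_prior(
    m: np.ndarray,
    P_hat: np.ndarray,
    ig_a: float = DEFAULT_IG_A,
    ig_b: float = DEFAULT_IG_B,
) -> TermPrior:
    """Transferred prior N(m, tau^2 P_hat^-1); only valid with the
    posterior-mode estimator (the sampler rejects it)."""
    return TermPrior(
        kind="posterior_mode",
        mean=np.asarray(m, dtype=float),
        precision_core=np.asarray(P_hat, dtype=float),
        scaled_by_tau=True,
        ig_a=ig_a,
        ig_b=ig_b,
    )


def ig_log_density(tau_sq: float, a: float, b: float) -> float:
    """Log density of the inverse-gamma IG(a, b) hyperprior at ``tau_sq``
    (normalizing constant included)."""
    if tau_sq <= 0 or a <= 0 or b <= 0:
        raise ValueError("tau_sq, a and b must all be positive")
    return float(stats.invgamma.logpdf(tau_sq, a, scale=b))


@dataclass(frozen=True)
class PriorBundle:
    """Stage-one hand-off artifact: posterior mean and precision per
    distributional parameter plus the basis specs (knots reused verbatim)."""

    m_mu: np.ndarray
    P_mu: np.ndarray
    m_sigma: np.ndarray
    P_sigma: np.ndarray
    spec_mu: SplineBasisSpec
    spec_sigma: SplineBasisSpec

    def term_prior(self, parameter: str, kind: str) -> TermPrior:
        """Build a transferred prior for ``parameter`` in {'mu','sigma'}."""
        m, P = (self.m_mu, self.P_mu) if parameter == "mu" else (self.m_sigma, self.P_sigma)
        if kind == "fixed_effects":
            return fixed_effects_prior(m, P)
        if kind == "posterior_mode":
            return posterior_mode_prior(m, P)
        raise ValueError(f"cannot build a transferred prior of kind {kind!r}")

    def to_dict(self) -> dict:
        return {
            "m_mu": self.m_mu.tolist(),
            "P_mu": self.P_mu.tolist(),
            "m_sigma": self.m_sigma.tolist(),
            "P_sigma": self.P_sigma.tolist(),
            "spec_mu": self.spec_mu.to_dict(),
            "spec_sigma": self.spec_sigma.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorBundle":
        return cls(
            m_mu=np.asarray(d["m_mu"], dtype=float),
            P_mu=np.asarray(d["P_mu"], dtype=float),
            m_sigma=np.asarray(d["m_sigma"], dtype=float),
            P_sigma=np.asarray(d["P_sigma"], dtype=float),
            spec_mu=SplineBasisSpec.from_dict(d["spec_mu"]),
            spec_sigma=SplineBasisSpec.from_dict(d["spec_sigma"]),
        )


def _precision_from_draws(draws: np.ndarray) -> np.ndarray:
    """Invert the sample covariance of pooled draws, with a small diagonal
    ridge to tolerate near-singular covariances."""
    n, p = draws.shape
    if n < p + 1:
        raise ValueError(
            f"need at least {p + 1} pooled draws to invert a {p}x{p} covariance; got {n}"
        )
    S = np.cov(draws, rowvar=False)
    S = np.atleast_2d(S)
    ridge = COV_RIDGE_REL * np.trace(S) / S.shape[0]
    S_r = S + ridge * np.eye(S.shape[0])
    try:
        P = np.linalg.inv(S_r)
    except np.linalg.LinAlgError:
        raise ValueError(
            "posterior draw covariance is singular even after ridging; "
            "run more MCMC iterations"
        ) from None
    # reject the degenerate all-equal-draws case the ridge would mask
    if np.trace(S) <= 0:
        raise ValueError("posterior draws have zero variance; cannot form a precision")
    return 0.5 * (P + P.T)


def extract_prior_from_fit(fit: "DistributionalFit") -> PriorBundle:
    """Posterior mean and precision of the spline coefficients from a
    first-stage MCMC fit; knots are copied verbatim."""
    if not fit.is_mcmc:
        raise ValueError("prior extraction requires an MCMC fit with draws")
    bm = fit.pooled("beta_mu")
    bs = fit.pooled("beta_sigma")
    return PriorBundle(
        m_mu=bm.mean(axis=0),
        P_mu=_precision_from_draws(bm),
        m_sigma=bs.mean(axis=0),
        P_sigma=_precision_from_draws(bs),
        spec_mu=fit.model.term_mu,
        spec_sigma=fit.model.term_sigma,
    )
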