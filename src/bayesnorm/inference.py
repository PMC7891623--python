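"""Model estimation: MH-within-Gibbs sampling, posterior-mode optimization,
conjugate smoothing-variance updates, AICc knot selection and convergence
diagnostics.

Sampling scheme
---------------
Coefficient blocks are updated with Gaussian proposals built from the
iteratively weighted least squares (IWLS) approximation at the current
state.  For the mean term (identity link, Gaussian response) the IWLS
Gaussian *is* the exact full conditional, so that block is an exact Gibbs
draw; for the log-scale term the proposal uses the expected-information
weights (2 per observation) and a Metropolis-Hastings correction with the
full proposal asymmetry.  Smoothing variances of tau-scaled priors are
drawn exactly from their inverse-gamma full conditionals.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .basis import make_knots
from .model import (
    ETA_SIGMA_BOUND,
    CoefficientState,
    ModelSpec,
    additive_predictor,
    gaussian_loglik,
    invert_links,
)
from .priors import TermPrior, ig_log_density, weakly_informative_prior

__all__ = [
    "DistributionalFit",
    "log_posterior",
    "tau_full_conditional",
    "fit_mcmc",
    "fit_posterior_mode",
    "gelman_rubin",
    "aicc",
    "select_knots_aicc",
]

logger = logging.getLogger(__name__)

_MIN_GAMMA = 1e-300
_MAX_TAU_SQ = 1e300


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------


@dataclass
class DistributionalFit:
    """Result of an MCMC run (per-chain draws) or a mode search (one state)."""

    model: ModelSpec
    n_chains: int
    n_iter: int
    n_burnin: int
    seed: int
    beta_mu_draws: np.ndarray | None = None  # (chains, kept, p_mu)
    beta_sigma_draws: np.ndarray | None = None
    tau_sq_mu_draws: np.ndarray | None = None  # (chains, kept)
    tau_sq_sigma_draws: np.ndarray | None = None
    mode_state: CoefficientState | None = None
    acceptance_rates: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    logpost_trace: np.ndarray | None = None

    @property
    def is_mcmc(self) -> bool:
        return self.beta_mu_draws is not None

    @property
    def n_retained(self) -> int:
        if not self.is_mcmc:
            return 0
        return self.beta_mu_draws.shape[0] * self.beta_mu_draws.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: (chains*kept, p) or (chains*kept,)."""
        arr = getattr(self, f"{name}_draws")
        if arr is None:
            raise ValueError("no draws available (mode-only fit)")
        return arr.reshape(-1, *arr.shape[2:])

    def posterior_mean_state(self) -> CoefficientState:
        if self.is_mcmc:
            return CoefficientState(
                beta_mu=self.pooled("beta_mu").mean(axis=0),
                beta_sigma=self.pooled("beta_sigma").mean(axis=0),
                tau_sq_mu=float(self.pooled("tau_sq_mu").mean()),
                tau_sq_sigma=float(self.pooled("tau_sq_sigma").mean()),
            )
        assert self.mode_state is not None
        return self.mode_state.copy()

    def rhat_values(self) -> np.ndarray:
        """All spline-coefficient R-hat values, concatenated."""
        parts = [self.rhat.get("beta_mu"), self.rhat.get("beta_sigma")]
        parts = [np.atleast_1d(p) for p in parts if p is not None]
        return np.concatenate(parts) if parts else np.empty(0)

    # -- prediction --------------------------------------------------------

    def curves(self, clamp: bool = True):
        """Plug-in (mu_fn, sigma_fn) at the posterior mean (or mode) of the
        coefficients.  Ages outside the knot inner range are clamped when
        ``clamp`` is true."""
        from .basis import bspline_design  # local to avoid cycle at import
        from .norming import clamp_ages

        state = self.posterior_mean_state()
        spec_mu, spec_sigma = self.model.term_mu, self.model.term_sigma

        def mu_fn(ages):
            a = np.atleast_1d(np.asarray(ages, dtype=float))
            if clamp:
                a = clamp_ages(a, spec_mu.inner_range)
            return bspline_design(a, spec_mu) @ state.beta_mu

        def sigma_fn(ages):
            a = np.atleast_1d(np.asarray(ages, dtype=float))
            if clamp:
                a = clamp_ages(a, spec_sigma.inner_range)
            return np.exp(bspline_design(a, spec_sigma) @ state.beta_sigma)

        return mu_fn, sigma_fn

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """Write the fit to a directory: metadata JSON plus one delimited
        array file per parameter and chain (full double precision)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "model": self.model.to_dict(),
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "n_burnin": self.n_burnin,
            "seed": self.seed,
            "acceptance_rates": self.acceptance_rates,
            "rhat": {k: np.atleast_1d(v).tolist() for k, v in self.rhat.items()},
            "is_mcmc": self.is_mcmc,
        }
        if self.mode_state is not None:
            meta["mode_state"] = {
                "beta_mu": self.mode_state.beta_mu.tolist(),
                "beta_sigma": self.mode_state.beta_sigma.tolist(),
                "tau_sq_mu": self.mode_state.tau_sq_mu,
                "tau_sq_sigma": self.mode_state.tau_sq_sigma,
            }
        if self.logpost_trace is not None:
            meta["logpost_trace"] = np.asarray(self.logpost_trace).tolist()
        (path / "metadata.json").write_text(json.dumps(meta, indent=2))
        if self.is_mcmc:
            for name in ("beta_mu", "beta_sigma", "tau_sq_mu", "tau_sq_sigma"):
                arr = getattr(self, f"{name}_draws")
                for c in range(self.n_chains):
                    np.savetxt(
                        path / f"draws_{name}_chain{c}.csv",
                        np.atleast_2d(arr[c].T).T,
                        delimiter=",",
                        fmt="%.17e",
                    )
            report = _convergence_report(self.rhat)
            (path / "convergence.txt").write_text(report)

    @classmethod
    def load(cls, path) -> "DistributionalFit":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        model = ModelSpec.from_dict(meta["model"])
        fit = cls(
            model=model,
            n_chains=meta["n_chains"],
            n_iter=meta["n_iter"],
            n_burnin=meta["n_burnin"],
            seed=meta["seed"],
            acceptance_rates=meta.get("acceptance_rates", {}),
            rhat={k: np.asarray(v) for k, v in meta.get("rhat", {}).items()},
        )
        if "mode_state" in meta:
            ms = meta["mode_state"]
            fit.mode_state = CoefficientState(
                np.asarray(ms["beta_mu"]),
                np.asarray(ms["beta_sigma"]),
                ms["tau_sq_mu"],
                ms["tau_sq_sigma"],
            )
        if "logpost_trace" in meta:
            fit.logpost_trace = np.asarray(meta["logpost_trace"])
        if meta.get("is_mcmc"):
            for name in ("beta_mu", "beta_sigma", "tau_sq_mu", "tau_sq_sigma"):
                chains = []
                for c in range(fit.n_chains):
                    a = np.loadtxt(path / f"draws_{name}_chain{c}.csv", delimiter=",", ndmin=2)
                    if name.startswith("tau"):
                        a = a.ravel()
                    chains.append(a)
                setattr(fit, f"{name}_draws", np.stack(chains))
        return fit


def _convergence_report(rhat: dict) -> str:
    lines = ["coefficients with R-hat >= 1.1:"]
    bad = 0
    for name, vals in rhat.items():
        for i, v in enumerate(np.atleast_1d(vals)):
            if np.isfinite(v) and v >= 1.1:
                lines.append(f"  {name}[{i}] = {v:.4f}")
                bad += 1
    if bad == 0:
        lines.append("  (none)")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# log posterior and conjugate tau update
# ---------------------------------------------------------------------------


def log_posterior(
    state: CoefficientState,
    y: np.ndarray,
    design_mu: np.ndarray,
    design_sigma: np.ndarray,
    prior_mu: TermPrior,
    prior_sigma: TermPrior,
) -> float:
    """Joint log posterior (up to an additive constant): Gaussian
    log-likelihood plus, per term, the coefficient log prior given tau^2
    and the inverse-gamma log hyperprior on tau^2."""
    eta_mu = additive_predictor(state.beta_mu, design_mu)
    eta_sigma = additive_predictor(state.beta_sigma, design_sigma)
    mu, sigma = invert_links(eta_mu, eta_sigma)
    lp = gaussian_loglik(y, mu, sigma)
    lp += prior_mu.log_density(state.beta_mu, state.tau_sq_mu)
    lp += ig_log_density(state.tau_sq_mu, prior_mu.ig_a, prior_mu.ig_b)
    lp += prior_sigma.log_density(state.beta_sigma, state.tau_sq_sigma)
    lp += ig_log_density(state.tau_sq_sigma, prior_sigma.ig_a, prior_sigma.ig_b)
    return float(lp)


def tau_full_conditional(
    beta: np.ndarray,
    core: np.ndarray,
    a: float,
    b: float,
    rank: int | None = None,
    mean: np.ndarray | None = None,
) -> tuple[float, float]:
    """Shape and rate of the inverse-gamma full conditional of tau^2 under a
    Gaussian prior N(mean, tau^2 core^-1): shape = a + rank(core)/2 and
    rate = b + (beta-mean)' core (beta-mean) / 2."""
    beta = np.asarray(beta, dtype=float)
    core = np.asarray(core, dtype=float)
    if rank is None:
        rank = int(np.linalg.matrix_rank(core, hermitian=True))
    d = beta if mean is None else beta - np.asarray(mean, dtype=float)
    quad = float(d @ core @ d)
    return a + rank / 2.0, b + quad / 2.0


def _draw_tau_sq(rng: np.random.Generator, shape: float, rate: float) -> float:
    g = max(rng.gamma(shape), _MIN_GAMMA)
    return float(min(rate / g, _MAX_TAU_SQ)) if rate > 0 else _MIN_GAMMA


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _initial_state(
    x: np.ndarray,
    y: np.ndarray,
    X_mu: np.ndarray,
    X_sigma: np.ndarray,
    tau_sq_init: float = 10.0,
) -> CoefficientState:
    """Deterministic starting values: beta_mu from (lightly ridged) least
    squares of y, beta_sigma from the log of a moving-window residual SD
    projected on the sigma design."""
    p_mu = X_mu.shape[1]
    A = X_mu.T @ X_mu + 1e-8 * np.eye(p_mu)
    beta_mu = np.linalg.solve(A, X_mu.T @ y)
    resid = y - X_mu @ beta_mu

    order = np.argsort(x, kind="stable")
    n = len(y)
    window = max(11, n // 20)
    sd = np.empty(n)
    r_sorted = resid[order]
    for i in range(n):
        lo = max(0, i - window // 2)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        sd[order[i]] = np.std(r_sorted[lo:hi])
    overall = max(float(np.std(resid)), 1e-8)
    sd = np.clip(sd, 1e-3 * overall, None)

    p_s = X_sigma.shape[1]
    A_s = X_sigma.T @ X_sigma + 1e-8 * np.eye(p_s)
    beta_sigma = np.linalg.solve(A_s, X_sigma.T @ np.log(sd))
    return CoefficientState(beta_mu, beta_sigma, tau_sq_init, tau_sq_init)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


def _solve_gaussian(A: np.ndarray, rhs: np.ndarray):
    """Cholesky factor and mean of N(A^-1 rhs, A^-1)."""
    c, low = cho_factor(A, lower=False, check_finite=False)
    mean = cho_solve((c, low), rhs, check_finite=False)
    return c, mean


def _sigma_block_objective(
    eta: np.ndarray, resid_sq: np.ndarray, beta: np.ndarray, prior: TermPrior, tau_sq: float
) -> float:
    """Log target for the log-scale coefficients: likelihood part plus the
    Gaussian prior kernel (tau-normalization omitted: constant in beta)."""
    ll = float(np.sum(-eta - 0.5 * resid_sq * np.exp(-2.0 * eta)))
    d = beta - prior.mean
    Peff = prior.effective_precision(tau_sq)
    return ll - 0.5 * float(d @ Peff @ d)


def fit_mcmc(
    x: np.ndarray,
    y: np.ndarray,
    model: ModelSpec,
    prior_mu: TermPrior,
    prior_sigma: TermPrior,
    *,
    n_chains: int = 2,
    n_iter: int = 2000,
    n_burnin: int = 500,
    seed: int = 0,
    fix_beta_sigma: np.ndarray | None = None,
    fix_tau_sq_mu: float | None = None,
    fix_tau_sq_sigma: float | None = None,
) -> DistributionalFit:
    """MH-within-Gibbs sampler for the Gaussian location-scale model.

    Chains are run sequentially with seeds ``seed, seed + 1, ...``; output
    is a pure function of the inputs and the seed.  ``fix_*`` arguments pin
    parts of the state (useful for conjugate checks); fixed quantities are
    not updated but still recorded in the draws.
    """
    from .basis import bspline_design

    for prior, name in ((prior_mu, "mu"), (prior_sigma, "sigma")):
        if prior.kind == "posterior_mode":
            raise ValueError(
                f"the posterior_mode prior on the {name} term cannot be "
                "sampled by MCMC (its tau-scaled transferred precision "
                "requires posterior-mode estimation); use fit_posterior_mode"
            )
    if n_burnin >= n_iter:
        raise ValueError("n_burnin must be smaller than n_iter")

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X_mu = bspline_design(x, model.term_mu)
    X_sigma = bspline_design(x, model.term_sigma)
    p_mu, p_s = X_mu.shape[1], X_sigma.shape[1]
    n_keep = n_iter - n_burnin

    init = _initial_state(x, y, X_mu, X_sigma)
    if fix_beta_sigma is not None:
        init.beta_sigma = np.asarray(fix_beta_sigma, dtype=float)
    if fix_tau_sq_mu is not None:
        init.tau_sq_mu = float(fix_tau_sq_mu)
    if fix_tau_sq_sigma is not None:
        init.tau_sq_sigma = float(fix_tau_sq_sigma)
    lp0 = log_posterior(init, y, X_mu, X_sigma, prior_mu, prior_sigma)
    if not np.isfinite(lp0):
        raise RuntimeError(
            f"log posterior not finite at the initial state (value {lp0}); "
            "check data scaling and prior matrices"
        )

    XtX_sigma2 = 2.0 * (X_sigma.T @ X_sigma)  # constant Fisher weights

    beta_mu_out = np.empty((n_chains, n_keep, p_mu))
    beta_sigma_out = np.empty((n_chains, n_keep, p_s))
    tau_mu_out = np.empty((n_chains, n_keep))
    tau_sigma_out = np.empty((n_chains, n_keep))
    accept = {}

    for c in range(n_chains):
        rng = np.random.default_rng(seed + c)
        state = init.copy()
        eta_mu = X_mu @ state.beta_mu
        eta_sigma = X_sigma @ state.beta_sigma
        n_acc_sigma = 0
        n_prop_sigma = 0
        rw_scale = None  # None => IWLS proposals; float => random-walk fallback

        for it in range(n_iter):
            # ---- mu block: exact Gibbs draw of the Gaussian conditional
            w = np.exp(-2.0 * eta_sigma)
            Peff = prior_mu.effective_precision(state.tau_sq_mu)
            A = (X_mu * w[:, None]).T @ X_mu + Peff
            rhs = X_mu.T @ (w * y) + Peff @ prior_mu.mean
            cfac, mean = _solve_gaussian(A, rhs)
            z = rng.standard_normal(p_mu)
            state.beta_mu = mean + solve_triangular(cfac, z, lower=False, check_finite=False)
            eta_mu = X_mu @ state.beta_mu

            # ---- sigma block: IWLS MH (or adaptive random walk fallback)
            if fix_beta_sigma is None:
                resid_sq = (y - eta_mu) ** 2
                Peff_s = prior_sigma.effective_precision(state.tau_sq_sigma)
                A_s = XtX_sigma2 + Peff_s
                cfac_s, _ = _solve_gaussian(A_s, np.zeros(p_s))
                f_cur = _sigma_block_objective(
                    eta_sigma, resid_sq, state.beta_sigma, prior_sigma, state.tau_sq_sigma
                )
                if rw_scale is None:
                    u = resid_sq * np.exp(-2.0 * eta_sigma)
                    z_work = eta_sigma + 0.5 * (u - 1.0)
                    rhs_s = 2.0 * (X_sigma.T @ z_work) + Peff_s @ prior_sigma.mean
                    mean_f = cho_solve((cfac_s, False), rhs_s, check_finite=False)
                    zs = rng.standard_normal(p_s)
                    beta_prop = mean_f + solve_triangular(
                        cfac_s, zs, lower=False, check_finite=False
                    )
                    eta_prop = X_sigma @ beta_prop
                    f_prop = _sigma_block_objective(
                        eta_prop, resid_sq, beta_prop, prior_sigma, state.tau_sq_sigma
                    )
                    # reverse proposal mean (same A_s: weights do not depend on beta)
                    u_p = resid_sq * np.exp(-2.0 * eta_prop)
                    z_work_p = eta_prop + 0.5 * (u_p - 1.0)
                    rhs_p = 2.0 * (X_sigma.T @ z_work_p) + Peff_s @ prior_sigma.mean
                    mean_r = cho_solve((cfac_s, False), rhs_p, check_finite=False)
                    d_f = beta_prop - mean_f
                    d_r = state.beta_sigma - mean_r
                    log_q_fwd = -0.5 * float(d_f @ A_s @ d_f)
                    log_q_rev = -0.5 * float(d_r @ A_s @ d_r)
                    log_alpha = (f_prop - f_cur) + (log_q_rev - log_q_fwd)
                else:
                    zs = rng.standard_normal(p_s)
                    step = rw_scale * solve_triangular(
                        cfac_s, zs, lower=False, check_finite=False
                    )
                    beta_prop = state.beta_sigma + step
                    eta_prop = X_sigma @ beta_prop
                    f_prop = _sigma_block_objective(
                        eta_prop, resid_sq, beta_prop, prior_sigma, state.tau_sq_sigma
                    )
                    log_alpha = f_prop - f_cur  # symmetric proposal
                n_prop_sigma += 1
                if np.isfinite(log_alpha) and np.log(rng.uniform()) < log_alpha:
                    state.beta_sigma = beta_prop
                    eta_sigma = eta_prop
                    n_acc_sigma += 1
                if rw_scale is not None and it < n_burnin:
                    # Robbins-Monro drift toward ~23% acceptance
                    acc = 1.0 if state.beta_sigma is beta_prop else 0.0
                    rw_scale *= np.exp((acc - 0.23) / max(1, it) ** 0.6)
                if (
                    rw_scale is None
                    and it == n_burnin // 2
                    and n_prop_sigma > 0
                    and n_acc_sigma / n_prop_sigma < 0.05
                ):
                    logger.warning(
                        "sigma-block IWLS acceptance %.1f%% during burn-in; "
                        "switching to adaptive random walk",
                        100 * n_acc_sigma / n_prop_sigma,
                    )
                    rw_scale = 0.1

            # ---- smoothing variances
            if prior_mu.scaled_by_tau:
                if fix_tau_sq_mu is None:
                    shp, rate = tau_full_conditional(
                        state.beta_mu,
                        prior_mu.precision_core,
                        prior_mu.ig_a,
                        prior_mu.ig_b,
                        rank=prior_mu.core_rank,
                        mean=prior_mu.mean,
                    )
                    state.tau_sq_mu = _draw_tau_sq(rng, shp, rate)
            elif fix_tau_sq_mu is None:
                state.tau_sq_mu = _draw_tau_sq(rng, prior_mu.ig_a, prior_mu.ig_b)
            if prior_sigma.scaled_by_tau:
                if fix_tau_sq_sigma is None:
                    shp, rate = tau_full_conditional(
                        state.beta_sigma,
                        prior_sigma.precision_core,
                        prior_sigma.ig_a,
                        prior_sigma.ig_b,
                        rank=prior_sigma.core_rank,
                        mean=prior_sigma.mean,
                    )
                    state.tau_sq_sigma = _draw_tau_sq(rng, shp, rate)
            elif fix_tau_sq_sigma is None:
                state.tau_sq_sigma = _draw_tau_sq(rng, prior_sigma.ig_a, prior_sigma.ig_b)

            if it >= n_burnin:
                k = it - n_burnin
                beta_mu_out[c, k] = state.beta_mu
                beta_sigma_out[c, k] = state.beta_sigma
                tau_mu_out[c, k] = state.tau_sq_mu
                tau_sigma_out[c, k] = state.tau_sq_sigma

        if fix_beta_sigma is None and n_prop_sigma > 0 and n_acc_sigma == 0:
            raise RuntimeError(
                "sigma block accepted no proposals; rescale the data or "
                "override the proposal step scale"
            )
        accept[f"chain{c}"] = {
            "mu": 1.0,  # exact Gibbs
            "sigma": (n_acc_sigma / n_prop_sigma) if n_prop_sigma else 1.0,
        }

    rhat = {
        "beta_mu": _rhat_array(beta_mu_out),
        "beta_sigma": _rhat_array(beta_sigma_out),
    }
    return DistributionalFit(
        model=model,
        n_chains=n_chains,
        n_iter=n_iter,
        n_burnin=n_burnin,
        seed=seed,
        beta_mu_draws=beta_mu_out,
        beta_sigma_draws=beta_sigma_out,
        tau_sq_mu_draws=tau_mu_out,
        tau_sq_sigma_draws=tau_sigma_out,
        acceptance_rates=accept,
        rhat=rhat,
    )


# ---------------------------------------------------------------------------
# posterior mode
# ---------------------------------------------------------------------------


def fit_posterior_mode(
    x: np.ndarray,
    y: np.ndarray,
    model: ModelSpec,
    prior_mu: TermPrior,
    prior_sigma: TermPrior,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    fix_beta_sigma: np.ndarray | None = None,
    fix_tau_sq_mu: float | None = None,
    fix_tau_sq_sigma: float | None = None,
) -> DistributionalFit:
    """Maximize the log posterior by block-coordinate ascent.

    Mean coefficients solve a penalized weighted least-squares problem
    exactly; log-scale coefficients take damped Newton steps (step-halving
    guarantees ascent); each smoothing variance is set to the mode of its
    inverse-gamma full conditional.  Any prior kind is admissible here.
    """
    from .basis import bspline_design

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X_mu = bspline_design(x, model.term_mu)
    X_sigma = bspline_design(x, model.term_sigma)
    p_s = X_sigma.shape[1]

    state = _initial_state(x, y, X_mu, X_sigma)
    if fix_beta_sigma is not None:
        state.beta_sigma = np.asarray(fix_beta_sigma, dtype=float)
    if fix_tau_sq_mu is not None:
        state.tau_sq_mu = float(fix_tau_sq_mu)
    if fix_tau_sq_sigma is not None:
        state.tau_sq_sigma = float(fix_tau_sq_sigma)

    XtX_sigma2 = 2.0 * (X_sigma.T @ X_sigma)
    trace = [log_posterior(state, y, X_mu, X_sigma, prior_mu, prior_sigma)]
    if not np.isfinite(trace[0]):
        raise RuntimeError("log posterior not finite at the initial state")

    for _ in range(max_iter):
        eta_sigma = X_sigma @ state.beta_sigma
        # mu block: exact penalized WLS
        w = np.exp(-2.0 * eta_sigma)
        Peff = prior_mu.effective_precision(state.tau_sq_mu)
        A = (X_mu * w[:, None]).T @ X_mu + Peff
        rhs = X_mu.T @ (w * y) + Peff @ prior_mu.mean
        state.beta_mu = cho_solve(cho_factor(A), rhs)
        eta_mu = X_mu @ state.beta_mu

        # sigma block: damped Newton with expected-information weights
        if fix_beta_sigma is None:
            resid_sq = (y - eta_mu) ** 2
            Peff_s = prior_sigma.effective_precision(state.tau_sq_sigma)
            A_s = XtX_sigma2 + Peff_s
            cfac_s = cho_factor(A_s)
            for _inner in range(50):
                f_cur = _sigma_block_objective(
                    eta_sigma, resid_sq, state.beta_sigma, prior_sigma, state.tau_sq_sigma
                )
                u = resid_sq * np.exp(-2.0 * eta_sigma)
                z_work = eta_sigma + 0.5 * (u - 1.0)
                rhs_s = 2.0 * (X_sigma.T @ z_work) + Peff_s @ prior_sigma.mean
                target = cho_solve(cfac_s, rhs_s)
                step = target - state.beta_sigma
                s = 1.0
                improved = False
                for _half in range(30):
                    cand = state.beta_sigma + s * step
                    eta_cand = X_sigma @ cand
                    if np.max(np.abs(eta_cand)) > ETA_SIGMA_BOUND:
                        logger.warning(
                            "log-sigma predictor exceeded +/-%g; damping step",
                            ETA_SIGMA_BOUND,
                        )
                        s *= 0.5
                        continue
                    f_new = _sigma_block_objective(
                        eta_cand, resid_sq, cand, prior_sigma, state.tau_sq_sigma
                    )
                    if np.isfinite(f_new) and f_new >= f_cur:
                        state.beta_sigma = cand
                        eta_sigma = eta_cand
                        improved = f_new > f_cur + 1e-12 * abs(f_cur)
                        break
                    s *= 0.5
                if not improved:
                    break

        # smoothing variances: mode of the IG full conditional
        if prior_mu.scaled_by_tau and fix_tau_sq_mu is None:
            shp, rate = tau_full_conditional(
                state.beta_mu,
                prior_mu.precision_core,
                prior_mu.ig_a,
                prior_mu.ig_b,
                rank=prior_mu.core_rank,
                mean=prior_mu.mean,
            )
            state.tau_sq_mu = max(rate / (shp + 1.0), 1e-12)
        elif not prior_mu.scaled_by_tau and fix_tau_sq_mu is None:
            state.tau_sq_mu = prior_mu.ig_b / (prior_mu.ig_a + 1.0)
        if prior_sigma.scaled_by_tau and fix_tau_sq_sigma is None:
            shp, rate = tau_full_conditional(
                state.beta_sigma,
                prior_sigma.precision_core,
                prior_sigma.ig_a,
                prior_sigma.ig_b,
                rank=prior_sigma.core_rank,
                mean=prior_sigma.mean,
            )
            state.tau_sq_sigma = max(rate / (shp + 1.0), 1e-12)
        elif not prior_sigma.scaled_by_tau and fix_tau_sq_sigma is None:
            state.tau_sq_sigma = prior_sigma.ig_b / (prior_sigma.ig_a + 1.0)

        trace.append(log_posterior(state, y, X_mu, X_sigma, prior_mu, prior_sigma))
        if trace[-1] - trace[-2] < tol:
            return DistributionalFit(
                model=model,
                n_chains=0,
                n_iter=len(trace) - 1,
                n_burnin=0,
                seed=0,
                mode_state=state,
                logpost_trace=np.asarray(trace),
            )
    raise RuntimeError(
        f"posterior-mode search did not converge in {max_iter} iterations; "
        f"objective trace tail: {trace[-5:]}"
    )


# ---------------------------------------------------------------------------
# diagnostics and model selection
# ---------------------------------------------------------------------------


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor of one scalar trace.

    ``chains`` is (m, n) with m >= 2 chains of equal retained length n >= 2.
    R-hat = sqrt(((n-1)/n W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = chains.shape
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0.0:
        return float("inf") if B > 0 else float("nan")
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def _rhat_array(draws: np.ndarray) -> np.ndarray:
    """Vectorized R-hat over the trailing coefficient axis of
    (chains, kept, p) draws."""
    m, n, p = draws.shape
    if m < 2 or n < 2:
        return np.full(p, np.nan)
    W = np.mean(np.var(draws, axis=1, ddof=1), axis=0)
    B = n * np.var(np.mean(draws, axis=1), axis=0, ddof=1)
    out = np.full(p, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.sqrt(((n - 1) / n * W + B / n) / W)
    ok = W > 0
    out[ok] = val[ok]
    out[(W == 0) & (B == 0)] = np.nan
    return out


def aicc(loglik: float, p: float, n: int) -> float:
    """Corrected Akaike information criterion
    ``-2 loglik + 2p + 2p(p+1)/(n-p-1)``."""
    if n - p - 1 <= 0:
        raise ValueError(f"AICc undefined for p={p}, n={n} (n - p - 1 <= 0)")
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1.0) / (n - p - 1.0)


def _effective_df(fit: DistributionalFit, x: np.ndarray, y: np.ndarray) -> float:
    """Effective number of coefficients: trace of the smoother matrix per
    term plus one per smoothing variance."""
    from .basis import bspline_design

    state = fit.posterior_mean_state()
    X_mu = bspline_design(x, fit.model.term_mu)
    X_sigma = bspline_design(x, fit.model.term_sigma)
    sigma = np.exp(X_sigma @ state.beta_sigma)
    w = sigma**-2
    K_mu = fit.model.term_mu.penalty().matrix
    K_s = fit.model.term_sigma.penalty().matrix
    H_mu = (X_mu * w[:, None]).T @ X_mu
    H_s = 2.0 * (X_sigma.T @ X_sigma)
    df_mu = float(np.trace(np.linalg.solve(H_mu + K_mu / state.tau_sq_mu, H_mu)))
    df_s = float(np.trace(np.linalg.solve(H_s + K_s / state.tau_sq_sigma, H_s)))
    return df_mu + df_s + 2.0


def select_knots_aicc(
    x: np.ndarray,
    y: np.ndarray,
    candidate_knot_counts,
    *,
    degree: int = 3,
    penalty_order: int = 2,
    x_range: tuple[float, float] | None = None,
    return_table: bool = False,
):
    """Pick the inner-knot count minimizing AICc of a posterior-mode fit
    with weakly informative priors; ties resolve to the smallest count.

    With ``return_table`` also returns ``{count: (aicc, loglik, p_eff)}``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_range is None:
        x_range = (float(x.min()), float(x.max()))
    best_count, best_aicc = None, np.inf
    table: dict[int, tuple[float, float, float]] = {}
    for count in sorted(int(c) for c in candidate_knot_counts):
        spec = make_knots(x_range[0], x_range[1], count, degree, penalty_order)
        model = ModelSpec(term_mu=spec, term_sigma=spec)
        prior = weakly_informative_prior(spec.penalty())
        fit = fit_posterior_mode(x, y, model, prior, prior)
        from .basis import bspline_design

        state = fit.posterior_mean_state()
        mu = bspline_design(x, spec) @ state.beta_mu
        sigma = np.exp(bspline_design(x, spec) @ state.beta_sigma)
        ll = gaussian_loglik(y, mu, sigma)
        p_eff = _effective_df(fit, x, y)
        if len(y) - p_eff - 1 <= 0:
            warnings.warn(
                f"skipping candidate {count}: effective p={p_eff:.1f} too "
                f"large for n={len(y)}",
                stacklevel=2,
            )
            continue
        val = aicc(ll, p_eff, len(y))
        table[count] = (val, ll, p_eff)
        if val < best_aicc - 1e-12:
            best_count, best_aicc = count, val
    if best_count is None:
        raise ValueError("no admissible knot-count candidate")
    if return_table:
        return best_count, table
    return best_count
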