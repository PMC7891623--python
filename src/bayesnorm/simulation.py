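"""Factorial simulation of norming efficiency and robustness.

Each replicate runs the two-stage design: a prior-stage sample is fitted
with the weakly informative prior, its posterior mean and precision become
the informative prior, and a norming-stage sample from a (possibly
misspecified) population is fitted with the condition's prior.  The outcome
is the percentile RMSE against the true norming population.

Seeding: every random stream is derived by hashing the structural
coordinates of the draw together with the study base seed.  Norming-sample
noise is shared across prior types *and* prior sample sizes (paired
comparisons); prior-stage samples depend only on (n_prior, replicate).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.special import ndtr

from .basis import make_knots
from .inference import fit_mcmc, fit_posterior_mode
from .model import ModelSpec
from .population import (
    AGE_RANGE,
    MISSPECIFICATION_LEVELS,
    PopulationModel,
    apply_misspecification,
    default_misspecification,
    default_prior_population,
    generate_sample,
)
from .priors import PriorBundle, extract_prior_from_fit, weakly_informative_prior

__all__ = [
    "SimulationCondition",
    "SimulationResult",
    "McmcSettings",
    "PRIOR_TYPES",
    "rmse_percentiles",
    "run_replicate",
    "run_study",
]

logger = logging.getLogger(__name__)

PRIOR_TYPES = ("weakly_informative", "fixed_effects", "posterior_mode")
N_PRIOR_LEVELS = (500, 1000, 2000)
N_NORM_LEVELS = (250, 500, 1000)
DEFAULT_N_KNOTS = 24


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the factorial design."""

    prior_type: str
    misspec_level: str
    n_prior: int
    n_norm: int
    n_replicates: int = 25
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_type not in PRIOR_TYPES:
            raise ValueError(f"unknown prior type {self.prior_type!r}")
        if self.misspec_level not in MISSPECIFICATION_LEVELS:
            raise ValueError(f"unknown misspecification level {self.misspec_level!r}")

    @property
    def uses_prior_stage(self) -> bool:
        return self.prior_type in ("fixed_effects", "posterior_mode")


@dataclass
class SimulationResult:
    """Per-condition replicate RMSEs and their summary statistics."""

    condition: SimulationCondition
    rmse: np.ndarray
    rhat_violation_fraction: float = float("nan")
    n_failed: int = 0

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.rmse, ddof=1)) if len(self.rmse) > 1 else float("nan")

    @property
    def se_mean_rmse(self) -> float:
        return self.sd_rmse / np.sqrt(len(self.rmse))


@dataclass(frozen=True)
class McmcSettings:
    n_chains: int = 2
    n_iter: int = 2000
    n_burnin: int = 500

    @classmethod
    def reduced(cls) -> "McmcSettings":
        """Scaled-down settings for CI-sized studies."""
        return cls(n_chains=2, n_iter=600, n_burnin=200)


def _derived_seed(base_seed: int, *parts) -> int:
    """Stable 31-bit seed from the base seed and structural coordinates."""
    payload = repr((int(base_seed),) + tuple(parts)).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "little") & 0x7FFFFFFF


def rmse_percentiles(
    fit_mu_fn,
    fit_sigma_fn,
    true_pop: PopulationModel,
    n_age: int = 1000,
    n_score: int = 1000,
) -> float:
    """Root mean squared difference between fitted and true percentiles on a
    grid of ``n_age`` equally spaced ages over the full age range and, per
    age, ``n_score`` scores at true z-scores equally spaced on [-3, 3].
    Probability scale."""
    lo, hi = AGE_RANGE
    ages = np.linspace(lo, hi, n_age)
    z = np.linspace(-3.0, 3.0, n_score)
    mu_t = np.asarray(true_pop.mu_fn(ages), dtype=float)[:, None]
    sigma_t = np.asarray(true_pop.sigma_fn(ages), dtype=float)[:, None]
    scores = mu_t + z[None, :] * sigma_t
    theta_true = ndtr(z)[None, :]
    mu_f = np.asarray(fit_mu_fn(ages), dtype=float)[:, None]
    sigma_f = np.asarray(fit_sigma_fn(ages), dtype=float)[:, None]
    if np.any(sigma_f <= 0):
        raise ValueError("fitted sigma must be positive over the evaluation grid")
    theta_hat = ndtr((scores - mu_f) / sigma_f)
    return float(np.sqrt(np.mean((theta_hat - theta_true) ** 2)))


def _default_model(n_knots: int = DEFAULT_N_KNOTS) -> ModelSpec:
    spec = make_knots(AGE_RANGE[0], AGE_RANGE[1], n_knots, degree=3, penalty_order=2)
    return ModelSpec(term_mu=spec, term_sigma=spec)


def _stage_one(
    n_prior: int,
    replicate_index: int,
    base_seed: int,
    model: ModelSpec,
    settings: McmcSettings,
) -> tuple[PriorBundle, np.ndarray]:
    """Weakly-informative MCMC fit on a prior-stage sample; returns the
    transferable prior bundle and the fit's R-hat values."""
    pop = default_prior_population()
    data_seed = _derived_seed(base_seed, "prior_data", n_prior, replicate_index)
    mcmc_seed = _derived_seed(base_seed, "prior_mcmc", n_prior, replicate_index)
    ages, scores = generate_sample(pop, n_prior, data_seed)
    prior = weakly_informative_prior(model.term_mu.penalty())
    fit = fit_mcmc(
        ages,
        scores,
        model,
        prior,
        prior,
        n_chains=settings.n_chains,
        n_iter=settings.n_iter,
        n_burnin=settings.n_burnin,
        seed=mcmc_seed,
    )
    return extract_prior_from_fit(fit), fit.rhat_values()


@dataclass
class ReplicateResult:
    rmse: float
    rhat_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    error: str | None = None


def run_replicate(
    condition: SimulationCondition,
    replicate_index: int,
    *,
    stage_one_cache: dict | None = None,
    settings: McmcSettings | None = None,
    model: ModelSpec | None = None,
    rmse_grid: tuple[int, int] = (1000, 1000),
) -> ReplicateResult:
    """One replicate of one design cell; deterministic given
    (condition.base_seed, replicate_index)."""
    settings = settings or McmcSettings()
    model = model or _default_model()
    rhat_parts: list[np.ndarray] = []

    prior_bundle = None
    if condition.uses_prior_stage:
        key = (condition.n_prior, replicate_index)
        if stage_one_cache is not None and key in stage_one_cache:
            prior_bundle, s1_rhat = stage_one_cache[key]
        else:
            prior_bundle, s1_rhat = _stage_one(
                condition.n_prior, replicate_index, condition.base_seed, model, settings
            )
            if stage_one_cache is not None:
                stage_one_cache[key] = (prior_bundle, s1_rhat)
        rhat_parts.append(s1_rhat)

    m_norm = apply_misspecification(
        default_prior_population(), default_misspecification(condition.misspec_level)
    )
    # norm-sample noise paired across prior types and prior sample sizes
    data_seed = _derived_seed(
        condition.base_seed, "norm_data", condition.misspec_level, condition.n_norm, replicate_index
    )
    ages, scores = generate_sample(m_norm, condition.n_norm, data_seed)

    if condition.prior_type == "weakly_informative":
        p_mu = weakly_informative_prior(model.term_mu.penalty())
        p_sigma = weakly_informative_prior(model.term_sigma.penalty())
    else:
        p_mu = prior_bundle.term_prior("mu", condition.prior_type)
        p_sigma = prior_bundle.term_prior("sigma", condition.prior_type)

    if condition.prior_type == "posterior_mode":
        fit = fit_posterior_mode(ages, scores, model, p_mu, p_sigma, tol=1e-6)
    else:
        mcmc_seed = _derived_seed(
            condition.base_seed,
            "norm_mcmc",
            condition.prior_type,
            condition.misspec_level,
            # weakly informative fits must not depend on the prior stage at all
            condition.n_prior if condition.uses_prior_stage else None,
            condition.n_norm,
            replicate_index,
        )
        fit = fit_mcmc(
            ages,
            scores,
            model,
            p_mu,
            p_sigma,
            n_chains=settings.n_chains,
            n_iter=settings.n_iter,
            n_burnin=settings.n_burnin,
            seed=mcmc_seed,
        )
        rhat_parts.append(fit.rhat_values())

    mu_fn, sigma_fn = fit.curves()
    rmse = rmse_percentiles(mu_fn, sigma_fn, m_norm, *rmse_grid)
    rhat = np.concatenate(rhat_parts) if rhat_parts else np.empty(0)
    return ReplicateResult(rmse=rmse, rhat_values=rhat)


def _replicate_block(
    conditions: list[SimulationCondition],
    replicate_index: int,
    settings: McmcSettings,
    model: ModelSpec,
    rmse_grid: tuple[int, int],
) -> list[dict]:
    """All conditions for one replicate, sharing the stage-one cache."""
    cache: dict = {}
    rows = []
    for cond in conditions:
        try:
            res = run_replicate(
                cond,
                replicate_index,
                stage_one_cache=cache,
                settings=settings,
                model=model,
                rmse_grid=rmse_grid,
            )
            rows.append(
                {
                    "prior_type": cond.prior_type,
                    "misspec_level": cond.misspec_level,
                    "n_prior": cond.n_prior,
                    "n_norm": cond.n_norm,
                    "replicate": replicate_index,
                    "rmse": res.rmse,
                    "n_rhat": int(res.rhat_values.size),
                    "n_rhat_violations": int(
                        np.sum(res.rhat_values[np.isfinite(res.rhat_values)] >= 1.1)
                    ),
                    "error": "",
                }
            )
        except Exception as exc:  # failures are recorded, not dropped
            logger.exception("replicate %d of %s failed", replicate_index, cond)
            rows.append(
                {
                    "prior_type": cond.prior_type,
                    "misspec_level": cond.misspec_level,
                    "n_prior": cond.n_prior,
                    "n_norm": cond.n_norm,
                    "replicate": replicate_index,
                    "rmse": float("nan"),
                    "n_rhat": 0,
                    "n_rhat_violations": 0,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    return rows


_KEY_COLS = ["prior_type", "misspec_level", "n_prior", "n_norm", "replicate"]


def run_study(
    conditions,
    n_replicates: int | None = None,
    parallel_workers: int = 1,
    *,
    settings: McmcSettings | None = None,
    n_knots: int = DEFAULT_N_KNOTS,
    rmse_grid: tuple[int, int] = (1000, 1000),
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the factorial study.

    Returns ``(long, summary)`` data frames: one row per (condition,
    replicate), and per-condition mean/SD/SE of the RMSE plus the R-hat
    violation fraction.  With ``out_path`` the long table is streamed to a
    CSV after every replicate block, and an interrupted study resumes from
    whatever that file already contains.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one condition")
    if n_replicates is None:
        n_replicates = conditions[0].n_replicates
    if n_replicates < 2:
        raise ValueError("need at least two replicates")
    settings = settings or McmcSettings()
    model = _default_model(n_knots)

    done = pd.DataFrame(columns=_KEY_COLS + ["rmse", "n_rhat", "n_rhat_violations", "error"])
    out_path = Path(out_path) if out_path is not None else None
    if out_path is not None and out_path.exists():
        done = pd.read_csv(out_path, keep_default_na=False, na_values=["nan", ""])
        logger.info("resuming study: %d rows already on disk", len(done))

    def block_done(r: int) -> bool:
        if done.empty:
            return False
        sub = done[done["replicate"] == r]
        return len(sub) >= len(conditions)

    def _append(base: pd.DataFrame, rows: list[dict]) -> pd.DataFrame:
        new = pd.DataFrame(rows)
        return new if base.empty else pd.concat([base, new], ignore_index=True)

    pending = [r for r in range(n_replicates) if not block_done(r)]
    if parallel_workers > 1 and pending:
        blocks = Parallel(n_jobs=parallel_workers)(
            delayed(_replicate_block)(conditions, r, settings, model, rmse_grid)
            for r in pending
        )
        for rows in blocks:
            done = _append(done, rows)
        if out_path is not None:
            done.to_csv(out_path, index=False)
    else:
        for r in pending:
            rows = _replicate_block(conditions, r, settings, model, rmse_grid)
            done = _append(done, rows)
            if out_path is not None:
                done.to_csv(out_path, index=False)

    long = done.sort_values(_KEY_COLS).reset_index(drop=True)
    long["rmse"] = pd.to_numeric(long["rmse"], errors="coerce")

    groups = []
    for keys, g in long.groupby(_KEY_COLS[:4], sort=False):
        ok = g[np.isfinite(g["rmse"])]
        n_fail = int(len(g) - len(ok))
        n_rhat = int(pd.to_numeric(g["n_rhat"]).sum())
        n_viol = int(pd.to_numeric(g["n_rhat_violations"]).sum())
        row = dict(zip(_KEY_COLS[:4], keys))
        row.update(
            {
                "n_replicates": int(len(g)),
                "n_failed": n_fail,
                "mean_rmse": float(ok["rmse"].mean()) if len(ok) else float("nan"),
                "sd_rmse": float(ok["rmse"].std(ddof=1)) if len(ok) > 1 else float("nan"),
                "se_mean_rmse": (
                    float(ok["rmse"].std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else float("nan")
                ),
                "rhat_violation_fraction": (n_viol / n_rhat) if n_rhat else float("nan"),
                "flagged": n_fail > 0.1 * len(g),
            }
        )
        groups.append(row)
        if row["flagged"]:
            logger.warning("condition %s: %d/%d replicates failed", keys, n_fail, len(g))
    summary = pd.DataFrame(groups)
    return long, summary
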