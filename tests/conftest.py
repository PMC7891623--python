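"""Shared fixtures.

The reduced factorial study is session-scoped because it backs both the
simulation-module invariants and the qualitative acceptance checks; it is
the single most expensive fixture (~4-6 minutes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bayesnorm as bn
from bayesnorm.simulation import McmcSettings, SimulationCondition, run_study

STUDY_SEED = 20260905
STUDY_REPLICATES = 25


@pytest.fixture(scope="session")
def spec8():
    return bn.make_knots(5.0, 21.0, 8, 3)


@pytest.fixture(scope="session")
def model8(spec8):
    return bn.ModelSpec(term_mu=spec8, term_sigma=spec8)


@pytest.fixture(scope="session")
def weak_prior8(spec8):
    return bn.weakly_informative_prior(spec8.penalty())


@pytest.fixture(scope="session")
def data400():
    pop = bn.default_prior_population()
    return bn.generate_sample(pop, 400, seed=123)


@pytest.fixture(scope="session")
def fit400(data400, model8, weak_prior8):
    x, y = data400
    return bn.fit_mcmc(
        x, y, model8, weak_prior8, weak_prior8, n_iter=800, n_burnin=300, seed=7
    )


def _study_conditions() -> list[SimulationCondition]:
    conds = []
    for ms in ("zero", "mu_age"):
        for nn in (250, 1000):
            conds.append(
                SimulationCondition(
                    "weakly_informative", ms, n_prior=500, n_norm=nn,
                    n_replicates=STUDY_REPLICATES, base_seed=STUDY_SEED,
                )
            )
            for npri in (500, 2000):
                conds.append(
                    SimulationCondition(
                        "fixed_effects", ms, n_prior=npri, n_norm=nn,
                        n_replicates=STUDY_REPLICATES, base_seed=STUDY_SEED,
                    )
                )
    for nn in (250, 1000):
        conds.append(
            SimulationCondition(
                "posterior_mode", "zero", n_prior=2000, n_norm=nn,
                n_replicates=STUDY_REPLICATES, base_seed=STUDY_SEED,
            )
        )
    return conds


@pytest.fixture(scope="session")
def reduced_study() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scaled-down factorial study: R=25 replicates, 600 iterations with 200
    burn-in per chain (full paper scale is R=1000 / 2000 iterations)."""
    long, summary = run_study(
        _study_conditions(),
        n_replicates=STUDY_REPLICATES,
        settings=McmcSettings.reduced(),
    )
    return long, summary


def study_mean(summary: pd.DataFrame, prior_type: str, misspec: str, n_prior: int, n_norm: int) -> float:
    row = summary[
        (summary.prior_type == prior_type)
        & (summary.misspec_level == misspec)
        & (summary.n_prior == n_prior)
        & (summary.n_norm == n_norm)
    ]
    assert len(row) == 1, f"no unique study cell for {prior_type}/{misspec}/{n_prior}/{n_norm}"
    return float(row.mean_rmse.iloc[0])


def study_se(summary: pd.DataFrame, prior_type: str, misspec: str, n_prior: int, n_norm: int) -> float:
    row = summary[
        (summary.prior_type == prior_type)
        & (summary.misspec_level == misspec)
        & (summary.n_prior == n_prior)
        & (summary.n_norm == n_norm)
    ]
    return float(row.se_mean_rmse.iloc[0])
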