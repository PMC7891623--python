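"""Readers and writers for normative data, prior bundles and norm tables.

The delimited-text dialect is fixed: comma-separated, header row required,
decimal point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .priors import PriorBundle

__all__ = [
    "NormativeDataset",
    "read_normative_csv",
    "write_normative_csv",
    "write_prior_json",
    "read_prior_json",
    "write_norm_table",
    "write_norm_card",
    "read_norm_card",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormativeDataset:
    """One record per testee: age (years) and raw score."""

    age: np.ndarray
    score: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=float)
        score = np.asarray(self.score, dtype=float)
        if age.shape != score.shape or age.ndim != 1:
            raise ValueError("age and score must be one-dimensional and equally long")
        if not np.all(np.isfinite(age)) or not np.all(np.isfinite(score)):
            raise ValueError("ages and scores must be finite after ingestion")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "score", score)

    @property
    def n(self) -> int:
        return int(self.age.size)


def read_normative_csv(
    path,
    age_column: str = "age",
    score_column: str = "score",
    inner_range: tuple[float, float] | None = None,
) -> NormativeDataset:
    """Parse a delimited normative data file.

    Rows with a missing age or score are dropped (count logged).  When an
    ``inner_range`` is given, out-of-range ages are clamped to its bounds
    (count logged) so that the data fit the active spline basis.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (age_column, score_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} (has {list(df.columns)})")
    raw = df[[age_column, score_column]].apply(pd.to_numeric, errors="coerce")
    bad = raw.isna().any(axis=1)
    if bad.any():
        rows = (raw.index[bad] + 2).tolist()  # 1-based incl. header
        logger.warning("dropped %d row(s) with missing/unparseable values (file rows %s)",
                       int(bad.sum()), rows[:10])
    raw = raw[~bad]
    age = raw[age_column].to_numpy(dtype=float)
    score = raw[score_column].to_numpy(dtype=float)
    if inner_range is not None:
        lo, hi = inner_range
        n_clamped = int(np.sum((age < lo) | (age > hi)))
        if n_clamped:
            logger.warning("clamped %d age value(s) to [%g, %g]", n_clamped, lo, hi)
        age = np.clip(age, lo, hi)
    return NormativeDataset(age=age, score=score, source_label=str(path))


def write_normative_csv(path, age: np.ndarray, score: np.ndarray) -> None:
    pd.DataFrame({"age": age, "score": score}).to_csv(path, index=False)


def write_prior_json(path, bundle: PriorBundle) -> None:
    Path(path).write_text(json.dumps(bundle.to_dict(), indent=2))


def read_prior_json(path) -> PriorBundle:
    return PriorBundle.from_dict(json.loads(Path(path).read_text()))


def write_norm_card(path, fit) -> None:
    """Compact JSON bundle — basis specs plus posterior-mean (or mode)
    coefficients — sufficient for score-to-percentile lookup without the
    full fit directory."""
    state = fit.posterior_mean_state()
    card = {
        "model": fit.model.to_dict(),
        "beta_mu": state.beta_mu.tolist(),
        "beta_sigma": state.beta_sigma.tolist(),
    }
    Path(path).write_text(json.dumps(card, indent=2))


def read_norm_card(path):
    """Load a norm card; returns clamping ``(mu_fn, sigma_fn)`` curves."""
    from .model import ModelSpec
    from .basis import bspline_design
    from .norming import clamp_ages

    card = json.loads(Path(path).read_text())
    model = ModelSpec.from_dict(card["model"])
    beta_mu = np.asarray(card["beta_mu"], dtype=float)
    beta_sigma = np.asarray(card["beta_sigma"], dtype=float)

    def mu_fn(ages):
        a = clamp_ages(np.atleast_1d(np.asarray(ages, dtype=float)), model.inner_range)
        return bspline_design(a, model.term_mu) @ beta_mu

    def sigma_fn(ages):
        a = clamp_ages(np.atleast_1d(np.asarray(ages, dtype=float)), model.inner_range)
        return np.exp(bspline_design(a, model.term_sigma) @ beta_sigma)

    return mu_fn, sigma_fn


def write_norm_table(path, ages, levels, mu_fn, sigma_fn, band=None) -> pd.DataFrame:
    """Long-format centile table (age, level, score), optionally with
    credible-interval columns, written as CSV."""
    from .norming import centile_curve

    records = []
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    for lv in levels:
        scores = centile_curve(float(lv), ages, mu_fn, sigma_fn)
        for i, a in enumerate(ages):
            rec = {"age": a, "level": float(lv), "score": scores[i]}
            if band is not None and float(lv) in band:
                lo, mean, hi = band[float(lv)]
                rec.update({"lower": lo[i], "mean": mean[i], "upper": hi[i]})
            records.append(rec)
    df = pd.DataFrame(records)
    df.to_csv(path, index=False, float_format="%.17g")
    return df
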