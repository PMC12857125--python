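"""Synthetic survey-cohort generator with known two-level structure.

Generates individual records shaped like the study's survey extract — four
social categories, a survey year, a binary current-drinker status and, for
drinkers, a positively skewed grams-per-day (GPD) consumption value — from an
explicit generating truth:

* drinker status: logit p = beta0 + x'beta + year effect + u_j (+ offset_j),
  u_j ~ Normal(0, sigma_u^2);
* consumption: gpd = exp(Normal(eta_j, sigma_e^2)) with its own stratum
  effects, then capped at 200 g.

The default coefficients are the study's published main-effects estimates,
so a cohort generated with them is a known-truth replica of the analysed
population structure; parameter-recovery tests fit the models back and
compare.  Setting all interaction offsets to zero makes the truth purely
additive on the link scale, which is the null condition for interaction
detection experiments.

Random streams are split per purpose (allocation, stratum effects, outcomes,
missingness) so changing one rate leaves the others untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .bayes import ModelSpec, build_design_matrix
from .design import GPD_CAP, StrataDesign, default_design

#: Published main-effects coefficients, drinker-status (logistic) model.
STATUS_MAIN_EFFECTS: dict[str, float] = {
    "intercept": 1.21,
    "sex:Women": -0.55,
    "age_group:25-59": -0.38,
    "age_group:60+": -1.30,
    "race_ethnicity:Hispanic": -0.77,
    "race_ethnicity:Black": -1.06,
    "race_ethnicity:Asian": -0.22,
    "race_ethnicity:Mixed-race": -0.80,
    "race_ethnicity:AI/AN": -0.55,
    "education:Some college": 0.57,
    "education:4+ years college": 0.82,
}

#: Published main-effects coefficients, log-GPD (linear) model.
GPD_MAIN_EFFECTS: dict[str, float] = {
    "intercept": 1.62,
    "sex:Women": -0.98,
    "age_group:25-59": -0.41,
    "age_group:60+": -0.66,
    "race_ethnicity:Hispanic": -0.46,
    "race_ethnicity:Black": -0.64,
    "race_ethnicity:Asian": -0.18,
    "race_ethnicity:Mixed-race": -0.11,
    "race_ethnicity:AI/AN": -0.41,
    "education:Some college": 0.04,
    "education:4+ years college": 0.18,
}

#: Published variance components (stratum-level; null and main models).
STATUS_NULL_INTERCEPT = 0.26
STATUS_STRATUM_VAR_NULL = 0.67
STATUS_STRATUM_VAR_MAIN = 0.05
GPD_NULL_INTERCEPT = 0.57
GPD_STRATUM_VAR_NULL = 0.41
GPD_STRATUM_VAR_MAIN = 0.04
GPD_RESIDUAL_VAR = 2.98


@dataclass(frozen=True)
class GeneratingTruth:
    """Generating-side parameters for one outcome family."""

    fixed_effects: Mapping[str, float]
    stratum_sd: float
    outcome_family: str  # 'logistic' | 'lognormal'
    residual_sd: float = 0.0
    interaction_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stratum_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.outcome_family not in ("logistic", "lognormal"):
            raise ValueError(f"unknown outcome family {self.outcome_family!r}")


def default_status_truth(
    stratum_var: float = STATUS_STRATUM_VAR_MAIN,
    interaction_offsets: np.ndarray | None = None,
) -> GeneratingTruth:
    """Main-effects drinker-status truth at the published coefficients."""
    return GeneratingTruth(
        fixed_effects=dict(STATUS_MAIN_EFFECTS),
        stratum_sd=float(np.sqrt(stratum_var)),
        outcome_family="logistic",
        interaction_offsets=interaction_offsets,
    )


def default_gpd_truth(
    stratum_var: float = GPD_STRATUM_VAR_MAIN,
    residual_var: float = GPD_RESIDUAL_VAR,
    interaction_offsets: np.ndarray | None = None,
) -> GeneratingTruth:
    """Main-effects log-consumption truth at the published coefficients."""
    return GeneratingTruth(
        fixed_effects=dict(GPD_MAIN_EFFECTS),
        stratum_sd=float(np.sqrt(stratum_var)),
        outcome_family="lognormal",
        residual_sd=float(np.sqrt(residual_var)),
        interaction_offsets=interaction_offsets,
    )


def null_status_truth(
    intercept: float = STATUS_NULL_INTERCEPT,
    stratum_var: float = STATUS_STRATUM_VAR_NULL,
) -> GeneratingTruth:
    """Null (intercept-only) drinker-status truth."""
    return GeneratingTruth(
        fixed_effects={"intercept": intercept},
        stratum_sd=float(np.sqrt(stratum_var)),
        outcome_family="logistic",
    )


@dataclass(frozen=True)
class CohortConfig:
    """How to build one synthetic cohort."""

    n_individuals: int
    design: StrataDesign = field(default_factory=default_design)
    allocation: str = "equal"  # 'equal' | 'proportional' | 'skewed'
    stratum_weights: np.ndarray | None = None
    year_range: tuple[int, int] = (2000, 2018)
    truth_status: GeneratingTruth = field(default_factory=default_status_truth)
    truth_gpd: GeneratingTruth = field(default_factory=default_gpd_truth)
    missingness_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.allocation == "equal" and self.n_individuals < self.design.n_strata:
            raise ValueError("equal allocation needs n_individuals >= n_strata")
        for k, v in self.missingness_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missingness rate for {k!r} must be in [0, 1]")


def skewed_stratum_weights(design: StrataDesign, seed: int = 0) -> np.ndarray:
    """Heavily imbalanced allocation weights (log-normal across strata).

    Mimics the 4-orders-of-magnitude spread of real stratum sizes (a national
    survey's strata ranged from single digits to tens of thousands), which is
    the regime where shrinkage matters.
    """
    rng = np.random.default_rng(seed)
    w = np.exp(rng.normal(0.0, 1.8, size=design.n_strata))
    return w / w.sum()


def _allocate(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """1-based stratum index per individual."""
    J = config.design.n_strata
    n = config.n_individuals
    if config.allocation == "equal":
        base = np.repeat(np.arange(1, J + 1), n // J)
        extra = rng.choice(np.arange(1, J + 1), size=n - base.size, replace=False) \
            if n - base.size <= J else rng.integers(1, J + 1, size=n - base.size)
        return np.sort(np.concatenate([base, extra]))
    if config.allocation == "proportional":
        w = config.stratum_weights
        if w is None:
            raise ValueError("proportional allocation requires stratum_weights")
    elif config.allocation == "skewed":
        w = skewed_stratum_weights(config.design, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown allocation {config.allocation!r}")
    w = np.asarray(w, dtype=float)
    if w.size != J or (w < 0).any() or w.sum() <= 0:
        raise ValueError("stratum_weights must be non-negative with positive sum")
    return rng.choice(np.arange(1, J + 1), size=n, p=w / w.sum())


def _linear_predictor(
    records: pd.DataFrame,
    truth: GeneratingTruth,
    design: StrataDesign,
    years: Sequence[int],
) -> np.ndarray:
    spec = ModelSpec(
        family="logistic" if truth.outcome_family == "logistic" else "linear",
        terms="main",
        design=design,
        include_year=True,
        years=tuple(years),
    )
    X, cols, _ = build_design_matrix(records, spec)
    beta = np.zeros(len(cols))
    pos = {c: i for i, c in enumerate(cols)}
    for name, value in truth.fixed_effects.items():
        if name not in pos:
            raise KeyError(f"unknown design-matrix column in truth: {name!r}")
        beta[pos[name]] = value
    return X @ beta


def generate_cohort(
    config: CohortConfig, return_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Generate one cohort; byte-identical for identical config and seed.

    Returns the record table and, when ``return_truth`` is set, a dict with
    the realised stratum effects and all generating parameters (for
    parameter-recovery experiments).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_alloc, rng_u_status, rng_u_gpd, rng_out_status, rng_out_gpd, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    design = config.design
    J = design.n_strata
    stratum = _allocate(config, rng_alloc)
    years = list(range(config.year_range[0], config.year_range[1] + 1))
    year = rng_alloc.choice(years, size=config.n_individuals)

    label_rows = np.array([design.strata[j - 1].labels for j in stratum])
    records = pd.DataFrame(
        {axis.name: label_rows[:, i] for i, axis in enumerate(design.axes)}
    )
    records["survey_year"] = year.astype(int)

    # drinker status from the two-level logistic truth
    u_status = rng_u_status.normal(0.0, config.truth_status.stratum_sd, size=J)
    eta = _linear_predictor(records, config.truth_status, design, years)
    eta = eta + u_status[stratum - 1]
    if config.truth_status.interaction_offsets is not None:
        off = np.asarray(config.truth_status.interaction_offsets, dtype=float)
        if off.size != J:
            raise ValueError("interaction_offsets length must equal stratum count")
        eta = eta + off[stratum - 1]
    drinker = (rng_out_status.random(config.n_individuals) < expit(eta)).astype(int)
    records["drinker"] = drinker

    # consumption for drinkers from the log-normal truth
    u_gpd = rng_u_gpd.normal(0.0, config.truth_gpd.stratum_sd, size=J)
    eta_g = _linear_predictor(records, config.truth_gpd, design, years)
    eta_g = eta_g + u_gpd[stratum - 1]
    if config.truth_gpd.interaction_offsets is not None:
        off = np.asarray(config.truth_gpd.interaction_offsets, dtype=float)
        if off.size != J:
            raise ValueError("interaction_offsets length must equal stratum count")
        eta_g = eta_g + off[stratum - 1]
    log_gpd = rng_out_gpd.normal(eta_g, config.truth_gpd.residual_sd)
    gpd = np.minimum(np.exp(log_gpd), GPD_CAP)
    records["gpd"] = np.where(drinker == 1, gpd, np.nan)

    if config.missingness_rates:
        records = inject_missingness(
            records, config.missingness_rates, rng=rng_miss
        )

    if return_truth:
        truth = {
            "u_status": u_status.tolist(),
            "u_gpd": u_gpd.tolist(),
            "fixed_effects_status": dict(config.truth_status.fixed_effects),
            "fixed_effects_gpd": dict(config.truth_gpd.fixed_effects),
            "stratum_sd_status": config.truth_status.stratum_sd,
            "stratum_sd_gpd": config.truth_gpd.stratum_sd,
            "residual_sd_gpd": config.truth_gpd.residual_sd,
            "seed": config.seed,
        }
        return records, truth
    return records


def inject_missingness(
    records: pd.DataFrame,
    rates: Mapping[str, float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Blank each targeted field independently with its rate."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out = records.copy()
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col!r} must be in [0, 1]")
        if col not in out.columns or rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if out[col].dtype == object:
            out.loc[mask, col] = None
        else:
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
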