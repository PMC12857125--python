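"""Two-level Bayesian random-intercept models fitted by Gibbs sampling.

Individuals (level 1) are nested in intersectional strata (level 2).  Two
families are supported:

* ``logistic`` — binary outcome (current-drinker status); the logistic
  likelihood is made conditionally conjugate by Polya-Gamma data
  augmentation, so every full conditional is Gaussian or inverse-gamma.
* ``linear`` — Gaussian outcome on the log scale (log grams/day for
  drinkers); the standard conjugate Gibbs sampler.

Priors are diffuse: Normal(0, 1e6) on every fixed effect and
InverseGamma(0.001, 0.001) on each variance component.  The logistic family
has no residual variance parameter; on the latent-response scale its
individual-level variance is the constant pi^2/3 ~= 3.29.

Because all covariates are functions of the stratum and the survey year, the
likelihood is aggregated over (stratum, year) cells before sampling, which
makes a fit on hundreds of thousands of records cost the same as one on a
few thousand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd

from .design import StrataDesign, assign_strata, log_transform_outcome

#: Latent-response individual-level variance of the logistic model.
LOGISTIC_RESIDUAL_VARIANCE = np.pi**2 / 3.0


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: family, fixed-effect structure, design and years.

    ``terms='null'`` fits intercept (+ optional year dummies) only;
    ``terms='main'`` adds one contrast column per non-reference level of
    each axis.  ``reference_year`` is the year absorbed into the intercept
    (defaults to the earliest year in the data).
    """

    family: str  # 'logistic' | 'linear'
    terms: str  # 'null' | 'main'
    design: StrataDesign
    include_year: bool = True
    years: tuple[int, ...] | None = None
    reference_year: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "linear"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.terms not in ("null", "main"):
            raise ValueError(f"unknown terms {self.terms!r}")


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings and priors for the Gibbs samplers."""

    chains: int = 2
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 1
    seed: int = 0
    prior_variance_fixed: float = 1e6
    variance_prior_shape: float = 0.001
    variance_prior_rate: float = 0.001
    rhat_threshold: float = 1.05
    ess_threshold: float = 200.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws for one fitted model.

    ``beta`` has one column per fixed-effect term (named in ``beta_names``),
    ``u`` one column per stratum (all strata of the design, in index order),
    ``sigma_u2`` the stratum-level variance, ``sigma_e2`` the individual-level
    variance (the constant pi^2/3 for the logistic family).  Draws from all
    chains are concatenated; ``n_chains``/``n_draws_per_chain`` recover the
    chain structure.
    """

    family: str
    beta: np.ndarray
    beta_names: list[str]
    u: np.ndarray
    sigma_u2: np.ndarray
    sigma_e2: np.ndarray
    n_chains: int
    n_draws_per_chain: int
    stratum_counts: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    #: year absorbed into the intercept (None when the fit had no year terms)
    reference_year: int | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def beta_mean(self) -> pd.Series:
        return pd.Series(self.beta.mean(axis=0), index=self.beta_names)

    def summary(self) -> pd.DataFrame:
        """Posterior mean and 95% interval for every scalar parameter."""
        names = list(self.beta_names) + ["sigma_u2", "sigma_e2"]
        cols = [self.beta[:, i] for i in range(self.beta.shape[1])]
        cols += [self.sigma_u2, self.sigma_e2]
        rows = [
            (n, c.mean(), np.percentile(c, 2.5), np.percentile(c, 97.5))
            for n, c in zip(names, cols)
        ]
        return pd.DataFrame(rows, columns=["term", "mean", "lo", "hi"]).set_index("term")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def design_columns(spec: ModelSpec, years: Sequence[int]) -> list[str]:
    """Fixed-effect column names for a spec (intercept first)."""
    cols = ["intercept"]
    if spec.terms == "main":
        for axis in spec.design.axes:
            cols += [
                f"{axis.name}:{lv}" for lv in axis.levels if lv != axis.reference_level
            ]
    if spec.include_year:
        ref = spec.reference_year if spec.reference_year is not None else min(years)
        cols += [f"year:{y}" for y in sorted(years) if y != ref]
    return cols


def build_design_matrix(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Indicator design matrix, column names and 1-based stratum indices.

    Reference levels (and the reference year) produce no column, so a record
    at all reference levels in the reference year is a row of zeros except
    for the intercept.
    """
    if spec.include_year:
        if spec.years is not None:
            years: Sequence[int] = spec.years
        else:
            years = sorted(pd.to_numeric(records["survey_year"]).unique().astype(int))
    else:
        years = []
    cols = design_columns(spec, years)
    n = len(records)
    X = np.zeros((n, len(cols)))
    X[:, 0] = 1.0
    pos = {c: i for i, c in enumerate(cols)}
    if spec.terms == "main":
        for axis in spec.design.axes:
            vals = records[axis.name].to_numpy()
            for lv in axis.levels:
                if lv == axis.reference_level:
                    continue
                X[vals == lv, pos[f"{axis.name}:{lv}"]] = 1.0
    if spec.include_year:
        yr = pd.to_numeric(records["survey_year"]).to_numpy().astype(int)
        for y in years:
            key = f"year:{y}"
            if key in pos:
                X[yr == y, pos[key]] = 1.0
    stratum = assign_strata(records, spec.design).to_numpy()
    return X, cols, stratum


# ---------------------------------------------------------------------------
# Polya-Gamma sampler
# ---------------------------------------------------------------------------

def sample_polya_gamma(
    b: np.ndarray, z: np.ndarray, rng: np.random.Generator, trunc: int = 200
) -> np.ndarray:
    """Draw PG(b, z) variates via the weighted sum-of-gammas representation.

    PG(b, z) = (1 / 2 pi^2) * sum_k  g_k / ((k - 1/2)^2 + z^2 / (4 pi^2)),
    g_k ~ Gamma(b, 1).  The series is truncated at ``trunc`` terms and the
    (deterministic) mean of the discarded tail is added back, which keeps the
    relative bias far below Monte-Carlo noise for the shape parameters that
    arise from aggregated cells.  Valid for any real b > 0.
    """
    b = np.asarray(b, dtype=float)
    z = np.asarray(z, dtype=float)
    b, z = np.broadcast_arrays(b, z)
    m = b.size
    c = np.abs(z).ravel() / (2.0 * np.pi)
    k = np.arange(1, trunc + 1) - 0.5  # (trunc,)
    denom = k[:, None] ** 2 + c[None, :] ** 2  # (trunc, m)
    g = rng.gamma(shape=np.broadcast_to(b.ravel(), (trunc, m)))
    x = (g / denom).sum(axis=0) / (2.0 * np.pi**2)
    # tail mean: integral approximation of sum_{k>trunc} 1/((k-1/2)^2 + c^2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = np.where(
            c > 0, (np.pi / 2 - np.arctan(trunc / np.maximum(c, 1e-300))) / c,
            1.0 / trunc,
        )
    x += b.ravel() * tail / (2.0 * np.pi**2)
    return x.reshape(b.shape)


def polya_gamma_mean(b, z):
    """E[PG(b, z)] = b/(2z) * tanh(z/2), with the z->0 limit b/4."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(z) < 1e-8, b / 4.0, b / (2.0 * z) * np.tanh(z / 2.0))
    return out


# ---------------------------------------------------------------------------
# Fitters
# ---------------------------------------------------------------------------

def _aggregate_cells(X: np.ndarray, stratum: np.ndarray, year_key: np.ndarray):
    """Collapse identical design rows into (stratum, year) cells."""
    key = stratum.astype(np.int64) * 1_000_000 + year_key.astype(np.int64)
    uniq, inv = np.unique(key, return_inverse=True)
    m = uniq.size
    first = np.full(m, -1, dtype=int)
    first[inv[::-1]] = np.arange(len(key) - 1, -1, -1)
    Xc = X[first]
    jc = stratum[first] - 1  # 0-based
    return inv, Xc, jc


def _draw_mvn(A: np.ndarray, bvec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample from N(A^-1 b, A^-1) via Cholesky of the precision A."""
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, bvec)
    return mean + np.linalg.solve(L.T, rng.standard_normal(A.shape[0]))


def _chain_seeds(seed: int, chains: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(chains)]


def _stratum_level_columns(spec: ModelSpec, cols: list[str]) -> np.ndarray:
    """Stratum-level design matrix Xs (J x p): covariate values that are
    constant within a stratum (intercept and axis contrasts); year columns,
    which vary within strata, are zero here and excluded from interweaving.
    """
    J = spec.design.n_strata
    pos = {c: i for i, c in enumerate(cols)}
    Xs = np.zeros((J, len(cols)))
    Xs[:, 0] = 1.0
    for jrow, stratum in enumerate(spec.design.strata):
        for axis, lv in zip(spec.design.axes, stratum.labels):
            key = f"{axis.name}:{lv}"
            if key in pos:
                Xs[jrow, pos[key]] = 1.0
    return Xs


def _interweave(beta, u, Xs, level_cols, sigma_u2, prior_var, rng):
    """Translation (interweaving) update along likelihood-invariant directions.

    For a stratum-level column c, the map ``u_j -> u_j - delta * Xs[j, c]``,
    ``beta_c -> beta_c + delta`` leaves the likelihood unchanged, so the
    conditional of delta comes from the priors alone and is Gaussian.
    Sampling it exactly breaks the random-walk coupling between the fixed
    effects and the stratum intercepts that otherwise cripples mixing.
    """
    for c in level_cols:
        x = Xs[:, c]
        prec = (x @ x) / sigma_u2 + 1.0 / prior_var
        mean = ((x @ u) / sigma_u2 - beta[c] / prior_var) / prec
        delta = mean + rng.standard_normal() / np.sqrt(prec)
        u -= delta * x
        beta[c] += delta
    return beta, u


def fit_model(records: pd.DataFrame, spec: ModelSpec, mcmc: McmcConfig) -> PosteriorDraws:
    """Fit a two-level random-intercept model and return posterior draws.

    Logistic family expects a 0/1 ``drinker`` column; linear family expects a
    positive ``gpd`` column (log-transformed internally) or a ready-made
    ``log_gpd`` column.  Raises if fewer than two strata are populated (the
    stratum variance is then unidentified).  Convergence is assessed with
    split-chain R-hat and bulk effective sample size; a failing fit is
    returned with ``converged=False`` and a warning, never silently.
    """
    X, cols, stratum = build_design_matrix(records, spec)
    J = spec.design.n_strata
    counts = np.bincount(stratum - 1, minlength=J)
    if (counts > 0).sum() < 2:
        raise ValueError(
            "stratum variance is unidentified with fewer than two populated strata"
        )
    if spec.include_year:
        year_key = pd.to_numeric(records["survey_year"]).to_numpy().astype(int)
    else:
        year_key = np.zeros(len(records), dtype=int)
    inv, Xc, jc = _aggregate_cells(X, stratum, year_key)
    m = Xc.shape[0]

    if spec.family == "logistic":
        y = pd.to_numeric(records["drinker"]).to_numpy().astype(float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("logistic family requires a 0/1 drinker outcome")
        n_c = np.bincount(inv, minlength=m).astype(float)
        k_c = np.bincount(inv, weights=y, minlength=m)
        sampler = _logistic_chain
        stats = (n_c, k_c)
    else:
        if "log_gpd" in records.columns:
            ylog = pd.to_numeric(records["log_gpd"]).to_numpy().astype(float)
        else:
            ylog = log_transform_outcome(pd.to_numeric(records["gpd"]).to_numpy())
        if np.isnan(ylog).any():
            raise ValueError(
                "linear family requires a positive consumption outcome for "
                "every record; filter to drinkers with valid gpd first"
            )
        n_c = np.bincount(inv, minlength=m).astype(float)
        sy = np.bincount(inv, weights=ylog, minlength=m)
        syy = np.bincount(inv, weights=ylog**2, minlength=m)
        sampler = _linear_chain
        stats = (n_c, sy, syy)

    Xs = _stratum_level_columns(spec, cols)
    level_cols = [i for i, c in enumerate(cols) if not c.startswith("year:")]
    kept = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
    p = len(cols)
    beta_ch = np.empty((mcmc.chains, kept, p))
    u_ch = np.empty((mcmc.chains, kept, J))
    su2_ch = np.empty((mcmc.chains, kept))
    se2_ch = np.empty((mcmc.chains, kept))
    for ci, rng in enumerate(_chain_seeds(mcmc.seed, mcmc.chains)):
        beta_ch[ci], u_ch[ci], su2_ch[ci], se2_ch[ci] = sampler(
            Xc, jc, stats, J, mcmc, kept, rng, Xs, level_cols
        )

    if spec.include_year:
        years = sorted(pd.to_numeric(records["survey_year"]).unique().astype(int)) \
            if spec.years is None else sorted(spec.years)
        fit_ref_year = (
            spec.reference_year if spec.reference_year is not None else int(min(years))
        )
    else:
        fit_ref_year = None
    diagnostics = _diagnostics(beta_ch, su2_ch, cols, mcmc)
    fit = PosteriorDraws(
        family=spec.family,
        beta=beta_ch.reshape(-1, p),
        beta_names=cols,
        u=u_ch.reshape(-1, J),
        sigma_u2=su2_ch.ravel(),
        sigma_e2=se2_ch.ravel(),
        n_chains=mcmc.chains,
        n_draws_per_chain=kept,
        stratum_counts=counts,
        diagnostics=diagnostics,
        converged=diagnostics["converged"],
        reference_year=fit_ref_year,
    )
    if not fit.converged:
        warnings.warn(
            "MCMC convergence diagnostics exceeded thresholds "
            f"(max R-hat {diagnostics['max_rhat']:.3f}, "
            f"min ESS {diagnostics['min_ess']:.0f}); "
            "treat this fit with caution",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit


def _logistic_chain(Xc, jc, stats, J, mcmc, kept, rng, Xs, level_cols):
    n_c, k_c = stats
    kappa = k_c - n_c / 2.0
    p = Xc.shape[1]
    prior_prec = np.eye(p) / mcmc.prior_variance_fixed
    a0, b0 = mcmc.variance_prior_shape, mcmc.variance_prior_rate
    beta = np.zeros(p)
    u = np.zeros(J)
    sigma_u2 = 1.0
    out_b = np.empty((kept, p))
    out_u = np.empty((kept, J))
    out_s = np.empty(kept)
    idx = 0
    for it in range(mcmc.iterations):
        xb = Xc @ beta
        omega = sample_polya_gamma(n_c, xb + u[jc], rng)
        # stratum effects
        prec_j = np.bincount(jc, weights=omega, minlength=J) + 1.0 / sigma_u2
        mean_j = np.bincount(jc, weights=kappa - omega * xb, minlength=J) / prec_j
        u = mean_j + rng.standard_normal(J) / np.sqrt(prec_j)
        # fixed effects
        A = Xc.T @ (omega[:, None] * Xc) + prior_prec
        bvec = Xc.T @ (kappa - omega * u[jc])
        beta = _draw_mvn(A, bvec, rng)
        beta, u = _interweave(
            beta, u, Xs, level_cols, sigma_u2, mcmc.prior_variance_fixed, rng
        )
        # stratum variance
        sigma_u2 = b0 + 0.5 * u @ u
        sigma_u2 /= rng.gamma(a0 + J / 2.0)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            out_b[idx] = beta
            out_u[idx] = u
            out_s[idx] = sigma_u2
            idx += 1
    se2 = np.full(kept, LOGISTIC_RESIDUAL_VARIANCE)
    return out_b, out_u, out_s, se2


def _linear_chain(Xc, jc, stats, J, mcmc, kept, rng, Xs, level_cols):
    n_c, sy, syy = stats
    N = n_c.sum()
    p = Xc.shape[1]
    prior_prec = np.eye(p) / mcmc.prior_variance_fixed
    a0, b0 = mcmc.variance_prior_shape, mcmc.variance_prior_rate
    beta = np.zeros(p)
    beta[0] = sy.sum() / N  # start at the grand mean
    u = np.zeros(J)
    sigma_u2, sigma_e2 = 1.0, 1.0
    n_j = np.bincount(jc, weights=n_c, minlength=J)
    out_b = np.empty((kept, p))
    out_u = np.empty((kept, J))
    out_su = np.empty(kept)
    out_se = np.empty(kept)
    idx = 0
    for it in range(mcmc.iterations):
        xb = Xc @ beta
        # stratum effects
        prec_j = n_j / sigma_e2 + 1.0 / sigma_u2
        mean_j = np.bincount(jc, weights=sy - n_c * xb, minlength=J) / sigma_e2 / prec_j
        u = mean_j + rng.standard_normal(J) / np.sqrt(prec_j)
        # fixed effects
        A = Xc.T @ (n_c[:, None] * Xc) / sigma_e2 + prior_prec
        bvec = Xc.T @ (sy - n_c * u[jc]) / sigma_e2
        beta = _draw_mvn(A, bvec, rng)
        beta, u = _interweave(
            beta, u, Xs, level_cols, sigma_u2, mcmc.prior_variance_fixed, rng
        )
        # residual variance from cell sufficient statistics
        mu = Xc @ beta + u[jc]
        ssr = float((syy - 2.0 * mu * sy + n_c * mu**2).sum())
        sigma_e2 = (b0 + 0.5 * ssr) / rng.gamma(a0 + N / 2.0)
        # stratum variance
        sigma_u2 = (b0 + 0.5 * u @ u) / rng.gamma(a0 + J / 2.0)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            out_b[idx] = beta
            out_u[idx] = u
            out_su[idx] = sigma_u2
            out_se[idx] = sigma_e2
            idx += 1
    return out_b, out_u, out_su, out_se


def _diagnostics(beta_ch, su2_ch, cols, mcmc) -> dict:
    """Split-chain R-hat and bulk ESS for fixed effects and sigma_u2."""
    def shape_for_az(a):
        # arviz needs >= 2 chains for R-hat; split a single chain in half
        if a.shape[0] == 1:
            half = a.shape[1] // 2
            a = np.stack([a[0, :half], a[0, half : 2 * half]])
        return a

    data = {"sigma_u2": shape_for_az(np.log(su2_ch))}
    for i, c in enumerate(cols):
        data[c] = shape_for_az(beta_ch[:, :, i])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = {k: float(az.rhat(v)) for k, v in data.items()}
        ess = {k: float(az.ess(v)) for k, v in data.items()}
    max_rhat = max(rhat.values())
    min_ess = min(ess.values())
    return {
        "rhat": rhat,
        "ess": ess,
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "converged": bool(
            max_rhat <= mcmc.rhat_threshold and min_ess >= mcmc.ess_threshold
        ),
    }


# ---------------------------------------------------------------------------
# Closed-form shrinkage oracle
# ---------------------------------------------------------------------------

def blup_oracle(
    y: np.ndarray,
    stratum: np.ndarray,
    n_strata: int,
    sigma_u2: float,
    sigma_e2: float,
) -> np.ndarray:
    """Closed-form shrunken stratum effects for the linear null model.

    With known variances, the best predictor of the stratum effect is
    ``u_j = lambda_j * (ybar_j - mu)`` with shrinkage factor
    ``lambda_j = sigma_u2 / (sigma_u2 + sigma_e2 / n_j)`` and ``mu`` the
    precision-weighted grand mean of the stratum means.  Empty strata shrink
    fully to zero.  Serves as an independent check on the Gibbs sampler.
    """
    stratum = np.asarray(stratum, dtype=int)
    y = np.asarray(y, dtype=float)
    n_j = np.bincount(stratum - 1, minlength=n_strata).astype(float)
    sum_j = np.bincount(stratum - 1, weights=y, minlength=n_strata)
    with np.errstate(divide="ignore", invalid="ignore"):
        ybar = np.where(n_j > 0, sum_j / np.maximum(n_j, 1), 0.0)
        w = np.where(n_j > 0, 1.0 / (sigma_u2 + sigma_e2 / np.maximum(n_j, 1e-300)), 0.0)
    mu = float((w * ybar).sum() / w.sum())
    lam = np.where(n_j > 0, sigma_u2 / (sigma_u2 + sigma_e2 / np.maximum(n_j, 1e-300)), 0.0)
    return lam * (ybar - mu)
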