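"""Presentation surfaces: ranked strata tables, caterpillar plots and the
between-outcome correlation with 2-SD outlier flagging.

These operations are pure I/O over prediction tables produced by
:mod:`maihda.core`; they recompute no model quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

RANK_MODES = (
    "highest",
    "lowest",
    "largest-positive-interaction",
    "largest-negative-interaction",
)


def rank_strata(
    predictions: pd.DataFrame,
    k: int,
    mode: str,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Top-k strata under one ranking mode.

    ``highest``/``lowest`` rank by the total estimate; the interaction modes
    rank by the interaction estimate and, by default, consider only strata
    whose interaction interval excludes zero (set ``significant_only=False``
    to include all).  Ties break by stratum index.  Adds a 1-based ``rank``
    column.
    """
    if mode not in RANK_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if k < 0:
        raise ValueError("k must be >= 0")
    df = predictions.copy()
    if mode == "highest":
        df = df.sort_values(["total", "stratum"], ascending=[False, True])
    elif mode == "lowest":
        df = df.sort_values(["total", "stratum"], ascending=[True, True])
    else:
        if significant_only:
            df = df[df["significant"]]
        asc = mode == "largest-negative-interaction"
        df = df.sort_values(["interaction", "stratum"], ascending=[asc, True])
    out = df.head(k).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


@dataclass
class CorrelationReport:
    """OLS relationship between two per-stratum predicted outcomes."""

    r: float
    slope: float
    intercept: float
    residual_sd: float
    residuals: np.ndarray
    outliers: pd.DataFrame  # strata with |residual| > 2 * residual_sd
    x: np.ndarray
    y: np.ndarray
    labels: list[str]
    residual_sd_ddof: int = 0  # population formula by default


def correlate_outcomes(
    pred_status: pd.DataFrame,
    pred_gpd: pd.DataFrame,
    ddof: int = 0,
) -> CorrelationReport:
    """Correlate per-stratum drinker percentages with mean consumption.

    Fits consumption on the drinker percentage by least squares and flags
    strata whose residual exceeds twice the residual standard deviation
    (population formula by default; ``ddof=2`` for the n-2 convention).
    Inputs are aligned on the ``stratum`` column.
    """
    merged = pred_status.merge(pred_gpd, on="stratum", suffixes=("_status", "_gpd"))
    if len(merged) < 3:
        raise ValueError("need at least 3 strata to correlate outcomes")
    x = merged["total_status"].to_numpy(dtype=float)
    y = merged["total_gpd"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor outcome")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sd = float(np.sqrt(np.sum(resid**2) / (len(resid) - ddof)))
    flag = np.abs(resid) > 2.0 * sd
    labels = merged[
        "label_status" if "label_status" in merged else "label"
    ].tolist()
    outliers = pd.DataFrame(
        {
            "stratum": merged["stratum"][flag],
            "label": np.asarray(labels, dtype=object)[flag],
            "x": x[flag],
            "y": y[flag],
            "residual": resid[flag],
        }
    ).reset_index(drop=True)
    return CorrelationReport(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=sd,
        residuals=resid,
        outliers=outliers,
        x=x,
        y=y,
        labels=labels,
        residual_sd_ddof=ddof,
    )


def caterpillar_plot(
    predictions: pd.DataFrame,
    path,
    group_axis: str = "sex",
    title: str | None = None,
) -> None:
    """Per-stratum total vs additive-only estimates with 95% CIs.

    Strata are ordered by their additive estimate; points are coloured by
    the first letter of the canonical label (the sex short code) so the two
    sex series are visually separated, with lighter markers for the
    additive-only series.
    """
    fig, ax = plt.subplots(figsize=(12, 5))
    if len(predictions):
        df = predictions.sort_values(["additive", "stratum"]).reset_index(drop=True)
        groups = df["label"].str.split(",").str[0].str.strip()
        palette = {g: c for g, c in zip(sorted(groups.unique()),
                                        plt.rcParams["axes.prop_cycle"].by_key()["color"])}
        xs = np.arange(len(df))
        for g in sorted(groups.unique()):
            sel = (groups == g).to_numpy()
            ax.errorbar(
                xs[sel], df["additive"][sel],
                yerr=[df["additive"][sel] - df["additive_lo"][sel],
                      df["additive_hi"][sel] - df["additive"][sel]],
                fmt="o", ms=3, alpha=0.4, color=palette[g],
                label=f"{g} (additive only)",
            )
            ax.errorbar(
                xs[sel], df["total"][sel],
                yerr=[df["total"][sel] - df["total_lo"][sel],
                      df["total_hi"][sel] - df["total"][sel]],
                fmt="s", ms=3, color=palette[g], label=f"{g} (total)",
            )
        ax.legend(fontsize=8)
        ax.set_xlabel("stratum (ordered by additive estimate)")
    ax.set_ylabel("predicted outcome")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def scatter_plot(report: CorrelationReport, path, title: str | None = None) -> None:
    """Outcome-vs-outcome scatter with OLS line and highlighted outliers."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(report.x, report.y, s=14, color="steelblue", zorder=2)
    if len(report.outliers):
        ax.scatter(
            report.outliers["x"], report.outliers["y"],
            s=30, color="red", zorder=3, label="outliers (>2 SD)",
        )
        ax.legend(fontsize=8)
    xs = np.linspace(report.x.min(), report.x.max(), 50)
    ax.plot(xs, report.intercept + report.slope * xs, color="black", lw=1, zorder=1)
    ax.set_xlabel("predicted % current drinkers")
    ax.set_ylabel("predicted mean grams/day")
    ax.annotate(f"r = {report.r:.2f}", xy=(0.05, 0.92), xycoords="axes fraction")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
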