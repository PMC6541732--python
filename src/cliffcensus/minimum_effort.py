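"""Minimum sampling-effort analysis for grid-cell censuses.

The question this module answers: how small a random fraction of the
grid cells can be censused while the estimated population total stays
accurate and its confidence interval acceptably tight?

The procedure mirrors the full-census workflow. The best-fitting count
family is chosen once on the complete census; then, for each sampling
fraction (by default 90% down to 5% in 5% steps) and each of 25 random
replicates, a simple random sample of cells is drawn WITHOUT replacement,
the family is refitted to the sampled counts, and the population total is
estimated by expansion:

    T_hat = n_total_cells x fitted_mean x CF

(the fitted mean equals the sample mean for all three supported families,
so T_hat is the classical expansion estimator). Two 95% confidence
intervals accompany every estimate:

* ``ML`` -- a log-normal (delta-method) interval: the standard error of
  log T_hat is SE(mean)/mean with SE(mean) from the fitted family's
  information at the MLE, and the interval is
  T_hat x exp(-/+ z_{1-alpha/2} s).
* ``SB`` ("simple bootstrap") -- the sampled cells are resampled with
  replacement B times (default 10,000), the total is re-estimated on
  each resample, and the interval is the (alpha/2, 1-alpha/2) percentile
  band of the B re-estimates.

Aggregating the replicates per fraction gives the effort summary: mean
estimate, CI envelope, mean CI width and coverage of the full-census
total per method. The recommended method is the one with the smaller
mean CI width at the fraction of interest; the recommended (minimum)
fraction is the smallest one whose mean relative CI half-width stays
within tolerance while coverage stays above the floor.

Estimates treat the cell counts as i.i.d. draws from the fitted count
model (a superpopulation view, consistent with the distribution-fitting
step); no finite-population correction is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .correction_factor import CorrectionFactor
from .distribution_fit import (
    FittedDistribution,
    distribution_mean,
    distribution_variance,
    fit_distribution,
)
from .errors import InsufficientDataError, ValidationError
from .grid_io import GridCensus

__all__ = [
    "SubsampleDesign",
    "EffortRecord",
    "EffortSummary",
    "draw_subsample",
    "estimate_total",
    "ci_maximum_likelihood",
    "ci_simple_bootstrap",
    "run_effort_analysis",
    "summarize_effort",
    "records_to_frame",
    "render_effort_plots",
]

DEFAULT_FRACTIONS: Tuple[float, ...] = tuple(np.round(np.arange(0.90, 0.049, -0.05), 2))


@dataclass(frozen=True)
class SubsampleDesign:
    """Parameters of the subsampling experiment.

    Defaults follow the reference protocol: fractions 0.90 down to 0.05
    in steps of 0.05, 25 replicates per fraction, 10,000 bootstrap
    resamples, alpha 0.05.
    """

    fractions: Tuple[float, ...] = DEFAULT_FRACTIONS
    repetitions: int = 25
    bootstrap_B: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        if not fr:
            raise ValidationError("at least one sampling fraction required")
        if any(not (0 < f <= 1) for f in fr):
            raise ValidationError("sampling fractions must lie in (0, 1]")
        if any(f2 >= f1 for f1, f2 in zip(fr, fr[1:])):
            raise ValidationError("fractions must be strictly decreasing")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if self.bootstrap_B < 100:
            raise ValidationError("bootstrap_B must be >= 100")
        if not (0 < self.alpha < 0.5):
            raise ValidationError("alpha must lie in (0, 0.5)")
        object.__setattr__(self, "fractions", fr)


@dataclass(frozen=True)
class EffortRecord:
    """One subsample replicate: the estimate and both intervals."""

    fraction: float
    replicate: int
    n_cells_sampled: int
    estimated_total: float
    ci_ml: Tuple[float, float]
    ci_sb: Tuple[float, float]


def records_to_frame(records: Sequence[EffortRecord]) -> pd.DataFrame:
    """Flatten records to the canonical CSV layout."""
    return pd.DataFrame(
        {
            "fraction": [r.fraction for r in records],
            "replicate": [r.replicate for r in records],
            "n_cells": [r.n_cells_sampled for r in records],
            "estimate": [r.estimated_total for r in records],
            "ml_low": [r.ci_ml[0] for r in records],
            "ml_high": [r.ci_ml[1] for r in records],
            "sb_low": [r.ci_sb[0] for r in records],
            "sb_high": [r.ci_sb[1] for r in records],
        }
    )


@dataclass(frozen=True)
class EffortSummary:
    """Per-fraction aggregation over replicates plus the recommendation."""

    table: pd.DataFrame
    census_total: float
    alpha: float
    recommended_method: str
    recommended_fraction: Optional[float]
    fraction_of_interest: float

    def to_dict(self) -> dict:
        return {
            "census_total": self.census_total,
            "alpha": self.alpha,
            "recommended_method": self.recommended_method,
            "recommended_fraction": self.recommended_fraction,
            "fraction_of_interest": self.fraction_of_interest,
            "per_fraction": self.table.to_dict(orient="records"),
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# -- sampling and estimation ---------------------------------------------------


def subsample_size(fraction: float, n_included: int) -> int:
    """Round-half-up of fraction x n, floored at one cell."""
    return max(1, int(np.floor(fraction * n_included + 0.5)))


def draw_subsample(
    census: GridCensus, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Simple random sample of included cells, without replacement.

    Cells are physical plots on the wall, so each can be censused at most
    once per subsample. Returns the sampled visual-unit counts.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    counts = census.included_counts
    if counts.size == 0:
        raise InsufficientDataError("census has no included cells")
    k = subsample_size(fraction, counts.size)
    idx = rng.choice(counts.size, size=k, replace=False)
    return counts[idx]


def estimate_total(
    sampled_counts: Sequence[int],
    n_total_cells: int,
    family: str = "poisson",
    cf: Optional[CorrectionFactor] = None,
) -> float:
    """Expansion estimate of the population total from a subsample.

    Fits the family to the sampled counts by MLE and expands the fitted
    mean to all cells, times the CF mean if one is supplied. Because the
    MLE mean equals the sample mean for every supported family, this is
    n_total_cells x sample_mean x CF -- a property downstream code and
    tests rely on. An all-zero subsample gives estimate 0 with a warning
    (the geometric/negative-binomial fits sit on their boundary there).
    """
    x = np.asarray(sampled_counts)
    if x.size == 0:
        raise InsufficientDataError("empty subsample")
    factor = cf.mean_ratio if cf is not None else 1.0
    if x.max() == 0:
        warnings.warn("all-zero subsample: estimated total is 0", stacklevel=2)
        return 0.0
    if x.size == 1:
        return n_total_cells * float(x[0]) * factor
    fit = fit_distribution(x, family)
    return n_total_cells * distribution_mean(fit) * factor


def ci_maximum_likelihood(
    sampled_counts: Sequence[int],
    n_total_cells: int,
    family: str = "poisson",
    alpha: float = 0.05,
    cf: Optional[CorrectionFactor] = None,
) -> Tuple[float, float]:
    """Log-normal (delta-method) confidence interval for the total.

    The total is T_hat = N x mean_hat x CF, so log T_hat has standard
    error s = SE(mean_hat)/mean_hat, with SE(mean_hat) = sqrt(V_hat/n)
    and V_hat the fitted family's variance at the MLE (the inverse
    information for the mean parameter). The interval is
    (T_hat e^{-zs}, T_hat e^{+zs}); it is asymmetric around T_hat with
    high/T_hat = T_hat/low. A degenerate sample (all counts identical)
    has no estimable spread and yields a zero-width interval at the
    estimate; an all-zero sample yields (0, 0) with a warning.
    """
    x = np.asarray(sampled_counts)
    t_hat = estimate_total(x, n_total_cells, family, cf)
    if t_hat == 0:
        warnings.warn("zero estimate: ML interval undefined on the log scale", stacklevel=2)
        return (0.0, 0.0)
    if x.size < 2 or np.ptp(x) == 0:
        return (t_hat, t_hat)
    fit = fit_distribution(x, family)
    mean = distribution_mean(fit)
    se_mean = np.sqrt(distribution_variance(fit) / x.size)
    s = se_mean / mean
    z = stats.norm.ppf(1 - alpha / 2)
    return (t_hat * np.exp(-z * s), t_hat * np.exp(z * s))


def ci_simple_bootstrap(
    sampled_counts: Sequence[int],
    n_total_cells: int,
    family: str = "poisson",
    alpha: float = 0.05,
    B: int = 10_000,
    cf: Optional[CorrectionFactor] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Percentile bootstrap confidence interval for the total.

    The sampled cells are resampled with replacement B times and the
    total re-estimated on each resample; the interval is the
    (alpha/2, 1-alpha/2) percentile band. The re-estimation uses the
    identity estimate = N x resample_mean x CF, which is exactly what
    refitting any of the three families would give (MLE mean = sample
    mean), so the resampling loop is vectorised.
    """
    if B < 100:
        raise ValidationError("bootstrap_B must be >= 100")
    x = np.asarray(sampled_counts, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty subsample")
    if rng is None:
        rng = np.random.default_rng()
    factor = cf.mean_ratio if cf is not None else 1.0
    idx = rng.integers(0, x.size, size=(B, x.size))
    boot_totals = n_total_cells * x[idx].mean(axis=1) * factor
    low, high = np.quantile(boot_totals, [alpha / 2, 1 - alpha / 2])
    return (float(low), float(high))


# -- the experiment ------------------------------------------------------------


def _replicate_rng(seed: int, fraction_index: int, replicate: int) -> np.random.Generator:
    """Deterministic per-(fraction, replicate) stream, independent of run order."""
    return np.random.default_rng([seed, fraction_index, replicate])


def run_effort_analysis(
    census: GridCensus,
    design: SubsampleDesign = SubsampleDesign(),
    family: str = "poisson",
    cf: Optional[CorrectionFactor] = None,
) -> List[EffortRecord]:
    """Run the full subsampling experiment: every fraction x replicate.

    ``family`` should be the best-fitting family chosen on the full
    census (see :func:`cliffcensus.distribution_fit.compare_models`); it
    is refitted to every subsample. Returns |fractions| x repetitions
    records, fully reproducible from ``design.seed`` (each replicate has
    its own derived random stream, so results do not depend on execution
    order).
    """
    n_total = census.n_included
    if n_total == 0:
        raise InsufficientDataError("census has no included cells")
    records: List[EffortRecord] = []
    for fi, fraction in enumerate(design.fractions):
        for rep in range(design.repetitions):
            rng = _replicate_rng(design.seed, fi, rep)
            sample = draw_subsample(census, fraction, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = estimate_total(sample, n_total, family, cf)
                ml = ci_maximum_likelihood(sample, n_total, family, design.alpha, cf)
                sb = ci_simple_bootstrap(
                    sample, n_total, family, design.alpha, design.bootstrap_B, cf, rng
                )
            records.append(
                EffortRecord(
                    fraction=fraction,
                    replicate=rep,
                    n_cells_sampled=sample.size,
                    estimated_total=est,
                    ci_ml=ml,
                    ci_sb=sb,
                )
            )
    return records


def summarize_effort(
    records: Sequence[EffortRecord],
    census_total: float,
    alpha: float = 0.05,
    fraction_of_interest: Optional[float] = None,
    rel_halfwidth_tol: float = 0.15,
    coverage_floor: float = 0.90,
) -> EffortSummary:
    """Aggregate replicates per fraction and recommend method and effort.

    Per fraction and method: mean estimate, mean/max/min CI bounds, mean
    CI width, and coverage (share of replicates whose interval contains
    ``census_total``). The recommended method is the one with the smaller
    mean CI width at ``fraction_of_interest`` (default: the fraction
    nearest 0.55, a typical mid-range effort to inspect in detail). The
    recommended minimum fraction is the smallest fraction whose mean
    relative CI half-width (half-width / estimate, recommended method)
    is <= ``rel_halfwidth_tol`` and whose coverage >= ``coverage_floor``;
    the final call on real data remains a judgement on the plots.
    """
    if not records:
        raise ValidationError("no records to summarise")
    df = records_to_frame(records)
    rows = []
    for fraction, grp in df.groupby("fraction", sort=True):
        row = {
            "fraction": float(fraction),
            "n_replicates": len(grp),
            "mean_estimate": grp["estimate"].mean(),
            "min_estimate": grp["estimate"].min(),
            "max_estimate": grp["estimate"].max(),
        }
        for method, lo_c, hi_c in (("ml", "ml_low", "ml_high"), ("sb", "sb_low", "sb_high")):
            width = grp[hi_c] - grp[lo_c]
            covers = (grp[lo_c] <= census_total) & (census_total <= grp[hi_c])
            with np.errstate(divide="ignore", invalid="ignore"):
                rel_hw = np.where(grp["estimate"] > 0, width / (2 * grp["estimate"]), np.inf)
            row.update(
                {
                    f"{method}_mean_low": grp[lo_c].mean(),
                    f"{method}_min_low": grp[lo_c].min(),
                    f"{method}_mean_high": grp[hi_c].mean(),
                    f"{method}_max_high": grp[hi_c].max(),
                    f"{method}_mean_width": width.mean(),
                    f"{method}_coverage": covers.mean(),
                    f"{method}_mean_rel_halfwidth": float(np.mean(rel_hw)),
                }
            )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("fraction", ignore_index=True)

    fractions = table["fraction"].to_numpy()
    if fraction_of_interest is None:
        fraction_of_interest = float(fractions[np.argmin(np.abs(fractions - 0.55))])
    foi_row = table.iloc[int(np.argmin(np.abs(fractions - fraction_of_interest)))]
    method = "ML" if foi_row["ml_mean_width"] <= foi_row["sb_mean_width"] else "SB"
    m = method.lower()
    ok = (table[f"{m}_mean_rel_halfwidth"] <= rel_halfwidth_tol) & (
        table[f"{m}_coverage"] >= coverage_floor
    )
    recommended_fraction = float(table.loc[ok, "fraction"].min()) if ok.any() else None
    return EffortSummary(
        table=table,
        census_total=census_total,
        alpha=alpha,
        recommended_method=method,
        recommended_fraction=recommended_fraction,
        fraction_of_interest=fraction_of_interest,
    )


def render_effort_plots(
    records: Sequence[EffortRecord],
    summary: EffortSummary,
    outdir: Union[str, Path],
    detail_fraction: float = 0.55,
) -> List[Path]:
    """Render the three standard effort figures.

    1. Boxplots of the CI bounds per fraction for both methods, with a
       horizontal red reference line at the full-census total.
    2. Range of mean estimates per fraction for both methods.
    3. Detail view of the intervals at one selected fraction.
    """
    if not records:
        raise ValidationError("no records to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    fractions = sorted(df["fraction"].unique())
    paths: List[Path] = []

    # 1. CI envelope boxplots
    fig, axes = plt.subplots(2, 1, figsize=(10, 8), sharex=True)
    for ax, (name, lo_c, hi_c) in zip(
        axes, (("SB", "sb_low", "sb_high"), ("ML", "ml_low", "ml_high"))
    ):
        data = [
            pd.concat([df.loc[df["fraction"] == f, lo_c], df.loc[df["fraction"] == f, hi_c]])
            for f in fractions
        ]
        ax.boxplot(data, tick_labels=[f"{f:.0%}" for f in fractions])
        ax.axhline(summary.census_total, color="red", lw=1.2)
        ax.set_ylabel(f"{name} CI bounds")
    axes[-1].set_xlabel("sampling fraction")
    fig.tight_layout()
    p = outdir / "effort_ci_boxplots.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    # 2. Range of mean estimates
    fig, ax = plt.subplots(figsize=(9, 5))
    means = df.groupby("fraction")["estimate"].agg(["mean", "min", "max"]).loc[fractions]
    ax.fill_between(fractions, means["min"], means["max"], alpha=0.25, label="range")
    ax.plot(fractions, means["mean"], "o-", label="mean estimate")
    ax.axhline(summary.census_total, color="red", lw=1.2, label="census total")
    ax.set_xlabel("sampling fraction")
    ax.set_ylabel("estimated total")
    ax.legend()
    fig.tight_layout()
    p = outdir / "effort_estimate_range.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    # 3. Detail at one fraction
    near = min(fractions, key=lambda f: abs(f - detail_fraction))
    sub = df[df["fraction"] == near]
    fig, ax = plt.subplots(figsize=(9, 5))
    reps = sub["replicate"].to_numpy()
    for off, (name, lo_c, hi_c, color) in enumerate(
        (("SB", "sb_low", "sb_high", "C0"), ("ML", "ml_low", "ml_high", "C1"))
    ):
        ax.vlines(reps + 0.2 * off, sub[lo_c], sub[hi_c], color=color, label=name)
    ax.axhline(summary.census_total, color="red", lw=1.2)
    ax.set_xlabel("replicate")
    ax.set_ylabel(f"CI at fraction {near:.0%}")
    ax.legend()
    fig.tight_layout()
    p = outdir / "effort_detail_fraction.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
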