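"""Graphical model checks: density, CDF overlay, PP and QQ series.

Every diagnostic is computed as a plain data series first (headlessly
testable, exportable as CSV) and only then rendered with matplotlib.

Conventions for discrete data: the plotting position of the i-th order
statistic is the Hazen position (i - 0.5)/n, and the theoretical quantile
at probability p is the smallest support point whose CDF reaches p. PP
axes are (theoretical CDF at the order statistic, plotting position); QQ
axes are (theoretical quantile, empirical order statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

from .distribution_fit import FittedDistribution
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "DiagnosticSeries",
    "empirical_cdf",
    "pp_points",
    "qq_points",
    "density_series",
    "render_diagnostics",
]


@dataclass(frozen=True)
class DiagnosticSeries:
    """One plottable diagnostic: kind, points, and an identity-line flag."""

    kind: str  # cdf | pp | qq | density
    points: List[Tuple[float, float]]
    label: str = ""
    reference: bool = False  # draw the y = x reference line (pp/qq)

    def __post_init__(self) -> None:
        if self.kind not in {"cdf", "pp", "qq", "density"}:
            raise ValidationError(f"unknown diagnostic kind {self.kind!r}")
        if self.kind == "pp":
            for x, y in self.points:
                if not (0 <= x <= 1 and 0 <= y <= 1):
                    raise ValidationError("pp points must lie in the unit square")
        if self.kind == "cdf":
            ys = [y for _, y in self.points]
            if any(b < a for a, b in zip(ys, ys[1:])):
                raise ValidationError("cdf series must be non-decreasing")

    def to_csv(self, path: Union[str, Path]) -> None:
        lines = ["x,y"] + [f"{x},{y}" for x, y in self.points]
        Path(path).write_text("\n".join(lines) + "\n")


def _sorted_counts(counts: Sequence[int]) -> np.ndarray:
    x = np.sort(np.asarray(counts))
    if x.size == 0:
        raise InsufficientDataError("no counts supplied")
    return x


def empirical_cdf(counts: Sequence[int]) -> DiagnosticSeries:
    """Step-function CDF: for each distinct value v, (v, fraction <= v)."""
    x = _sorted_counts(counts)
    values, cum = np.unique(x, return_counts=True)
    frac = np.cumsum(cum) / x.size
    return DiagnosticSeries("cdf", list(zip(values.astype(float), frac)), label="empirical")


def theoretical_cdf(fitted: FittedDistribution, upto: int) -> DiagnosticSeries:
    """Model CDF evaluated on the support 0..upto."""
    dist = fitted.frozen()
    support = np.arange(upto + 1)
    return DiagnosticSeries(
        "cdf", list(zip(support.astype(float), dist.cdf(support))), label=fitted.family
    )


def pp_points(counts: Sequence[int], fitted: FittedDistribution) -> DiagnosticSeries:
    """Probability-probability series: model CDF vs empirical plotting position.

    Discrete data tie heavily, so each distinct observed value yields one
    point: x = model CDF at the value, y = Hazen plotting position
    (i - 0.5)/n of the highest tied rank i (for untied data this is the
    usual per-order-statistic construction; a single observation sits at
    y = 0.5). Under the true model the points track the identity line at
    the empirical-CDF convergence rate.
    """
    x = _sorted_counts(counts)
    n = x.size
    dist = fitted.frozen()
    values, counts_per = np.unique(x, return_counts=True)
    top_rank = np.cumsum(counts_per)  # highest rank within each tie block
    theo = dist.cdf(values)
    emp = (top_rank - 0.5) / n
    return DiagnosticSeries("pp", list(zip(theo, emp)), label=fitted.family, reference=True)


def qq_points(counts: Sequence[int], fitted: FittedDistribution) -> DiagnosticSeries:
    """Quantile-quantile series: model quantile at the Hazen position vs order statistic."""
    x = _sorted_counts(counts)
    n = x.size
    dist = fitted.frozen()
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = dist.ppf(probs)  # smallest support point with CDF >= p
    return DiagnosticSeries("qq", list(zip(theo, x.astype(float))), label=fitted.family, reference=True)


def density_series(counts: Sequence[int], fitted: FittedDistribution = None) -> DiagnosticSeries:
    """Relative frequency per count class (empirical) or model pmf (fitted given)."""
    x = _sorted_counts(counts)
    kmax = int(x.max())
    support = np.arange(kmax + 1)
    if fitted is None:
        freq = np.bincount(x, minlength=kmax + 1) / x.size
        return DiagnosticSeries("density", list(zip(support.astype(float), freq)), label="empirical")
    pmf = fitted.frozen().pmf(support)
    return DiagnosticSeries("density", list(zip(support.astype(float), pmf)), label=fitted.family)


def render_diagnostics(
    series: Sequence[DiagnosticSeries],
    path: Union[str, Path],
    title: str = "",
) -> Path:
    """Render diagnostic series grouped by kind into one multi-panel figure.

    Empirical series draw in black, theoretical series in red, matching
    the usual presentation of these overlays. Writes PNG or SVG depending
    on the file suffix.
    """
    if not series:
        raise ValidationError("no series to render")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kinds = sorted({s.kind for s in series})
    fig, axes = plt.subplots(1, len(kinds), figsize=(4.5 * len(kinds), 4))
    if len(kinds) == 1:
        axes = [axes]
    for ax, kind in zip(axes, kinds):
        for s in (s for s in series if s.kind == kind):
            xs, ys = zip(*s.points) if s.points else ((), ())
            color = "black" if s.label == "empirical" else "red"
            if kind in {"cdf", "density"}:
                ax.step(xs, ys, where="post", label=s.label or None, color=color, alpha=0.8)
            else:
                ax.plot(xs, ys, "o", ms=3, label=s.label or None, color=color, alpha=0.7)
            if s.reference and s.points:
                lo, hi = min(min(xs), min(ys)), max(max(xs), max(ys))
                ax.plot([lo, hi], [lo, hi], "-", color="grey", lw=0.8)
        ax.set_title(kind.upper())
        ax.legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
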