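"""Observer correction factor (CF) estimation from paired counts.

On an inaccessible wall the field counts are "visual units" seen through
a low-magnification lens (20x). To convert them into individuals, the
observer repeats the count on 30-40 easily delimited areas with a
high-magnification lens (60x) -- or, where accessible areas exist, with a
true count. The CF is the mean of the per-area ratios
``high_mag_count / low_mag_count`` (individuals per visual unit); the
ratios should be roughly normal for the mean to be a sensible summary,
which is checked with a Shapiro-Wilk test. The CF is specific to an
observer and a sampling year.
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

from .errors import FormatError, InsufficientDataError, ValidationError
from .grid_io import GridCensus

__all__ = [
    "PairedObservation",
    "CorrectionFactor",
    "load_calibration_pairs",
    "compute_ratios",
    "test_normality",
    "estimate_cf",
    "apply_cf",
]

RECOMMENDED_MIN_PAIRS = 30  # field protocol: 30-40 calibration areas


@dataclass(frozen=True)
class PairedObservation:
    """One calibration area counted at both magnifications."""

    area_id: str
    low_mag_count: int
    high_mag_count: int

    def __post_init__(self) -> None:
        if self.low_mag_count < 0:
            raise ValidationError(f"area {self.area_id!r}: negative low-magnification count")
        if self.high_mag_count < 1:
            raise ValidationError(f"area {self.area_id!r}: high-magnification count must be >= 1")


@dataclass(frozen=True)
class CorrectionFactor:
    """Observer/year-specific multiplier from visual units to individuals.

    ``mean_ratio`` multiplies visual units (individuals per visual unit =
    high/low); ``reciprocal`` = 1/mean-of-ratios is reported alongside for
    traceability with the shrink-factor orientation (low/high).
    """

    mean_ratio: float
    sd_ratio: float
    n_pairs: int
    normality_p: float
    observer_id: str = "obs1"
    year: int = 0
    warnings_: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mean_ratio <= 0:
            raise ValidationError("CF mean_ratio must be positive")
        if self.n_pairs < 2:
            raise InsufficientDataError("a CF requires at least 2 calibration pairs")

    @property
    def reciprocal(self) -> float:
        return 1.0 / self.mean_ratio

    def to_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "reciprocal": self.reciprocal,
            "sd_ratio": self.sd_ratio,
            "n_pairs": self.n_pairs,
            "normality_p": self.normality_p,
            "observer_id": self.observer_id,
            "year": self.year,
            "warnings": list(self.warnings_),
        }

    def write_report(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_calibration_pairs(path: Union[str, Path]) -> pd.DataFrame:
    """Read paired calibration counts from CSV.

    Expected header: ``area_id,low_mag_count,high_mag_count[,observer_id][,year]``.
    """
    df = pd.read_csv(path)
    for col in ("area_id", "low_mag_count", "high_mag_count"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def compute_ratios(pairs: Sequence[PairedObservation]) -> List[float]:
    """Per-area ratios high/low: the factor converting visual units to individuals."""
    zero = [p.area_id for p in pairs if p.low_mag_count == 0]
    if zero:
        raise ValidationError(
            f"area(s) {zero} have zero low-magnification counts; a ratio is undefined"
        )
    return [p.high_mag_count / p.low_mag_count for p in pairs]


def test_normality(ratios: Sequence[float], alpha: float = 0.05) -> Tuple[float, bool]:
    """Shapiro-Wilk normality check on the ratios.

    Returns ``(p_value, passed)`` with ``passed`` true iff ``p >= alpha``.
    A zero-variance sample is degenerate: no evidence against normality is
    computable, so it passes with ``p = 1`` and a warning.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size < 3:
        raise InsufficientDataError("normality test requires at least 3 ratios")
    if np.ptp(r) == 0:
        warnings.warn("all ratios identical; normality test degenerate", stacklevel=2)
        return 1.0, True
    p = float(stats.shapiro(r).pvalue)
    return p, p >= alpha


test_normality.__test__ = False  # library function, not a pytest case


def estimate_cf(
    pairs: Sequence[PairedObservation],
    alpha: float = 0.05,
    *,
    observer_id: str = "obs1",
    year: int = 0,
    drop_zero_low: bool = True,
) -> CorrectionFactor:
    """Estimate the CF as the arithmetic mean of the high/low ratios.

    Pairs with a zero low-magnification count are dropped with a warning
    (their ratio is undefined). Fewer than 30 usable pairs, or a failed
    normality check, produce warnings recorded on the result, never
    errors: the mean is still used because the field protocol prescribes
    no alternative.
    """
    notes: List[str] = []
    usable = list(pairs)
    if drop_zero_low:
        dropped = [p.area_id for p in usable if p.low_mag_count == 0]
        if dropped:
            notes.append(f"dropped {len(dropped)} pair(s) with zero low counts: {dropped}")
            usable = [p for p in usable if p.low_mag_count > 0]
    if len(usable) < 2:
        raise InsufficientDataError("CF estimation requires at least 2 usable pairs")
    ratios = np.asarray(compute_ratios(usable))
    if len(usable) < RECOMMENDED_MIN_PAIRS:
        notes.append(
            f"only {len(usable)} pairs; the field protocol recommends "
            f"{RECOMMENDED_MIN_PAIRS}-40 calibration areas"
        )
    if ratios.size >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p, ok = test_normality(ratios, alpha)
        if not ok:
            notes.append(f"ratios fail Shapiro-Wilk normality at alpha={alpha} (p={normality_p:.4g})")
    else:
        normality_p = float("nan")
        notes.append("too few pairs for a normality check")
    return CorrectionFactor(
        mean_ratio=float(ratios.mean()),
        sd_ratio=float(ratios.std(ddof=1)),
        n_pairs=int(ratios.size),
        normality_p=normality_p,
        observer_id=observer_id,
        year=year,
        warnings_=tuple(notes),
    )


def apply_cf(census: GridCensus, cf: CorrectionFactor) -> pd.DataFrame:
    """Per-cell corrected values: ``visual_units * mean_ratio``.

    Returns a new DataFrame with a ``corrected`` column of reals; the raw
    integer counts are never overwritten. Excluded cells get a corrected
    value too (they are simply ignored by totals).
    """
    df = census.cells.copy()
    df["corrected"] = df["visual_units"].astype(float) * cf.mean_ratio
    return df
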