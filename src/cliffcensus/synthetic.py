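"""Synthetic cliff censuses and calibration pairs with known ground truth.

The generator emulates the field situation end to end so every stage of
the pipeline is testable without field data: a rectangular wall divided
into square cells (the reference wall is about 1470 m^2, i.e. roughly
147 cells of 10 m x 10 m), per-cell counts drawn i.i.d. from one of the
three supported count families, and an observer whose low-magnification
"visual unit" counts under-resolve the truth by a multiplicative factor
with Gaussian relative noise -- the minimal error model consistent with a
ratio-based correction factor.

Ground truth (the generating parameters, the expected total and the
realised census total) is always returned beside the fixtures so tests
never have to reverse-engineer it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .correction_factor import PairedObservation
from .distribution_fit import FAMILIES
from .errors import ValidationError
from .grid_io import GridCensus

__all__ = ["SyntheticScenario", "SyntheticCensus", "generate_census", "generate_calibration_pairs"]


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth description of one simulated cliff.

    Defaults: 147 cells (a ~1470 m^2 wall on a 10 m grid), Poisson counts
    with mean 5 per cell, a true correction factor of 1.5 with 10%
    relative observer noise, and 35 calibration areas (inside the 30-40
    band the field protocol recommends).
    """

    n_cells: int = 147
    family: str = "poisson"
    params: Dict[str, float] = field(default_factory=lambda: {"lambda": 5.0})
    cf_true: float = 1.5
    cf_noise_sd: float = 0.1
    n_calibration_pairs: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ValidationError("n_cells must be >= 10")
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.cf_true <= 0:
            raise ValidationError("cf_true must be positive")
        if self.cf_noise_sd < 0:
            raise ValidationError("cf_noise_sd must be non-negative")
        _family_mean(self.family, self.params)  # validates parameter domains

    @property
    def true_mean(self) -> float:
        """Expected count per cell under the generating model."""
        return _family_mean(self.family, self.params)

    @property
    def true_total(self) -> float:
        """Expected population total: n_cells x per-cell mean."""
        return self.n_cells * self.true_mean


@dataclass(frozen=True)
class SyntheticCensus:
    """A generated census together with its ground truth."""

    census: GridCensus
    scenario: SyntheticScenario
    true_total: float  # expected total under the generating model
    realised_total: int  # sum of the drawn counts


def _family_mean(family: str, params: Dict[str, float]) -> float:
    if family == "poisson":
        lam = params["lambda"]
        if lam <= 0:
            raise ValidationError("poisson lambda must be positive")
        return lam
    if family == "geometric":
        p = params["p"]
        if not (0 < p <= 1):
            raise ValidationError("geometric p must lie in (0, 1]")
        return (1 - p) / p
    if family == "negative_binomial":
        r, mu = params["r"], params["mu"]
        if r <= 0 or mu <= 0:
            raise ValidationError("negative binomial r and mu must be positive")
        return mu
    raise ValidationError(f"unknown family {family!r}")


def _draw_counts(family: str, params: Dict[str, float], size: int, rng: np.random.Generator) -> np.ndarray:
    if family == "poisson":
        return rng.poisson(params["lambda"], size)
    if family == "geometric":
        # failures before first success, support {0, 1, ...}
        return rng.geometric(params["p"], size) - 1
    if family == "negative_binomial":
        r, mu = params["r"], params["mu"]
        return rng.negative_binomial(r, r / (r + mu), size)
    raise ValidationError(f"unknown family {family!r}")


def generate_census(scenario: SyntheticScenario) -> SyntheticCensus:
    """Draw a full synthetic census: i.i.d. per-cell counts, seeded.

    Cell ids are ``C001, C002, ...`` in row order; every cell is included
    (edge exclusion is an input-processing concern, exercised separately).
    """
    rng = np.random.default_rng([scenario.seed, 0])
    counts = _draw_counts(scenario.family, scenario.params, scenario.n_cells, rng)
    df = pd.DataFrame(
        {
            "cell_id": [f"C{i + 1:03d}" for i in range(scenario.n_cells)],
            "visual_units": counts,
            "included": True,
        }
    )
    census = GridCensus(df, cell_size_m=10.0, wall_area_m2=scenario.n_cells * 100.0)
    return SyntheticCensus(
        census=census,
        scenario=scenario,
        true_total=scenario.true_total,
        realised_total=int(counts.sum()),
    )


def generate_calibration_pairs(scenario: SyntheticScenario) -> List[PairedObservation]:
    """Draw paired observer counts for CF calibration.

    The high-magnification count is the (near-)true count, drawn from the
    scenario family and floored at 1 (an area with nothing to count would
    never be chosen as a calibration area). The low-magnification count
    under-resolves it: low = round(high / cf_true x (1 + N(0, sd))),
    floored at 1, so that high/low ratios scatter around cf_true.
    """
    if scenario.n_calibration_pairs < 2:
        raise ValidationError("n_calibration_pairs must be >= 2")
    rng = np.random.default_rng([scenario.seed, 1])
    high = np.maximum(
        _draw_counts(scenario.family, scenario.params, scenario.n_calibration_pairs, rng), 1
    )
    noise = 1.0 + rng.normal(0.0, scenario.cf_noise_sd, scenario.n_calibration_pairs)
    low = np.maximum(np.floor(high / scenario.cf_true * noise + 0.5).astype(int), 1)
    return [
        PairedObservation(area_id=f"A{i + 1:02d}", low_mag_count=int(lo), high_mag_count=int(hi))
        for i, (lo, hi) in enumerate(zip(low, high))
    ]
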