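"""Maximum-likelihood fitting of count models to per-cell censuses.

Three candidate families describe how plants distribute over grid cells:

* ``poisson`` -- complete spatial randomness; mean = variance = lambda.
* ``geometric`` -- number of failures before the first success, support
  {0, 1, 2, ...}; heavily right-skewed, variance > mean.
* ``negative_binomial`` -- aggregated (clumped) counts, parameterised by
  dispersion ``r`` (size) and mean ``mu``; variance = mu + mu^2/r, so
  small ``r`` means strong clumping and r -> inf recovers the Poisson.

All three MLEs equate the model mean to the sample mean, which downstream
code exploits: the fitted mean times the number of cells is the expansion
estimate of the population total.

Model choice combines a chi-square goodness-of-fit test on pooled count
classes with AIC/BIC ranking (lower is better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "FAMILIES",
    "FittedDistribution",
    "GofResult",
    "fit_distribution",
    "chi_square_gof",
    "compare_models",
    "distribution_mean",
]

FAMILIES = ("geometric", "poisson", "negative_binomial")

# r above this is reported as a Poisson-boundary fit (variance <= mean data)
_NB_R_BOUNDARY = 1e6


@dataclass(frozen=True)
class FittedDistribution:
    """A count-model family with its MLE parameters and fit indices."""

    family: str
    params: Dict[str, float]
    loglik: float
    n: int
    boundary: bool = False  # NB fit pinned at the large-r (Poisson) boundary

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return 2 if self.family == "negative_binomial" else 1

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2 * self.loglik

    def frozen(self) -> stats.rv_discrete:
        """The fitted scipy distribution (support starts at 0 for all families)."""
        if self.family == "poisson":
            return stats.poisson(self.params["lambda"])
        if self.family == "geometric":
            # geometric on {0,1,...} == negative binomial with size 1
            return stats.nbinom(1, self.params["p"])
        if self.family == "negative_binomial":
            r, mu = self.params["r"], self.params["mu"]
            return stats.nbinom(r, r / (r + mu))
        raise ValidationError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "boundary": self.boundary,
        }


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit outcome on pooled count classes."""

    chi2: float
    df: int
    p_value: float
    bins: List[Tuple[str, float, float]]  # (label, observed, expected)
    low_resolution: bool = False  # pooling left <= 2 classes; df floored

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "bins": [{"class": c, "observed": o, "expected": e} for c, o, e in self.bins],
            "low_resolution": self.low_resolution,
        }


def _check_counts(counts: Sequence[int]) -> np.ndarray:
    x = np.asarray(counts)
    if x.size == 0:
        raise InsufficientDataError("no counts supplied")
    if np.any(x < 0) or not np.issubdtype(x.dtype, np.integer) and np.any(x != np.floor(x)):
        raise ValidationError("counts must be non-negative integers")
    return x.astype(np.int64)


def _nb_profile_loglik(log_r: float, x: np.ndarray, mu: float) -> float:
    """NB log-likelihood with mu profiled at the sample mean, as a function of log r."""
    r = np.exp(log_r)
    # log pmf = lgamma(x+r) - lgamma(r) - lgamma(x+1) + r log(r/(r+mu)) + x log(mu/(r+mu))
    n = x.size
    ll = (
        gammaln(x + r).sum()
        - n * gammaln(r)
        - gammaln(x + 1).sum()
        + n * r * np.log(r / (r + mu))
        + x.sum() * np.log(mu / (r + mu))
    )
    return float(ll)


def fit_distribution(counts: Sequence[int], family: str) -> FittedDistribution:
    """Fit one family by maximum likelihood.

    Closed forms where exact: Poisson ``lambda = mean``; geometric (on
    {0,1,...}) ``p = 1/(1+mean)``. The negative binomial profiles the mean
    out (``mu = mean`` solves the score for any r) and maximises the
    profile log-likelihood over log r numerically. Data with sample
    variance <= mean push r to the large-r boundary; the fit is returned
    with ``boundary=True`` rather than failing, since it simply degenerates
    toward the Poisson.
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = _check_counts(counts)
    if x.size < 2:
        raise InsufficientDataError("fitting requires at least 2 observations")
    m = float(x.mean())
    n = int(x.size)

    if family == "poisson":
        lam = m
        ll = float(stats.poisson.logpmf(x, lam).sum())  # lam=0 degenerates to mass 1 at 0
        return FittedDistribution("poisson", {"lambda": lam}, ll, n)

    if family == "geometric":
        p = 1.0 / (1.0 + m)
        ll = float(stats.nbinom.logpmf(x, 1, p).sum())
        return FittedDistribution("geometric", {"p": p}, ll, n)

    # negative binomial
    if m == 0:
        raise InsufficientDataError("negative binomial undefined for all-zero data")
    res = optimize.minimize_scalar(
        lambda lr: -_nb_profile_loglik(lr, x, m),
        bounds=(np.log(1e-4), np.log(_NB_R_BOUNDARY)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    r = float(np.exp(res.x))
    boundary = r > 0.99 * _NB_R_BOUNDARY
    if boundary:
        warnings.warn(
            "variance <= mean: negative binomial fit at the large-r (Poisson) boundary",
            stacklevel=2,
        )
    ll = _nb_profile_loglik(np.log(r), x, m)
    return FittedDistribution("negative_binomial", {"r": r, "mu": m}, ll, n, boundary=boundary)


def distribution_mean(fitted: FittedDistribution) -> float:
    """Theoretical mean of the fitted model (equals the sample mean by MLE)."""
    if fitted.family == "poisson":
        return fitted.params["lambda"]
    if fitted.family == "geometric":
        p = fitted.params["p"]
        return (1.0 - p) / p
    if fitted.family == "negative_binomial":
        return fitted.params["mu"]
    raise ValidationError(f"unknown family {fitted.family!r}")


def distribution_variance(fitted: FittedDistribution) -> float:
    """Theoretical variance of the fitted model."""
    if fitted.family == "poisson":
        return fitted.params["lambda"]
    if fitted.family == "geometric":
        p = fitted.params["p"]
        return (1.0 - p) / p**2
    if fitted.family == "negative_binomial":
        r, mu = fitted.params["r"], fitted.params["mu"]
        return mu + mu**2 / r
    raise ValidationError(f"unknown family {fitted.family!r}")


def nb_size_prob(fitted: FittedDistribution) -> Tuple[float, float]:
    """Convert an NB fit from (size r, mean mu) to (size r, prob p)."""
    if fitted.family != "negative_binomial":
        raise ValidationError("nb_size_prob applies to negative binomial fits only")
    r, mu = fitted.params["r"], fitted.params["mu"]
    return r, r / (r + mu)


def chi_square_gof(
    counts: Sequence[int],
    fitted: FittedDistribution,
    min_expected: float = 5.0,
) -> GofResult:
    """Chi-square goodness of fit on count classes 0, 1, 2, ...

    Classes are pooled from the largest count downward (merging into an
    open upper-tail class) until the tail class has expected frequency
    >= ``min_expected``. chi2 = sum (O-E)^2/E over the pooled classes;
    df = classes - 1 - estimated parameters, floored at 1. The null is
    that observed and expected class frequencies agree; it is rejected
    when the p-value falls below the chosen significance level.
    """
    x = _check_counts(counts)
    n = x.size
    kmax = int(x.max())
    dist = fitted.frozen()
    support = np.arange(kmax + 1)
    expected = n * dist.pmf(support)
    tail = n * float(dist.sf(kmax))  # open class "> kmax"
    observed = np.bincount(x, minlength=kmax + 1).astype(float)

    exp_bins = list(expected) + [tail]
    obs_bins = list(observed) + [0.0]
    labels = [str(v) for v in support] + [f">{kmax}"]
    # pool from the largest class downward until the open tail class and the
    # class just below it both reach min_expected (sparse top classes would
    # otherwise dominate the statistic)
    while len(exp_bins) > 2 and (
        exp_bins[-1] < min_expected or exp_bins[-2] < min_expected
    ):
        e, o = exp_bins.pop(), obs_bins.pop()
        labels.pop()
        exp_bins[-1] += e
        obs_bins[-1] += o
        labels[-1] = f">={labels[-1].lstrip('>=')}"
    low_res = len(exp_bins) <= 2
    if low_res:
        warnings.warn("pooling left <= 2 count classes; chi-square has low resolution", stacklevel=2)

    exp_arr = np.asarray(exp_bins)
    obs_arr = np.asarray(obs_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp_arr > 0, (obs_arr - exp_arr) ** 2 / exp_arr, 0.0)
    chi2 = float(terms.sum())
    df = max(len(exp_bins) - 1 - fitted.k, 1)
    p = float(stats.chi2.sf(chi2, df))
    return GofResult(chi2, df, p, list(zip(labels, obs_bins, exp_bins)), low_resolution=low_res)


def compare_models(
    counts: Sequence[int],
    families: Sequence[str] = FAMILIES,
    alpha: float = 0.05,
    min_expected: float = 5.0,
) -> List[Tuple[FittedDistribution, GofResult]]:
    """Fit and GOF-test each family; rank ascending by AIC.

    Ties break by BIC, then by fewer parameters. A family whose
    chi-square test rejects at ``alpha`` stays in the ranking (the test
    flags it; both indices and test are reported, and the final call is
    the analyst's). A family that fails to fit is dropped with a warning.
    """
    if not families:
        raise ValidationError("at least one family required")
    results: List[Tuple[FittedDistribution, GofResult]] = []
    for fam in families:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_distribution(counts, fam)
                gof = chi_square_gof(counts, fit, min_expected=min_expected)
        except (InsufficientDataError, ValidationError) as exc:
            warnings.warn(f"family {fam!r} unavailable: {exc}", stacklevel=2)
            continue
        results.append((fit, gof))
    results.sort(key=lambda fg: (fg[0].aic, fg[0].bic, fg[0].k))
    return results
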