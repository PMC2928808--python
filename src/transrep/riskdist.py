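"""Population distributions of genetic relative risk.

For one population the model maps the distribution of total risk-allele
counts among controls through ``logRR = (RA - RA0) * ln(OR_i)``, where
``OR_i`` is that population's fitted per-allele odds ratio and ``RA0`` a
common centering constant (the mean control allele count, 18.5 in the
source study) so that logRR = 0 at the reference count.  All statistics
are computed on the discrete distribution; a smoothing spline (or KDE) is
offered purely for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import gaussian_kde

from .exceptions import DataError, ParameterError


def logrr(ra, or_i: float, center: float = 18.5):
    """Log relative risk of allele count ``ra``: ``(ra - center) * ln(or_i)``."""
    if or_i <= 0:
        raise ParameterError(f"per-allele OR must be > 0, got {or_i}")
    return (np.asarray(ra, dtype=float) - center) * np.log(or_i)


@dataclass
class RiskDistribution:
    """Discrete distribution of logRR for one population."""

    population: str
    per_allele_or: float
    center: float
    support: np.ndarray  # allele-count values
    rel_freq: np.ndarray  # sums to 1

    @property
    def logrr_grid(self) -> np.ndarray:
        return logrr(self.support, self.per_allele_or, self.center)

    @property
    def mean_logrr(self) -> float:
        return float(self.logrr_grid @ self.rel_freq)

    @property
    def sd_logrr(self) -> float:
        g = self.logrr_grid
        m = self.mean_logrr
        return float(np.sqrt(((g - m) ** 2) @ self.rel_freq))


def build_distribution(
    control_scores,
    or_i: float,
    center: float = 18.5,
    population: str = "",
) -> RiskDistribution:
    """Empirical allele-count distribution of controls mapped to logRR.

    Scores are binned to the nearest integer allele count (imputed scores
    are non-integer).  Requires at least 10 control scores.
    """
    scores = np.asarray(pd.Series(control_scores).dropna(), dtype=float)
    if scores.size == 0:
        raise DataError("no control scores")
    if scores.size < 10:
        raise DataError(f"need >= 10 control scores, got {scores.size}")
    counts = np.rint(scores).astype(int)
    support, freq = np.unique(counts, return_counts=True)
    rel = freq / freq.sum()
    return RiskDistribution(
        population=population,
        per_allele_or=float(or_i),
        center=float(center),
        support=support.astype(float),
        rel_freq=rel,
    )


def smooth_distribution(
    dist: RiskDistribution,
    method: str = "spline",
    n_grid: int = 256,
    lam: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Display-only smooth curve (x on the logRR axis, density integrating
    to one over the support range).

    ``spline`` fits a cubic smoothing spline to the discrete frequency
    polygon with non-negativity clamping and renormalisation; ``kde`` is a
    Gaussian kernel estimate.  With fewer than 4 support points falls back
    to the discrete bars with a warning.
    """
    x_pts = dist.logrr_grid
    order = np.argsort(x_pts)
    x_pts, y_pts = x_pts[order], dist.rel_freq[order]
    if len(x_pts) < 4 or np.ptp(x_pts) == 0:
        warnings.warn("fewer than 4 distinct support points; returning discrete bars")
        return x_pts, y_pts
    step = np.abs(np.diff(x_pts)).min()
    grid = np.linspace(x_pts.min(), x_pts.max(), n_grid)
    if method == "spline":
        spl = make_smoothing_spline(x_pts, y_pts / step, lam=lam)
        dens = np.clip(spl(grid), 0.0, None)
    elif method == "kde":
        kde = gaussian_kde(x_pts, weights=y_pts)
        dens = kde(grid)
    else:
        raise ParameterError(f"unknown smoothing method {method!r}")
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise DataError("smoothed curve degenerate (zero area)")
    return grid, dens / area


@dataclass(frozen=True)
class DistributionComparison:
    """Location/spread/overlap summary of two logRR distributions."""

    mean_shift: float  # mean(a) - mean(b)
    sd_diff: float  # sd(a) - sd(b)
    overlap: float  # in [0, 1]


def compare_distributions(
    dist_a: RiskDistribution,
    dist_b: RiskDistribution,
    n_bins: int = 400,
) -> DistributionComparison:
    """Compare two distributions on a common logRR axis.

    The overlap coefficient discretises both onto a shared bin grid and
    sums the bin-wise minima of the two probability masses.
    """
    ga, gb = dist_a.logrr_grid, dist_b.logrr_grid
    lo = min(ga.min(), gb.min())
    hi = max(ga.max(), gb.max())
    if hi == lo:
        overlap = 1.0 if np.array_equal(ga, gb) else 0.0
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)
        wa = np.histogram(ga, bins=edges, weights=dist_a.rel_freq)[0]
        wb = np.histogram(gb, bins=edges, weights=dist_b.rel_freq)[0]
        overlap = float(np.minimum(wa, wb).sum())
    return DistributionComparison(
        mean_shift=dist_a.mean_logrr - dist_b.mean_logrr,
        sd_diff=dist_a.sd_logrr - dist_b.sd_logrr,
        overlap=overlap,
    )
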