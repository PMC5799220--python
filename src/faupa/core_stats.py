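"""Scalar and vector statistics used throughout the package.

All correlation-based detection rests on a handful of primitives: the
Pearson correlation coefficient of two time courses, its two-tailed
p-value via the t transform, one-tailed t-tests (paired and two-sample),
and the normal-quantile thresholds TH1 = mu - 1.645*sigma and
TH2 = mu - 2.327*sigma that turn the mean/spread of a region's
member correlations into membership and acceptance criteria.

Conventions
-----------
* Sample standard deviations use the n-1 denominator.
* Correlations are clipped to [-1, 1]; values within ``SNAP_TOL`` of
  +/-1 are snapped to exactly +/-1 so that the noise-free limit of the
  generative model (where every member course is an exact rescaling of
  a common course, hence R_i = 1) is representable without round-off
  jitter destabilising the thresholding iteration.
* Zero-variance series raise :class:`~faupa.errors.DegenerateSeriesError`;
  callers exclude such voxels rather than assigning them r = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateSeriesError, ParameterError

#: correlations within this distance of +/-1 are snapped to exactly +/-1
SNAP_TOL = 1e-12

#: z multipliers for the one-tail 5% and 1% normal quantiles
Z_TH1 = 1.645
Z_TH2 = 2.327

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class Thresholds:
    """Correlation thresholds derived from the member-R_i moments.

    ``th1 = mu - 1.645*sigma`` (one-tail probability < 5%) defines region
    membership; ``th2 = mu - 2.327*sigma`` (one-tail probability < 1%)
    bounds the 4%-band used by the border acceptance criterion.
    """

    th1: float
    th2: float

    def __post_init__(self) -> None:
        if self.th2 > self.th1 + 1e-15:
            raise ParameterError("th2 must not exceed th1")


@dataclass(frozen=True)
class CorrSummary:
    """Summary of a voxel set's correlations with its mean course."""

    r_values: np.ndarray
    mu: float
    sigma: float
    r_bar: float

    @classmethod
    def from_r_values(cls, r_values: Sequence[float]) -> "CorrSummary":
        r = np.asarray(r_values, dtype=float)
        if r.size == 0:
            raise ParameterError("need at least one correlation value")
        if np.any(np.abs(r) > 1.0):
            raise ParameterError("correlation values must lie in [-1, 1]")
        mu = float(r.mean())
        sigma = float(r.std(ddof=1)) if r.size > 1 else 0.0
        return cls(r_values=r, mu=mu, sigma=sigma, r_bar=mu)


def _snap(r: np.ndarray | float):
    r = np.clip(r, -1.0, 1.0)
    r = np.where(np.abs(1.0 - np.abs(r)) < SNAP_TOL, np.sign(r), r)
    return r


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of two equal-length series.

    Raises
    ------
    DegenerateSeriesError
        If either series has zero variance.
    ParameterError
        If the series differ in length or are shorter than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("series must be 1-D and of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 time points")
    dx = x - x.mean()
    dy = y - y.mean()
    nx = np.linalg.norm(dx)
    ny = np.linalg.norm(dy)
    if nx == 0.0 or ny == 0.0:
        raise DegenerateSeriesError("zero-variance series has no correlation")
    return float(_snap(float(dx @ dy) / (nx * ny)))


def corr_with_course(courses: np.ndarray, course: np.ndarray) -> np.ndarray:
    """Correlate every row of ``courses`` (shape (..., T)) with ``course``.

    Vectorised workhorse behind region growing. Degenerate rows (zero
    variance) yield NaN; the reference course must itself be
    non-degenerate.
    """
    course = np.asarray(course, dtype=float)
    courses = np.asarray(courses, dtype=float)
    dc = course - course.mean()
    nc = np.linalg.norm(dc)
    if nc == 0.0:
        raise DegenerateSeriesError("reference course has zero variance")
    d = courses - courses.mean(axis=-1, keepdims=True)
    n = np.sqrt((d * d).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (d @ dc) / (n * nc)
    r = np.where(n == 0.0, np.nan, r)
    return _snap(r)


def pearson_p(r: float, n: int) -> float:
    """Two-tailed p-value for a correlation via the t transform.

    Uses ``t = r * sqrt((n-2)/(1-r^2))`` with ``n-2`` degrees of freedom.
    ``|r| = 1`` returns the smallest positive float rather than zero.
    """
    if n < 3:
        raise ParameterError("need n >= 3")
    if abs(r) > 1.0:
        raise ParameterError("correlation must lie in [-1, 1]")
    if abs(r) == 1.0:
        return _TINY_P
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(max(min(p, 1.0), _TINY_P))


def thresholds_from_moments(mu: float, sigma: float,
                            z1: float = Z_TH1, z2: float = Z_TH2) -> Thresholds:
    """TH1/TH2 from the mean and sd of member correlations (exact arithmetic)."""
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    return Thresholds(th1=mu - z1 * sigma, th2=mu - z2 * sigma)


def normal_band_probability(z_low: float, z_high: float) -> float:
    """P(z_low < Z < z_high) for a standard normal Z.

    With (z_low, z_high) = (-2.327, -1.645) this is the ~4% chance that a
    border voxel's R_i lands between TH2 and TH1 under the region's own
    correlation model, which anchors the border acceptance criterion.
    """
    if z_low > z_high:
        raise ParameterError("z_low must not exceed z_high")
    return float(stats.norm.cdf(z_high) - stats.norm.cdf(z_low))


def one_tail_paired_t(a: Sequence[float], b: Sequence[float]) -> float:
    """One-tailed paired t-test p-value for mean(a - b) > 0.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``n-1`` degrees of freedom,
    where ``d = a - b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ParameterError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateSeriesError("all paired differences are identical")
    t = d.mean() / (sd / np.sqrt(n))
    return float(stats.t.sf(t, n - 1))


def one_tail_two_sample_t(a: Sequence[float], b: Sequence[float],
                          equal_var: bool = True) -> float:
    """One-tailed two-sample t-test p-value for mean(a) > mean(b).

    Defaults to the pooled-variance (Student) form; ``equal_var=False``
    selects the Welch form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ParameterError("need two 1-D samples of length >= 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            raise DegenerateSeriesError("both samples constant and equal")
        return 0.0 if diff > 0 else 1.0
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = diff / se
    return float(stats.t.sf(t, df))
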