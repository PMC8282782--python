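"""Rosenthal-Henderson B-factor analysis of resolution-vs-particle-number data.

The overall quality of a single-particle cryo-EM dataset can be summarized by
a single B-factor that models the Gaussian fall-off of usable signal with
spatial frequency.  It is estimated by reconstructing maps from random
particle subsets of increasing size N, plotting the squared reciprocal
resolution 1/d^2 against ln N, and fitting a straight line:

    1/d^2 = slope * ln N + offset,        B = 2 / slope   [A^2]

The slope measures how fast information is gained with more particles (signal
decay with spatial frequency); the offset reflects the overall per-particle
signal-to-noise ratio.  Two derived, B-factor-linked performance measures are
computed from the same line: the resolution attainable from a reference
particle count (default 100 000) and the particle count needed to reach a
reference resolution (default 3.0 A).  Standard errors for all derived
quantities come from first-order (delta-method) propagation of the fitted
slope/offset uncertainties, including their covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "SubsetPoint",
    "RHFit",
    "DerivedMetrics",
    "Measurement",
    "InsufficientDataError",
    "NonPhysicalFitError",
    "CollinearInputError",
    "OutOfFitRangeError",
    "exclude_outliers",
    "fit_rh",
    "resolution_at_particles",
    "particles_at_resolution",
    "derived_metrics",
    "reconstruct_fit",
]

DEFAULT_MIN_PARTICLES = 2000  # subsets below ~1-2 k particles misalign; see docs
DEFAULT_REF_PARTICLES = 100_000
DEFAULT_REF_RESOLUTION = 3.0  # A


class InsufficientDataError(ValueError):
    """Fewer usable data points than the operation requires."""


class NonPhysicalFitError(ValueError):
    """Fitted slope <= 0: resolution does not improve with more particles."""


class CollinearInputError(ValueError):
    """All points share one particle count; the line is undetermined."""


class OutOfFitRangeError(ValueError):
    """Requested point lies where the fitted line predicts 1/d^2 <= 0."""


class Measurement(NamedTuple):
    """A scalar with its standard error (``nan`` when not estimable)."""

    value: float
    se: float


@dataclass(frozen=True)
class SubsetPoint:
    """One random-subset reconstruction: particle count and global resolution.

    Transformed fit coordinates are x = ln(n_particles) and
    y = 1/resolution^2 (A^-2).
    """

    n_particles: int
    resolution: float  # A
    included: bool = True

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError(f"n_particles must be >= 1, got {self.n_particles}")
        if not self.resolution > 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")

    @property
    def x(self) -> float:
        return math.log(self.n_particles)

    @property
    def y(self) -> float:
        return self.resolution ** -2


@dataclass(frozen=True)
class RHFit:
    """Fitted Rosenthal-Henderson line and the derived B-factor.

    ``slope`` is in A^-2 per ln-particle, ``offset`` in A^-2, ``bfactor`` in
    A^2.  ``se_*`` and ``cov_slope_offset`` are ``nan`` when not estimable
    (two-point fits, or lines reconstructed from printed summary values).
    """

    slope: float
    offset: float
    se_slope: float
    se_offset: float
    cov_slope_offset: float
    bfactor: float
    se_bfactor: float
    n_points_used: int

    def covariance(self) -> np.ndarray:
        """2x2 covariance matrix of (slope, offset)."""
        return np.array(
            [
                [self.se_slope ** 2, self.cov_slope_offset],
                [self.cov_slope_offset, self.se_offset ** 2],
            ]
        )


@dataclass(frozen=True)
class DerivedMetrics:
    """The two B-factor-linked performance measures of a subset."""

    resolution_at_ref: Measurement  # A, at ref_n particles
    particles_at_ref: Measurement  # count, to reach ref_resolution
    ref_n: int = DEFAULT_REF_PARTICLES
    ref_resolution: float = DEFAULT_REF_RESOLUTION


def exclude_outliers(
    points: Sequence[SubsetPoint], min_particles: int = DEFAULT_MIN_PARTICLES
) -> list[SubsetPoint]:
    """Flag low-particle-count outlier points for exclusion from the fit.

    Reconstructions from very small subsets (below ~1-2 k particles) fail to
    lock onto secondary-structure periodicity and fall off the linear trend,
    so they are excluded by a pure count threshold.  Points are flagged, not
    deleted: the returned list preserves order and length, with
    ``included=False`` where ``n_particles < min_particles``.
    """
    if min_particles < 0:
        raise ValueError("min_particles must be >= 0")
    flagged = [replace(p, included=p.n_particles >= min_particles) for p in points]
    n_kept = sum(p.included for p in flagged)
    if n_kept < 2:
        raise InsufficientDataError(
            f"only {n_kept} point(s) remain above {min_particles} particles; "
            "need at least 2 for a line fit"
        )
    return flagged


def fit_rh(points: Sequence[SubsetPoint], weights: Sequence[float] | None = None) -> RHFit:
    """Ordinary least-squares fit of 1/d^2 against ln N over included points.

    Standard errors use the usual OLS formulas with n-2 residual degrees of
    freedom; with exactly two points the errors are not estimable and are
    reported as ``nan``.  ``weights`` enables a weighted fit (off by default;
    the conventional B-factor plot is unweighted).
    """
    used = [p for p in points if p.included]
    if len(used) < 2:
        raise InsufficientDataError(f"need >= 2 included points, got {len(used)}")
    x = np.array([p.x for p in used])
    y = np.array([p.y for p in used])
    if np.ptp(x) == 0:
        raise CollinearInputError("all points share one particle count")

    design = sm.add_constant(x)  # params: [offset, slope]
    if weights is None:
        res = sm.OLS(y, design).fit()
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(used):
            raise ValueError("weights must match the number of included points")
        res = sm.WLS(y, design, weights=w).fit()

    offset, slope = res.params
    if slope <= 0:
        raise NonPhysicalFitError(
            f"fitted slope {slope:.4g} <= 0: resolution does not improve with N"
        )
    if len(used) == 2:
        se_slope = se_offset = cov = float("nan")
    else:
        cov_mat = res.cov_params()
        se_offset = math.sqrt(cov_mat[0, 0])
        se_slope = math.sqrt(cov_mat[1, 1])
        cov = cov_mat[0, 1]

    bfactor = 2.0 / slope
    se_bfactor = (2.0 / slope ** 2) * se_slope  # first-order propagation
    return RHFit(
        slope=slope,
        offset=offset,
        se_slope=se_slope,
        se_offset=se_offset,
        cov_slope_offset=cov,
        bfactor=bfactor,
        se_bfactor=se_bfactor,
        n_points_used=len(used),
    )


def resolution_at_particles(
    fit: RHFit, n: float, include_covariance: bool = True
) -> Measurement:
    """Resolution (A) the fitted line predicts for ``n`` particles.

    d(n) = 1/sqrt(slope*ln n + offset).  The standard error is first-order
    (delta-method): with y = slope*ln n + offset and d = y^(-1/2),
    the gradient is dd/dslope = -ln(n)/(2 y^(3/2)) and
    dd/doffset = -1/(2 y^(3/2)); var(d) = g^T C g with C the (slope, offset)
    covariance.  ``include_covariance=False`` drops the off-diagonal term for
    comparison with variance-only propagation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ln_n = math.log(n)
    y = fit.slope * ln_n + fit.offset
    if y <= 0:
        raise OutOfFitRangeError(
            f"fitted 1/d^2 = {y:.4g} <= 0 at N = {n:g}; resolution undefined"
        )
    d = y ** -0.5
    grad = np.array([-0.5 * ln_n * y ** -1.5, -0.5 * y ** -1.5])
    se = _propagate(fit, grad, include_covariance)
    return Measurement(d, se)


def particles_at_resolution(
    fit: RHFit, d: float, include_covariance: bool = True
) -> Measurement:
    """Particle count the fitted line predicts is needed to reach ``d`` (A).

    N(d) = exp((1/d^2 - offset)/slope), reported as a real number.  Delta
    method: with u = (1/d^2 - offset)/slope, dN/dslope = -N*u/slope and
    dN/doffset = -N/slope.
    """
    if not d > 0:
        raise ValueError("d must be > 0")
    if fit.slope <= 0:
        raise NonPhysicalFitError("slope <= 0")
    u = (d ** -2 - fit.offset) / fit.slope
    n = math.exp(u)
    grad = np.array([-n * u / fit.slope, -n / fit.slope])
    se = _propagate(fit, grad, include_covariance)
    return Measurement(n, se)


def derived_metrics(
    fit: RHFit,
    ref_n: int = DEFAULT_REF_PARTICLES,
    ref_resolution: float = DEFAULT_REF_RESOLUTION,
    include_covariance: bool = True,
) -> DerivedMetrics:
    """Both derived performance measures of a fit at the reference points."""
    return DerivedMetrics(
        resolution_at_ref=resolution_at_particles(fit, ref_n, include_covariance),
        particles_at_ref=particles_at_resolution(fit, ref_resolution, include_covariance),
        ref_n=ref_n,
        ref_resolution=ref_resolution,
    )


def reconstruct_fit(bfactor: float, resolution_at_n: float, n: float) -> RHFit:
    """Rebuild the fitted line from a (B-factor, resolution at N) summary pair.

    The B-factor, the resolution from a reference count and the particles to
    a reference resolution are mutually determined by the same line, so any
    two of them pin it down.  This enables validating published summary
    tables without the underlying subset points.  Standard errors are not
    recoverable from the pair and are reported as ``nan``.
    """
    if not bfactor > 0:
        raise ValueError("bfactor must be > 0")
    if not resolution_at_n > 0:
        raise ValueError("resolution_at_n must be > 0")
    slope = 2.0 / bfactor
    offset = resolution_at_n ** -2 - slope * math.log(n)
    nan = float("nan")
    return RHFit(
        slope=slope,
        offset=offset,
        se_slope=nan,
        se_offset=nan,
        cov_slope_offset=nan,
        bfactor=bfactor,
        se_bfactor=nan,
        n_points_used=0,
    )


def _propagate(fit: RHFit, grad: np.ndarray, include_covariance: bool) -> float:
    cov = fit.covariance()
    if not include_covariance:
        cov = np.diag(np.diag(cov))
    var = float(grad @ cov @ grad)
    if math.isnan(var):
        return float("nan")
    return math.sqrt(max(var, 0.0))
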