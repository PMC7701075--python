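"""Weighted distributions over fibril length or sedimentation coefficient.

The central container is :class:`WeightedDistribution`: a 1D density
tabulated on a strictly increasing grid (length in nm or sedimentation
coefficient in S) with an explicit weighting basis:

* ``number`` -- each fibril counts once;
* ``mass``   -- each fibril counts in proportion to its mass
  (proportional to h^2 l, i.e. to l at constant height);
* ``extinction`` -- optical weighting.  Every fibril is a stack of
  subunits contributing equally to the extinction signal, so extinction
  weighting is identical to mass weighting and the conversion between
  the two is the identity.

Distributions can be continuous (density per axis unit, trapezoid
normalisation) or discrete (point masses at the grid values).  The
module provides AFM length-table ingestion with the 50 nm minimum-length
filter, lognormal/Weibull least-squares fits, weighting conversions, the
Jacobian-based mapping between length space and s space through the
cylinder model, and quantile summaries (Q10/Q50/Q90, mode, mean, width).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.optimize import curve_fit

from . import cylinder_hydro as ch
from .cylinder_hydro import FibrilMaterial, SolventConditions

__all__ = [
    "WeightedDistribution",
    "LognormalFit",
    "WeibullFit",
    "QuantileSummary",
    "ingest_length_table",
    "convert_weighting",
    "fit_lognormal",
    "fit_weibull",
    "length_dist_to_s_dist",
    "s_dist_to_length_dist",
    "summarize",
]

WEIGHTINGS = ("number", "mass", "extinction")
AXIS_KINDS = ("length", "sedimentation_coefficient")

#: exponent of fibril length in the per-particle weight, relative to number
_LENGTH_EXPONENT = {"number": 0, "mass": 1, "extinction": 1}


@dataclass
class WeightedDistribution:
    """A 1D distribution over length [nm] or sedimentation coefficient [S].

    Parameters
    ----------
    axis_kind : {"length", "sedimentation_coefficient"}
    grid : array
        Strictly increasing positive axis values (nm or S).
    density : array
        Non-negative weights. For continuous distributions this is a
        density per axis unit normalised by the trapezoid rule; for
        discrete distributions it is the point-mass vector summing to 1.
    weighting : {"number", "mass", "extinction"}
    discrete : bool
    metadata : dict
        Free-form provenance (filter counts, seeds, conversion drift...).
    """

    axis_kind: str
    grid: np.ndarray
    density: np.ndarray
    weighting: str
    discrete: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.grid.ndim != 1 or self.grid.size < 1:
            raise ValueError("grid must be a non-empty 1D array")
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have matching shapes")
        if np.any(self.grid <= 0):
            raise ValueError("grid values must be positive")
        if self.grid.size > 1 and np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < -1e-300):
            raise ValueError("density must be non-negative")

    # -- normalisation ------------------------------------------------
    def integral(self) -> float:
        """Total weight: trapezoid integral (continuous) or sum (discrete)."""
        if self.discrete or self.grid.size == 1:
            return float(self.density.sum())
        return float(np.trapezoid(self.density, self.grid))

    def normalized(self) -> "WeightedDistribution":
        tot = self.integral()
        if tot <= 0:
            raise ValueError("cannot normalise a distribution with zero total weight")
        return replace(self, density=self.density / tot)

    # -- cumulative / quantiles ---------------------------------------
    def cumulative(self) -> np.ndarray:
        """Node-wise cumulative weight, non-decreasing from 0 (continuous)
        or from the first point mass (discrete) to the total."""
        if self.discrete or self.grid.size == 1:
            return np.cumsum(self.density)
        dx = np.diff(self.grid)
        seg = 0.5 * (self.density[:-1] + self.density[1:]) * dx
        return np.concatenate([[0.0], np.cumsum(seg)])

    def quantile(self, p) -> np.ndarray:
        """Axis value at cumulative fraction ``p`` by linear interpolation."""
        c = self.cumulative()
        tot = c[-1]
        if tot <= 0:
            raise ValueError("empty distribution")
        c = c / tot
        # make strictly monotone for interpolation
        c = np.maximum.accumulate(c)
        return np.interp(p, c, self.grid)

    def mean(self) -> float:
        """Weighted first moment of the axis variable."""
        if self.discrete or self.grid.size == 1:
            return float((self.grid * self.density).sum() / self.density.sum())
        return float(np.trapezoid(self.grid * self.density, self.grid) / self.integral())

    def std(self) -> float:
        m = self.mean()
        if self.discrete or self.grid.size == 1:
            var = float(((self.grid - m) ** 2 * self.density).sum() / self.density.sum())
        else:
            var = float(
                np.trapezoid((self.grid - m) ** 2 * self.density, self.grid) / self.integral()
            )
        return np.sqrt(max(var, 0.0))

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass(frozen=True)
class LognormalFit:
    """Least-squares lognormal fit of a tabulated density.

    density(x) = amplitude / (x sigma sqrt(2 pi)) exp(-(ln x - ln median)^2 / (2 sigma^2))
    """

    median: float
    shape: float  # sigma of ln x
    amplitude: float
    rss: float

    @property
    def mean(self) -> float:
        return self.median * np.exp(self.shape**2 / 2.0)

    def pdf(self, x):
        x = np.asarray(x, float)
        return (
            self.amplitude
            / (x * self.shape * np.sqrt(2 * np.pi))
            * np.exp(-((np.log(x) - np.log(self.median)) ** 2) / (2 * self.shape**2))
        )


@dataclass(frozen=True)
class WeibullFit:
    """Least-squares Weibull fit of a tabulated density.

    density(x) = amplitude (k/lam) ((x-loc)/lam)^(k-1) exp(-((x-loc)/lam)^k)
    """

    shape: float
    scale: float
    loc: float
    amplitude: float
    rss: float

    def pdf(self, x):
        x = np.asarray(x, float)
        z = np.clip((x - self.loc) / self.scale, 0.0, None)
        with np.errstate(invalid="ignore"):
            out = self.amplitude * (self.shape / self.scale) * z ** (self.shape - 1) * np.exp(
                -(z**self.shape)
            )
        return np.where(z > 0, out, 0.0)


@dataclass(frozen=True)
class QuantileSummary:
    """Q10/Q50/Q90 of the cumulative distribution plus mode/mean/width.

    ``q50`` is the median of the cumulative distribution; ``mean`` is the
    weighted first moment (the two coincide only for symmetric shapes,
    and field usage labels either as the "mean").  Two width conventions
    are reported: half the Q10--Q90 span, and the weighted standard
    deviation; ``width`` is the half-span, the single-number convention
    used throughout this package.
    """

    q10: float
    q50: float
    q90: float
    mean: float
    mode: float
    width_half_span: float
    width_sd: float

    @property
    def width(self) -> float:
        return self.width_half_span


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def ingest_length_table(
    lengths_nm,
    min_length_nm: float = 50.0,
    bins: Optional[int] = 64,
) -> WeightedDistribution:
    """Build a number-weighted length distribution from AFM length records.

    Records below ``min_length_nm`` (the resolution limit of the image
    analysis, ~50 nm) are removed; the number removed is reported in
    ``metadata["n_removed"]``.  Surviving records are binned into
    ``bins`` equal-width bins spanning their range (density at bin
    centres); ``bins=None`` returns a discrete distribution with point
    masses at the unique recorded lengths.
    """
    lengths = np.asarray(lengths_nm, dtype=float)
    if lengths.ndim != 1:
        lengths = lengths.ravel()
    if lengths.size == 0:
        raise ValueError("no length records supplied")
    keep = lengths >= min_length_nm
    n_removed = int((~keep).sum())
    survivors = lengths[keep]
    if survivors.size == 0:
        raise ValueError(
            f"no records remain after the {min_length_nm:g} nm minimum-length filter "
            f"({n_removed} removed)"
        )
    meta = {"n_removed": n_removed, "n_records": int(survivors.size),
            "min_length_nm": float(min_length_nm)}

    if bins is None or np.unique(survivors).size == 1:
        vals, counts = np.unique(survivors, return_counts=True)
        dens = counts / counts.sum()
        return WeightedDistribution(
            "length", vals, dens, "number", discrete=True, metadata=meta
        )

    counts, edges = np.histogram(survivors, bins=int(bins))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    dens = counts / (counts.sum() * width)
    dist = WeightedDistribution("length", centers, dens, "number", metadata=meta)
    return dist.normalized()


# ---------------------------------------------------------------------------
# weighting conversion
# ---------------------------------------------------------------------------

def convert_weighting(
    dist: WeightedDistribution,
    target: str,
    lengths_nm=None,
) -> WeightedDistribution:
    """Convert the weighting basis of a distribution.

    At constant fibril height the per-particle mass is proportional to
    the length, so mass weight = number weight x l (the constant h^2
    cancels in the normalisation).  Extinction weighting equals mass
    weighting (equal extinction per subunit).  For a distribution over
    sedimentation coefficient the corresponding lengths must be supplied
    via ``lengths_nm`` (same shape as the grid), obtained from the
    inverse cylinder model.
    """
    if target not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {target!r}")
    if dist.weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {dist.weighting!r} on input")
    delta = _LENGTH_EXPONENT[target] - _LENGTH_EXPONENT[dist.weighting]
    if delta == 0:
        out = replace(dist, weighting=target)
        return out.normalized()
    if dist.axis_kind == "length":
        ell = dist.grid
    else:
        if lengths_nm is None:
            raise ValueError(
                "converting the weighting of an s-distribution requires the "
                "corresponding lengths (lengths_nm) from the inverse model"
            )
        ell = np.asarray(lengths_nm, dtype=float)
        if ell.shape != dist.grid.shape:
            raise ValueError("lengths_nm must match the distribution grid")
    dens = dist.density * ell**delta
    out = replace(dist, density=dens, weighting=target)
    return out.normalized()


# ---------------------------------------------------------------------------
# shape fits
# ---------------------------------------------------------------------------

def _check_fit_input(dist: WeightedDistribution) -> None:
    if int((dist.density > 0).sum()) < 5:
        raise ValueError("need at least 5 grid points with positive density to fit")


def fit_lognormal(dist: WeightedDistribution) -> LognormalFit:
    """Least-squares lognormal fit to the tabulated density."""
    _check_fit_input(dist)
    x, y = dist.grid, dist.density

    # moment-based initial guess on the positive part
    w = np.clip(y, 0, None)
    m = float((x * w).sum() / w.sum())
    lx = np.log(x)
    mu0 = float((lx * w).sum() / w.sum())
    s0 = float(np.sqrt(np.clip(((lx - mu0) ** 2 * w).sum() / w.sum(), 1e-4, None)))

    def model(x, median, shape, amp):
        return (
            amp
            / (x * shape * np.sqrt(2 * np.pi))
            * np.exp(-((np.log(x) - np.log(median)) ** 2) / (2 * shape**2))
        )

    try:
        popt, _ = curve_fit(
            model, x, y, p0=[np.exp(mu0), s0, 1.0],
            bounds=([x.min() * 1e-3, 1e-4, 1e-12], [x.max() * 1e3, 10.0, 1e6]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise ValueError(f"lognormal fit did not converge: {err}") from err
    rss = float(((model(x, *popt) - y) ** 2).sum())
    return LognormalFit(median=float(popt[0]), shape=float(popt[1]),
                        amplitude=float(popt[2]), rss=rss)


def fit_weibull(dist: WeightedDistribution, fit_loc: bool = False) -> WeibullFit:
    """Least-squares Weibull fit to the tabulated density.

    With ``fit_loc`` a location offset is fitted as well (useful for
    s-densities that only rise above a threshold).
    """
    _check_fit_input(dist)
    x, y = dist.grid, dist.density
    w = np.clip(y, 0, None)
    m = float((x * w).sum() / w.sum())
    sd = float(np.sqrt(np.clip(((x - m) ** 2 * w).sum() / w.sum(), 1e-12, None)))
    k0 = max(0.5, min(10.0, (m / sd) if sd > 0 else 2.0))
    loc0 = max(0.0, x.min() - 0.5 * sd) if fit_loc else 0.0

    def model_full(x, shape, scale, loc, amp):
        z = np.clip((x - loc) / scale, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = amp * (shape / scale) * z ** (shape - 1) * np.exp(-(z**shape))
        return np.where(z > 0, out, 0.0)

    try:
        if fit_loc:
            popt, _ = curve_fit(
                model_full, x, y, p0=[k0, max(m - loc0, sd), loc0, 1.0],
                bounds=([0.05, 1e-9, 0.0, 1e-12], [50.0, np.inf, x.max(), 1e6]),
                maxfev=20000,
            )
        else:
            popt_, _ = curve_fit(
                lambda x, shape, scale, amp: model_full(x, shape, scale, 0.0, amp),
                x, y, p0=[k0, m, 1.0],
                bounds=([0.05, 1e-9, 1e-12], [50.0, np.inf, 1e6]),
                maxfev=20000,
            )
            popt = [popt_[0], popt_[1], 0.0, popt_[2]]
    except RuntimeError as err:
        raise ValueError(f"Weibull fit did not converge: {err}") from err
    rss = float(((model_full(x, *popt) - y) ** 2).sum())
    return WeibullFit(shape=float(popt[0]), scale=float(popt[1]),
                      loc=float(popt[2]), amplitude=float(popt[3]), rss=rss)


# ---------------------------------------------------------------------------
# length <-> s mapping
# ---------------------------------------------------------------------------

def length_dist_to_s_dist(
    dist: WeightedDistribution,
    height_nm: float,
    material: FibrilMaterial = FibrilMaterial(),
    solvent: SolventConditions = SolventConditions(),
) -> WeightedDistribution:
    """Map a length distribution to sedimentation-coefficient space.

    Each grid length is pushed through the forward cylinder model at
    constant ``height_nm``; the density is transformed with the exact
    Jacobian |dl/ds| so the integral is conserved, then renormalised
    (the residual discretisation drift is recorded in
    ``metadata["renorm_drift"]``).  The mapping is monotone, so the
    weighting basis and all quantiles carry over unchanged.
    """
    if dist.axis_kind != "length":
        raise ValueError("input must be a length distribution")
    s_grid = ch.sedimentation_coefficient_svedberg(dist.grid, height_nm, material, solvent)
    if dist.discrete or dist.grid.size == 1:
        out = WeightedDistribution(
            "sedimentation_coefficient", s_grid, dist.density, dist.weighting,
            discrete=True, metadata=dict(dist.metadata),
        )
        return out.normalized()
    jac = ch.ds_dl(dist.grid, height_nm, material, solvent)  # dS/dl > 0
    dens = dist.density / jac
    out = WeightedDistribution(
        "sedimentation_coefficient", s_grid, dens, dist.weighting,
        metadata=dict(dist.metadata),
    )
    drift = out.integral() - dist.integral()
    out = out.normalized()
    out.metadata["renorm_drift"] = float(drift)
    out.metadata["height_nm"] = float(height_nm)
    return out


def s_dist_to_length_dist(
    dist: WeightedDistribution,
    height_nm: float,
    material: FibrilMaterial = FibrilMaterial(),
    solvent: SolventConditions = SolventConditions(),
) -> WeightedDistribution:
    """Map an s-distribution to length space through the inverse model.

    Grid points below the rod limit s(q = 1) at this height have no
    cylinder solution; they are excluded and the excluded weight
    fraction is reported in ``metadata["excluded_fraction"]``.
    """
    if dist.axis_kind != "sedimentation_coefficient":
        raise ValueError("input must be a sedimentation-coefficient distribution")
    s_min = float(
        ch.sedimentation_coefficient_svedberg(height_nm, height_nm, material, solvent)
    )
    ok = dist.grid >= s_min
    if not np.any(ok):
        raise ValueError(
            f"entire s-grid lies below the rod limit {s_min:g} S at h = {height_nm:g} nm"
        )
    total = dist.integral()
    sub = WeightedDistribution(
        dist.axis_kind, dist.grid[ok], dist.density[ok], dist.weighting,
        discrete=dist.discrete, metadata=dict(dist.metadata),
    )
    excluded = 1.0 - sub.integral() / total
    lengths = ch.length_from_s(sub.grid, height_nm, material, solvent)
    lengths = np.atleast_1d(lengths)
    if sub.discrete or sub.grid.size == 1:
        out = WeightedDistribution(
            "length", lengths, sub.density, sub.weighting, discrete=True,
            metadata=dict(sub.metadata),
        )
    else:
        jac = ch.ds_dl(lengths, height_nm, material, solvent)
        dens = sub.density * jac
        out = WeightedDistribution(
            "length", lengths, dens, sub.weighting, metadata=dict(sub.metadata)
        )
    out = out.normalized()
    out.metadata["excluded_fraction"] = float(max(excluded, 0.0))
    out.metadata["height_nm"] = float(height_nm)
    return out


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize(dist: WeightedDistribution) -> QuantileSummary:
    """Quantile summary of a (normalised) distribution."""
    d = dist.normalized()
    q10, q50, q90 = (float(q) for q in d.quantile([0.1, 0.5, 0.9]))
    return QuantileSummary(
        q10=q10,
        q50=q50,
        q90=q90,
        mean=d.mean(),
        mode=d.mode(),
        width_half_span=0.5 * (q90 - q10),
        width_sd=d.std(),
    )
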