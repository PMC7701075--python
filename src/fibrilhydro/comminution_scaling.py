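"""Scaling analysis of fibril fragmentation under rotor-stator stressing.

In top-down size reduction the mean fragment size follows a power law in
the volume-specific energy input, x = a E_V^(-b).  For a rotor-stator
disperser run in the turbulent regime the power draw scales as
P = Ne n^3 d_R^5 rho (constant Newton number Ne), so E_V ~ n^3 with n
the number of rotor revolutions, and the fibril length obeys

    l ~ E_V^(-b) ~ n^(-3b).

The size-reduction exponent b is obtained by ordinary least squares of
ln(length) on ln(n); b = -slope / 3.  The stress intensity of one
stressing experiment is indexed simply by its rotation count
n = (rpm / 60) x t_stress.

Reynolds/Newton-number helpers are provided as diagnostics of the
turbulence assumption; they are not required for the b fit (the rotor
diameter of the dispersing tool is a configuration input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cylinder_hydro import SolventConditions

__all__ = [
    "StressCondition",
    "ComminutionSeries",
    "PowerLawFit",
    "rotations",
    "reynolds",
    "newton_power",
    "energy_per_volume",
    "fit_size_reduction",
    "DEFAULT_EXCLUSIONS",
]

#: Conditions excluded from fitting by default: at 11,000 rpm for only
#: 5 s the flow pattern around the stirrer is not yet fully developed.
DEFAULT_EXCLUSIONS = ((11000.0, 5.0),)

#: Reynolds number above which a stirred system is considered turbulent
#: (Newton number approximately constant).
TURBULENT_REYNOLDS = 1e4


def rotations(rpm: float, t_stress_s: float) -> float:
    """Number of rotor revolutions during one stressing experiment."""
    if rpm < 0 or t_stress_s < 0:
        raise ValueError("rotational speed and stressing time must be non-negative")
    return rpm / 60.0 * t_stress_s


@dataclass(frozen=True)
class StressCondition:
    """One rotor-stator stressing condition."""

    rpm: float
    t_stress_s: float
    rotor_diameter_m: Optional[float] = None
    volume_m3: Optional[float] = None

    @property
    def n_rotations(self) -> float:
        return rotations(self.rpm, self.t_stress_s)


@dataclass
class ComminutionSeries:
    """Characteristic fibril lengths across stressing conditions.

    ``table`` columns: rpm, seconds, length_nm, statistic (mean|modal),
    source (AFM|AUC).
    """

    table: pd.DataFrame

    REQUIRED = ("rpm", "seconds", "length_nm", "statistic", "source")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"comminution table is missing columns: {missing}")
        if (self.table["length_nm"] <= 0).any():
            raise ValueError("lengths must be positive")

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "ComminutionSeries":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))


@dataclass(frozen=True)
class PowerLawFit:
    """Result of the ln-ln regression of length on rotation count.

    ``b = -slope / 3`` via E_V ~ n^3; ``prefactor`` is exp(intercept),
    the length at n = 1 in nm.
    """

    prefactor: float
    slope: float
    b: float
    stderr_slope: float
    stderr_b: float
    residual_se: float
    n_points: int
    excluded: tuple
    statistic: Optional[str] = None
    source: Optional[str] = None


def reynolds(
    n_rev_s: float,
    rotor_diameter_m: float,
    solvent: SolventConditions = SolventConditions(),
) -> tuple:
    """Stirrer Reynolds number Re = n d_R^2 rho / eta and turbulence flag."""
    if n_rev_s <= 0 or rotor_diameter_m <= 0:
        raise ValueError("revolution rate and rotor diameter must be positive")
    re = n_rev_s * rotor_diameter_m**2 * solvent.density / solvent.viscosity
    return re, re > TURBULENT_REYNOLDS


def newton_power(
    newton_number: float,
    n_rev_s: float,
    rotor_diameter_m: float,
    solvent: SolventConditions = SolventConditions(),
) -> float:
    """Power draw P = Ne n^3 d_R^5 rho [W]."""
    if newton_number <= 0 or n_rev_s <= 0 or rotor_diameter_m <= 0:
        raise ValueError("Newton number, revolution rate and diameter must be positive")
    return newton_number * n_rev_s**3 * rotor_diameter_m**5 * solvent.density


def energy_per_volume(power_w: float, t_s: float, volume_m3: float) -> float:
    """Volume-specific energy input E_V = P t / V [J m^-3]."""
    if power_w <= 0 or t_s <= 0 or volume_m3 <= 0:
        raise ValueError("power, time and volume must be positive")
    return power_w * t_s / volume_m3


def fit_size_reduction(
    series: ComminutionSeries,
    exclude: Sequence[tuple] = DEFAULT_EXCLUSIONS,
    statistic: Optional[str] = None,
    source: Optional[str] = None,
) -> PowerLawFit:
    """Fit l = a n^(-3b) by ordinary least squares in ln-ln space.

    ``exclude`` lists (rpm, seconds) conditions left out of the fit; by
    default the 11,000 rpm / 5 s point (flow pattern not fully
    developed).  ``statistic``/``source`` filter the series to one
    length statistic (mean or modal) and one measurement technique.
    Exclusions are explicit and echoed in the result; there is no
    automatic outlier rejection.
    """
    df = series.table
    if statistic is not None:
        df = df[df["statistic"] == statistic]
    if source is not None:
        df = df[df["source"] == source]
    mask = np.ones(len(df), dtype=bool)
    for rpm, secs in exclude:
        mask &= ~(np.isclose(df["rpm"], rpm) & np.isclose(df["seconds"], secs))
    df = df[mask]
    if len(df) < 3:
        raise ValueError(
            f"need at least 3 data points after exclusions, have {len(df)}"
        )
    n = np.array([rotations(r, t) for r, t in zip(df["rpm"], df["seconds"])])
    if np.unique(n).size < 2:
        raise ValueError("need at least two distinct rotation counts")
    x = np.log(n)
    y = np.log(df["length_nm"].to_numpy(float))
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    dof = max(len(df) - 2, 1)
    res_se = float(np.sqrt((resid**2).sum() / dof))
    se_slope = res_se / np.sqrt(sxx)
    return PowerLawFit(
        prefactor=float(np.exp(intercept)),
        slope=float(slope),
        b=float(-slope / 3.0),
        stderr_slope=se_slope,
        stderr_b=se_slope / 3.0,
        residual_se=res_se,
        n_points=int(len(df)),
        excluded=tuple(tuple(e) for e in exclude),
        statistic=statistic,
        source=source,
    )
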