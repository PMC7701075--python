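"""Hydrodynamic model for sedimenting rigid circular cylinders.

A fragmented amyloid fibril is treated as a rigid rod of length ``l`` and
height ``h`` (the cylinder diameter), with aspect ratio ``q = l/h >= 1``.
Its sedimentation coefficient follows from Stokes drag on the
equal-volume sphere, corrected by the cylinder frictional ratio ``f/f0``,
a quartic-plus-septic polynomial in ``k = ln q`` (Hansen's numerical
result for translational friction of cylinders):

    s = d_eq^2 (rho_F_eff - rho_S) / (18 eta (f/f0))

where ``d_eq = (3 h^2 l / 2)^(1/3)`` is the diameter of the sphere with
the cylinder's volume, ``rho_F_eff`` the effective (hydrated, densified)
fibril density, ``rho_S`` and ``eta`` the solvent density and viscosity.

``s`` is strictly increasing in length at fixed height, which makes the
inverse map (length from a measured ``s``) well posed; it is solved by
bracketed root finding on ``ln q``.

All functions in this module work in SI units; Svedberg (1 S = 1e-13 s)
and nanometres appear only in explicitly suffixed helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import (
    AVOGADRO,
    BLG_DENSITY,
    FIBRIL_DENSIFICATION,
    SVEDBERG,
    WATER_DENSITY_20C,
    WATER_VISCOSITY_20C,
)

__all__ = [
    "CylinderGeometry",
    "SolventConditions",
    "FibrilMaterial",
    "NeutralBuoyancyWarning",
    "friction_ratio",
    "equivalent_sphere_diameter",
    "sedimentation_coefficient",
    "sedimentation_coefficient_svedberg",
    "length_from_s",
    "cylinder_molar_mass",
]

#: Polynomial coefficients of the cylinder frictional ratio in k = ln(q):
#: f/f0 = c0 + c1 k + c2 k^2 + c3 k^3 + c4 k^4 + c7 k^7
_FRICTION_COEFFS = {
    0: 1.0304,
    1: 0.0193,
    2: 0.06229,
    3: 0.00476,
    4: 0.00166,
    7: 2.66e-6,
}


class NeutralBuoyancyWarning(UserWarning):
    """Particle density equals solvent density: nothing sediments."""


@dataclass(frozen=True)
class CylinderGeometry:
    """Rigid circular cylinder standing in for a fragmented fibril.

    Parameters
    ----------
    length : float
        Cylinder length in metres.
    height : float
        Cylinder diameter ("height" in the AFM sense) in metres.
    """

    length: float
    height: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.length) and self.length > 0):
            raise ValueError(f"length must be positive and finite, got {self.length}")
        if not (np.isfinite(self.height) and self.height > 0):
            raise ValueError(f"height must be positive and finite, got {self.height}")
        if self.length < self.height:
            raise ValueError(
                "aspect ratio q = length/height must be >= 1 (rods, not disks); "
                f"got l = {self.length} m, h = {self.height} m"
            )

    @property
    def aspect_ratio(self) -> float:
        """q = l / h, always derived from the stored dimensions."""
        return self.length / self.height

    @property
    def k(self) -> float:
        """ln(q), the variable of the frictional-ratio polynomial."""
        return float(np.log(self.aspect_ratio))

    @property
    def volume(self) -> float:
        """Cylinder volume pi h^2 l / 4 in m^3."""
        return np.pi * self.height**2 * self.length / 4.0

    @classmethod
    def from_nm(cls, length_nm: float, height_nm: float) -> "CylinderGeometry":
        return cls(length_nm * 1e-9, height_nm * 1e-9)


@dataclass(frozen=True)
class SolventConditions:
    """Density and viscosity of the aqueous phase.

    Defaults are water at 20 degC, the measurement temperature; dilute
    pH-2 HCl is indistinguishable from water at this precision.
    """

    density: float = WATER_DENSITY_20C  # kg m^-3
    viscosity: float = WATER_VISCOSITY_20C  # Pa s
    temperature_c: float = 20.0  # informational

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"solvent density must be positive, got {self.density}")
        if self.viscosity <= 0:
            raise ValueError(f"solvent viscosity must be positive, got {self.viscosity}")


@dataclass(frozen=True)
class FibrilMaterial:
    """Effective material properties of the sedimenting fibril.

    ``base_density`` defaults to the inverse partial specific volume of
    beta-lactoglobulin; ``densification`` is the multiplicative increase
    of the packed fibril structure over the native protein.  Hydration is
    carried entirely by the effective height and effective density; there
    is no separate shell model.
    """

    base_density: float = BLG_DENSITY  # kg m^-3
    densification: float = FIBRIL_DENSIFICATION  # dimensionless

    def __post_init__(self) -> None:
        if self.base_density <= 0:
            raise ValueError(f"base density must be positive, got {self.base_density}")
        if self.densification <= 0:
            raise ValueError(f"densification must be positive, got {self.densification}")

    @property
    def effective_density(self) -> float:
        """rho_F_eff = base_density x densification [kg m^-3]."""
        return self.base_density * self.densification


def friction_ratio(q):
    """Frictional ratio f/f0 of a cylinder with aspect ratio ``q``.

    Evaluates the polynomial in ``k = ln q`` with coefficients 1.0304,
    0.0193, 0.06229, 0.00476, 0.00166 (k^0..k^4) and 2.66e-6 (k^7).
    Valid for rods, ``q >= 1``; the polynomial is not validated for
    disks and raises there.
    """
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("aspect ratio must be finite")
    if np.any(q < 1.0):
        raise ValueError("friction_ratio is only defined for rods (q >= 1)")
    k = np.log(q)
    out = sum(c * k**p for p, c in _FRICTION_COEFFS.items())
    return out if out.ndim else float(out)


def _deq(length, height):
    """Diameter of the sphere with the cylinder's volume [m].

    From pi h^2 l / 4 = pi d^3 / 6:  d = (3 h^2 l / 2)^(1/3),
    equivalently (3 h^3 q / 2)^(1/3) or (3 l^3 / (2 q^2))^(1/3).
    """
    return (1.5 * np.asarray(height, float) ** 2 * np.asarray(length, float)) ** (1.0 / 3.0)


def equivalent_sphere_diameter(geom: CylinderGeometry) -> float:
    """Equal-volume sphere diameter of a cylinder [m]."""
    return float(_deq(geom.length, geom.height))


def _sed_rate(length, height, effective_density, solvent: SolventConditions):
    """Vectorised sedimentation coefficient in seconds."""
    q = np.asarray(length, float) / np.asarray(height, float)
    ffo = friction_ratio(q)
    deq = _deq(length, height)
    return deq**2 * (effective_density - solvent.density) / (18.0 * solvent.viscosity * ffo)


def sedimentation_coefficient(
    geom: CylinderGeometry,
    material: FibrilMaterial = FibrilMaterial(),
    solvent: SolventConditions = SolventConditions(),
) -> float:
    """Sedimentation coefficient of a rigid cylinder, in seconds.

    Positive when the fibril is denser than the solvent; exactly zero
    (with a :class:`NeutralBuoyancyWarning`) at matching densities.
    """
    if material.effective_density == solvent.density:
        warnings.warn(
            "effective fibril density equals solvent density; s = 0",
            NeutralBuoyancyWarning,
            stacklevel=2,
        )
        return 0.0
    return float(_sed_rate(geom.length, geom.height, material.effective_density, solvent))


def sedimentation_coefficient_svedberg(
    length_nm: float,
    height_nm: float,
    material: FibrilMaterial = FibrilMaterial(),
    solvent: SolventConditions = SolventConditions(),
):
    """Interface helper: s in Svedberg from dimensions in nm.

    Accepts scalars or arrays (fully vectorised); the array form backs
    the distribution-mapping machinery.
    """
    return _sed_rate(
        np.asarray(length_nm, float) * 1e-9,
        np.asarray(height_nm, float) * 1e-9,
        material.effective_density,
        solvent,
    ) / SVEDBERG


def ds_dl(
    length_nm,
    height_nm: float,
    material: FibrilMaterial = FibrilMaterial(),
    solvent: SolventConditions = SolventConditions(),
):
    """Derivative of s [S] with respect to length [nm] at fixed height.

    Central difference with a relative step of 1e-6; the forward model is
    smooth so this is accurate to ~1e-10 relative, which is what the
    Jacobian-based density transforms need.
    """
    length_nm = np.asarray(length_nm, float)
    h = 1e-6 * length_nm
    up = sedimentation_coefficient_svedberg(length_nm + h, height_nm, material, solvent)
    dn = sedimentation_coefficient_svedberg(length_nm - h, height_nm, material, solvent)
    return (up - dn) / (2.0 * h)


def length_from_s(
    s_svedberg,
    height_nm: float,
    material: FibrilMaterial = FibrilMaterial(),
    solvent: SolventConditions = SolventConditions(),
    rtol: float = 1e-12,
):
    """Invert the forward model: cylinder length [nm] giving ``s`` [S].

    The forward model is strictly increasing in length at fixed height,
    so the root is unique.  Bracketing starts on q in [1, 1e6] and the
    upper bound is expanded if needed.  Raises for ``s`` below the rod
    limit s(q = 1) at this height (no rod solution).
    """
    s_arr = np.atleast_1d(np.asarray(s_svedberg, dtype=float))
    if np.any(~np.isfinite(s_arr)) or np.any(s_arr <= 0):
        raise ValueError("s must be positive and finite")
    if height_nm <= 0:
        raise ValueError("height must be positive")

    s_min = float(sedimentation_coefficient_svedberg(height_nm, height_nm, material, solvent))
    if np.any(s_arr < s_min * (1.0 - 1e-12)):
        bad = float(np.min(s_arr))
        raise ValueError(
            f"s = {bad:g} S is below the rod limit s(q=1) = {s_min:g} S at "
            f"h = {height_nm:g} nm; no rod solution exists"
        )

    def solve_one(s_target: float) -> float:
        if s_target <= s_min:
            return height_nm

        def f(ln_q: float) -> float:
            l_nm = height_nm * np.exp(ln_q)
            return float(
                sedimentation_coefficient_svedberg(l_nm, height_nm, material, solvent)
            ) - s_target

        lo, hi = 0.0, np.log(1e6)
        while f(hi) < 0:
            hi += np.log(10.0)
            if hi > np.log(1e12):  # pragma: no cover - physically absurd
                raise ValueError(f"no rod solution found for s = {s_target:g} S")
        ln_q = brentq(f, lo, hi, xtol=1e-14, rtol=rtol)
        return height_nm * float(np.exp(ln_q))

    out = np.array([solve_one(s) for s in s_arr])
    return float(out[0]) if np.isscalar(s_svedberg) or np.asarray(s_svedberg).ndim == 0 else out


def cylinder_molar_mass(
    geom: CylinderGeometry, material: FibrilMaterial = FibrilMaterial()
) -> float:
    """Molar mass of the cylinder in Da (g/mol).

    rho_F_eff x (pi/4) h^2 l x N_A.  Used to justify neglecting
    diffusion for fibril-sized species in sedimentation-velocity
    experiments.
    """
    mass_kg = material.effective_density * geom.volume
    return mass_kg * AVOGADRO * 1e3  # kg/mol -> g/mol (Da)
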