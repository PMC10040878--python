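"""Forward mechanical model of the aortic wall.

The pressurised abdominal aorta is treated as a thin-walled (membrane),
incompressible cylinder.  Two independent stress computations exist:

* **Equilibrium (Laplace) stresses** depend only on the applied pressure
  and the geometry (inner radius, wall cross-sectional area, axial force);
  they are statically determined and independent of material properties::

      sigma_theta_lp = (4 pi r0^2 + A) P / (2 A)
      sigma_z_lp     = (pi r0^2 P + F) / A

* **Constitutive stresses** follow from the Holzapfel-Gasser-Ogden strain
  energy (neo-Hookean matrix plus one exponential term for two symmetric
  collagen-fiber families)::

      psi = c (I1 - 3) + (k1 / k2) (exp(k2 (I - 1)^2) - 1)

  with ``I1 = lt^2 + lz^2 + (lt lz)^-2`` and
  ``I = lt^2 cos^2 b + lz^2 sin^2 b``.  The incompressibility multiplier
  ``p = 2 c (lt lz)^-2`` is fixed by a vanishing transmural (radial) stress,
  giving the isotropic/anisotropic split implemented below.

All quantities are SI (m, Pa, N); functions are vectorised over the inner
radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import ModelParameters, WallGeometry, AxialReference
from .units import M2_PER_MM2

__all__ = [
    "area_from_age",
    "axial_force",
    "laplace_stresses",
    "midwall_stretch",
    "kinematics",
    "constitutive_stresses",
    "pressure_from_radius",
    "solve_radius",
    "KinematicState",
    "LaplaceStress",
    "StressDecomposition",
]

# Cross-sectional-area-vs-age regression coefficients (mm^2, mm^2/yr),
# from population studies of the abdominal aorta.
_AREA_REGRESSION = {
    "male": (19.60, 0.80),
    "female": (20.52, 0.56),
}


def area_from_age(age: float, sex: str) -> float:
    """Wall cross-sectional area (m^2) from the age-sex regression.

    ``A = 19.60 + 0.80 * age`` (males) and ``A = 20.52 + 0.56 * age``
    (females), with age in years and A in mm^2, converted to m^2.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    try:
        intercept, slope = _AREA_REGRESSION[sex]
    except KeyError:
        raise ValueError(
            f"unknown sex {sex!r}; expected 'male' or 'female'"
        ) from None
    return (intercept + slope * age) * M2_PER_MM2


def axial_force(gamma: float, p_ref: float, r_ref: float, area: float) -> float:
    """In-situ axial force F (N) from a known reference stress ratio.

    Assuming the axial force is pressure-independent and the ratio
    ``gamma = sigma_z_lp / sigma_theta_lp`` is known at one reference
    pressure ``p_ref`` with inner radius ``r_ref``::

        F = pi r_ref^2 p_ref (2 gamma + gamma A / (2 pi r_ref^2) - 1)

    Substituting F back into the Laplace stresses at the reference state
    reproduces ``gamma`` identically.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    if p_ref <= 0 or r_ref <= 0:
        raise ValueError("reference pressure and radius must be positive")
    if area <= 0:
        raise ValueError("wall cross-sectional area must be positive")
    disc = np.pi * r_ref**2
    return disc * p_ref * (2.0 * gamma + gamma * area / (2.0 * disc) - 1.0)


def axial_force_from_reference(axial: AxialReference, geom: WallGeometry) -> float:
    """Convenience wrapper taking the dataclass records."""
    if axial.r_ref is None:
        raise ValueError("AxialReference.r_ref must be set before computing F")
    return axial_force(axial.gamma, axial.p_ref, axial.r_ref, geom.area)


@dataclass(frozen=True)
class LaplaceStress:
    """Membrane equilibrium stresses (Pa); scalars or arrays."""

    sigma_theta_lp: np.ndarray
    sigma_z_lp: np.ndarray


def laplace_stresses(r0, pressure, area: float, force: float) -> LaplaceStress:
    """Laplace-law membrane stresses at inner radius ``r0`` and pressure ``P``.

    Independent of the material model; requires the axial force F to be
    known (see :func:`axial_force`).
    """
    if area <= 0:
        raise ValueError("wall cross-sectional area must be positive")
    r0 = np.asarray(r0, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    s_theta = (4.0 * np.pi * r0**2 + area) * pressure / (2.0 * area)
    s_z = (np.pi * r0**2 * pressure + force) / area
    return LaplaceStress(s_theta, s_z)


def midwall_stretch(r0, r0_unloaded: float, lambda_z: float, area: float):
    """Mid-wall circumferential stretch.

    ``lambda_theta = (R0 / r0) (4 pi r0^2 + A) / (4 pi R0^2 + lambda_z A)``,
    where R0 is the unloaded inner radius and the area terms place the
    stretch at mid-wall thickness under incompressibility.
    """
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0) or r0_unloaded <= 0:
        raise ValueError("radii must be positive")
    num = 4.0 * np.pi * r0**2 + area
    den = 4.0 * np.pi * r0_unloaded**2 + lambda_z * area
    return (r0_unloaded / r0) * num / den


@dataclass(frozen=True)
class KinematicState:
    """Stretches, invariants, strain energy and pressure multiplier."""

    lambda_theta: np.ndarray
    lambda_z: float
    i1: np.ndarray
    i4: np.ndarray  # fiber invariant I
    psi: np.ndarray  # Pa
    p_multiplier: np.ndarray  # Pa


def kinematics(r0, params: ModelParameters, area: float) -> KinematicState:
    """Evaluate the kinematic state of the mid-wall at inner radius ``r0``."""
    if params.k2 == 0:
        raise ValueError("k2 must be nonzero (division by zero in the fiber term)")
    lt = midwall_stretch(r0, params.r0_unloaded, params.lambda_z, area)
    lz = params.lambda_z
    i1 = lt**2 + lz**2 + (lt * lz) ** -2
    cb2 = np.cos(params.beta_rad) ** 2
    sb2 = np.sin(params.beta_rad) ** 2
    i4 = lt**2 * cb2 + lz**2 * sb2
    if np.any(i4 < 1.0):
        warnings.warn(
            "fiber invariant I < 1 (fibers shorter than unloaded length); "
            "the exponential term is evaluated as printed, without a "
            "tension-only switch",
            RuntimeWarning,
            stacklevel=2,
        )
    psi = params.c * (i1 - 3.0) + (params.k1 / params.k2) * (
        np.exp(params.k2 * (i4 - 1.0) ** 2) - 1.0
    )
    p_mult = 2.0 * params.c * (lt * lz) ** -2
    return KinematicState(lt, lz, i1, i4, psi, p_mult)


@dataclass(frozen=True)
class StressDecomposition:
    """Constitutive stresses (Pa) split into isotropic and anisotropic parts.

    Totals are exact sums of the parts in each direction.
    """

    sigma_theta_iso: np.ndarray
    sigma_theta_aniso: np.ndarray
    sigma_z_iso: np.ndarray
    sigma_z_aniso: np.ndarray

    @property
    def sigma_theta_tot(self):
        return self.sigma_theta_iso + self.sigma_theta_aniso

    @property
    def sigma_z_tot(self):
        return self.sigma_z_iso + self.sigma_z_aniso

    def __sub__(self, other: "StressDecomposition") -> "StressDecomposition":
        return StressDecomposition(
            self.sigma_theta_iso - other.sigma_theta_iso,
            self.sigma_theta_aniso - other.sigma_theta_aniso,
            self.sigma_z_iso - other.sigma_z_iso,
            self.sigma_z_aniso - other.sigma_z_aniso,
        )


def constitutive_stresses(
    r0, params: ModelParameters, area: float
) -> StressDecomposition:
    """HGO membrane stresses with the iso/aniso split.

    With the multiplier ``p = 2 c (lt lz)^-2`` (zero transmural stress)::

        sigma_theta_iso   = 2 c (lt^2 - (lt lz)^-2)
        sigma_theta_aniso = 4 k1 (I-1) exp(k2 (I-1)^2) lt^2 cos^2 b
        sigma_z_iso       = 2 c (lz^2 - (lt lz)^-2)
        sigma_z_aniso     = 4 k1 (I-1) exp(k2 (I-1)^2) lz^2 sin^2 b
    """
    kin = kinematics(r0, params, area)
    lt, lz = kin.lambda_theta, kin.lambda_z
    inv2 = (lt * lz) ** -2
    fiber = 4.0 * params.k1 * (kin.i4 - 1.0) * np.exp(params.k2 * (kin.i4 - 1.0) ** 2)
    cb2 = np.cos(params.beta_rad) ** 2
    sb2 = np.sin(params.beta_rad) ** 2
    return StressDecomposition(
        sigma_theta_iso=2.0 * params.c * (lt**2 - inv2),
        sigma_theta_aniso=fiber * lt**2 * cb2,
        sigma_z_iso=2.0 * params.c * (lz**2 - inv2),
        sigma_z_aniso=fiber * lz**2 * sb2,
    )


def pressure_from_radius(r0, params: ModelParameters, area: float):
    """Lumen pressure implied by the constitutive model at radius ``r0``.

    Inverts the circumferential Laplace relation with the constitutive
    total stress: ``P = 2 A sigma_theta_tot / (4 pi r0^2 + A)``.  Feeding
    the result back into :func:`laplace_stresses` reproduces
    ``sigma_theta_tot`` identically.
    """
    r0 = np.asarray(r0, dtype=float)
    s_theta = constitutive_stresses(r0, params, area).sigma_theta_tot
    return 2.0 * area * s_theta / (4.0 * np.pi * r0**2 + area)


def solve_radius(
    params: ModelParameters,
    area: float,
    p_target: float,
    bracket: tuple[float, float] | None = None,
    xtol: float = 1e-12,
) -> float:
    """Inner radius at which the model produces ``p_target`` (Pa).

    Bracketed root finding on ``pressure_from_radius``.  Without an explicit
    bracket, the search starts just above the radius of unit circumferential
    stretch (where the model pressure vanishes) and expands upward.
    """

    def f(r):
        return float(pressure_from_radius(r, params, area) - p_target)

    if bracket is None:
        # radius of unit mid-wall stretch: below it the wall is compressed
        r_star = max(np.sqrt(area / (4.0 * np.pi)), params.r0_unloaded * 0.2)
        try:
            r_unit = brentq(
                lambda r: float(
                    midwall_stretch(r, params.r0_unloaded, params.lambda_z, area) - 1.0
                ),
                r_star,
                50.0 * params.r0_unloaded,
            )
        except ValueError:
            r_unit = params.r0_unloaded
        lo = r_unit * (1.0 + 1e-9)
        hi = r_unit * 1.05
        for _ in range(200):
            if f(hi) > 0:
                break
            hi *= 1.05
        else:
            raise ValueError("could not bracket the target pressure")
        bracket = (lo, hi)
    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    # allow modest outward expansion when the fitted model's range is tight
    grow = 0
    while flo * fhi > 0 and grow < 60:
        lo *= 0.99
        hi *= 1.01
        flo, fhi = f(lo), f(hi)
        grow += 1
    if flo * fhi > 0:
        raise ValueError(
            f"target pressure {p_target:.1f} Pa not bracketed by radii "
            f"[{lo:.4g}, {hi:.4g}] m"
        )
    return float(brentq(f, lo, hi, xtol=xtol))
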