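"""Model parameters, box bounds and small geometry records.

The constitutive model is parameterised by the six-vector
``kappa = (c, k1, k2, beta, R0, lambda_z)``:

* ``c`` (Pa) - stiffness of the isotropic matrix (mainly elastin),
* ``k1`` (Pa) - stiffness of the fiber (collagen) families,
* ``k2`` (-) - exponential fiber parameter (crimp/cross-linking),
* ``beta`` (deg) - mean fiber angle from the circumferential direction,
* ``R0`` (m) - unloaded, stress-free inner radius,
* ``lambda_z`` (-) - in-situ axial pre-stretch.

Internally SI units are used throughout (Pa, m); degrees are kept for
``beta`` because the fitting-range table is stated in degrees, and the
conversion to radians happens inside the trigonometric evaluation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .units import M_PER_MM, M2_PER_MM2, PA_PER_KPA

VALID_SEXES = ("male", "female")

#: Component order used whenever parameters travel as a plain vector.
PARAMETER_NAMES = ("c", "k1", "k2", "beta_deg", "r0_unloaded", "lambda_z")


@dataclass(frozen=True)
class ModelParameters:
    """HGO membrane model parameter vector (SI units internally)."""

    c: float  # Pa
    k1: float  # Pa
    k2: float  # dimensionless
    beta_deg: float  # degrees
    r0_unloaded: float  # m
    lambda_z: float  # dimensionless

    @property
    def beta_rad(self) -> float:
        return float(np.deg2rad(self.beta_deg))

    @classmethod
    def from_clinical(cls, c_kpa, k1_kpa, k2, beta_deg, r0_mm, lambda_z):
        """Build from the units used in clinical tables (kPa, mm, deg)."""
        return cls(
            c=c_kpa * PA_PER_KPA,
            k1=k1_kpa * PA_PER_KPA,
            k2=k2,
            beta_deg=beta_deg,
            r0_unloaded=r0_mm * M_PER_MM,
            lambda_z=lambda_z,
        )

    def as_array(self) -> np.ndarray:
        """Vector in :data:`PARAMETER_NAMES` order (SI units)."""
        return np.array(
            [self.c, self.k1, self.k2, self.beta_deg, self.r0_unloaded, self.lambda_z]
        )

    @classmethod
    def from_array(cls, x) -> "ModelParameters":
        c, k1, k2, beta_deg, r0, lz = (float(v) for v in x)
        return cls(c, k1, k2, beta_deg, r0, lz)

    def perturbed(self, name: str, factor: float) -> "ModelParameters":
        """Return a copy with one component multiplied by ``factor``."""
        if name not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        return dataclasses.replace(self, **{name: getattr(self, name) * factor})


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for ``kappa`` in :data:`PARAMETER_NAMES` order, SI units."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        if lo.shape != (6,) or up.shape != (6,):
            raise ValueError("bounds must be length-6 vectors")
        if np.any(lo > up):
            raise ValueError("lower bound exceeds upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @classmethod
    def default(cls) -> "ParameterBounds":
        """The standard fitting ranges.

        c, k1 in [1e-4, 5e5] kPa; k2 in [1e-4, 1e3]; beta in [1e-6, 90] deg;
        R0 in [1, 20] mm; lambda_z in [1, 5] (lower bound one to avoid
        buckling).
        """
        lower = np.array([1e-4 * PA_PER_KPA, 1e-4 * PA_PER_KPA, 1e-4, 1e-6, 1e-3, 1.0])
        upper = np.array([5e5 * PA_PER_KPA, 5e5 * PA_PER_KPA, 1e3, 90.0, 20e-3, 5.0])
        return cls(lower, upper)

    def contains(self, params: ModelParameters, rtol: float = 1e-9) -> bool:
        x = params.as_array()
        lo_ok = x >= self.lower - rtol * np.abs(self.lower)
        up_ok = x <= self.upper + rtol * np.abs(self.upper)
        return bool(np.all(lo_ok) and np.all(up_ok))


@dataclass(frozen=True)
class WallGeometry:
    """Wall cross-sectional area A (m^2) with its provenance."""

    area: float
    source: str = "given"  # "regression" | "given"

    def __post_init__(self):
        if not self.area > 0:
            raise ValueError(f"wall cross-sectional area must be positive, got {self.area}")


@dataclass(frozen=True)
class AxialReference:
    """Reference state fixing the in-situ axial force.

    The longitudinal-to-circumferential membrane stress ratio ``gamma`` is
    assumed known at one reference pressure ``p_ref`` with the corresponding
    inner radius ``r_ref``; the axial force ``force`` follows in closed form.
    """

    gamma: float = 0.59
    p_ref: float = 13.3e3  # Pa
    r_ref: float | None = None  # m, measured radius at p_ref
    force: float | None = None  # N, filled in once computed

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if not self.p_ref > 0:
            raise ValueError("reference pressure must be positive")
        if self.r_ref is not None and not self.r_ref > 0:
            raise ValueError("reference radius must be positive")
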