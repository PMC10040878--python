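"""Derived hemodynamic and stress metrics.

All "computed variables" of the analysis: systolic/diastolic/mean arterial
pressure and pulse pressure from the averaged loop; the stress
decomposition evaluated at SBP, DBP and MAP; pulsatile stresses
(systolic minus diastolic, per component); and load-bearing fractions
(component over total, per direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import mechanics
from .containers import AveragedLoop
from .mechanics import StressDecomposition
from .parameters import ModelParameters

__all__ = [
    "HemodynamicSummary",
    "hemodynamic_summary",
    "stress_at_pressure",
    "LoadBearingFractions",
    "DerivedStressMetrics",
    "pulsatile_and_fractions",
]


@dataclass(frozen=True)
class HemodynamicSummary:
    """Pressures (Pa) and extremal radii (m) of an averaged loop.

    MAP follows the standard one-third rule ``DBP + (SBP - DBP)/3``;
    pulse pressure is ``SBP - DBP``.
    """

    sbp: float
    dbp: float
    map: float
    pp: float
    r_at_sbp: float
    r_at_dbp: float


def hemodynamic_summary(
    loop: AveragedLoop, allow_flat: bool = False
) -> HemodynamicSummary:
    """SBP, DBP, MAP and PP from the averaged loop.

    SBP/DBP are the loop's pressure extrema and the radii are taken at the
    extremal samples.  A flat loop is rejected unless ``allow_flat`` (used
    only for degenerate unit checks).
    """
    p = loop.pressure
    i_max = int(np.argmax(p))
    i_min = int(np.argmin(p))
    sbp, dbp = float(p[i_max]), float(p[i_min])
    if sbp == dbp and not allow_flat:
        raise ValueError("flat pressure loop: SBP equals DBP")
    pp = sbp - dbp
    return HemodynamicSummary(
        sbp=sbp,
        dbp=dbp,
        map=dbp + pp / 3.0,
        pp=pp,
        r_at_sbp=float(loop.radius[i_max]),
        r_at_dbp=float(loop.radius[i_min]),
    )


def stress_at_pressure(
    kappa: ModelParameters,
    area: float,
    p_target: float,
    loop: AveragedLoop,
    xtol: float = 1e-12,
) -> StressDecomposition:
    """Constitutive stress decomposition at a target pressure (Pa).

    The radius is solved from the fitted model's pressure-radius relation
    by bracketed root finding over the loop's radius range (with a small
    outward expansion allowance since the fitted model need not reproduce
    the loop extrema exactly), then the decomposition is evaluated there.
    The target must lie within the loop's pressure range.
    """
    p = loop.pressure
    if not (p.min() <= p_target <= p.max()):
        raise ValueError(
            f"target pressure {p_target:.1f} Pa outside loop range "
            f"[{p.min():.1f}, {p.max():.1f}] Pa"
        )
    r = mechanics.solve_radius(
        kappa,
        area,
        p_target,
        bracket=(float(loop.radius.min()), float(loop.radius.max())),
        xtol=xtol,
    )
    return mechanics.constitutive_stresses(r, kappa, area)


@dataclass(frozen=True)
class LoadBearingFractions:
    """Isotropic and anisotropic share of the total stress (sum to one)."""

    iso: float
    aniso: float


@dataclass
class DerivedStressMetrics:
    """Stress decompositions at SBP/DBP, pulsatile stresses and fractions.

    ``undefined`` lists the direction/pressure combinations whose total
    stress vanished, making the fraction undefined (stored as NaN, never
    silently).
    """

    at_sbp: StressDecomposition
    at_dbp: StressDecomposition
    pulsatile: StressDecomposition
    fractions_sbp: dict
    fractions_dbp: dict
    fractions_pulsatile: dict
    undefined: list = field(default_factory=list)


def _fractions(dec: StressDecomposition, label: str, undefined: list) -> dict:
    out = {}
    for direction, iso, aniso in (
        ("theta", float(np.asarray(dec.sigma_theta_iso)), float(np.asarray(dec.sigma_theta_aniso))),
        ("z", float(np.asarray(dec.sigma_z_iso)), float(np.asarray(dec.sigma_z_aniso))),
    ):
        tot = iso + aniso
        if tot == 0.0:
            undefined.append(f"{direction}@{label}")
            warnings.warn(
                f"zero total stress in direction {direction} at {label}: "
                "load-bearing fraction undefined",
                RuntimeWarning,
                stacklevel=3,
            )
            out[direction] = LoadBearingFractions(np.nan, np.nan)
        else:
            out[direction] = LoadBearingFractions(iso / tot, aniso / tot)
    return out


def pulsatile_and_fractions(
    at_sbp: StressDecomposition, at_dbp: StressDecomposition
) -> DerivedStressMetrics:
    """Pulsatile stresses and load-bearing fractions.

    Pulsatile stress is the componentwise systolic-minus-diastolic
    difference; fractions are component over total per direction at each
    pressure, and pulsatile fractions are delta-component over delta-total.
    """
    pulsatile = at_sbp - at_dbp
    undefined: list = []
    return DerivedStressMetrics(
        at_sbp=at_sbp,
        at_dbp=at_dbp,
        pulsatile=pulsatile,
        fractions_sbp=_fractions(at_sbp, "SBP", undefined),
        fractions_dbp=_fractions(at_dbp, "DBP", undefined),
        fractions_pulsatile=_fractions(pulsatile, "PP", undefined),
        undefined=undefined,
    )
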