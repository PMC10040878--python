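"""Synthetic pressure-radius recordings with the cohort's statistical structure.

The generator emulates the acquisition used for the analysis: pressure and
inner radius sampled together at 870 Hz over 8-10 heartbeats, radius
quantised to the echo-tracker's 7.8 um resolution, an instrumentation
delay on the pressure channel, and multiplicative channel noise.  The beat
is a smooth asymmetric pulse (raised-cosine upstroke over the first 30% of
the cycle, Gaussian-like relaxation after); only the pressure-radius
relation matters downstream, and the pressure channel is produced from the
radius waveform through the forward HGO membrane model, so with zero noise
the circumferential Laplace/constitutive equality holds at every sample by
construction.

Reference population statistics (clinical units as printed in cohort
tables) drive the cohort sampler: per sex-and-age group SBP/DBP and
diameters, and per-sex model-parameter means and SDs.  Because identified
stiffness parameters scatter over decades (SD exceeding the mean) the
tabulated means are not a jointly consistent single subject; see
:func:`calibrate_parameters` for how subjects are made self-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import mechanics
from .containers import PressureRadiusSeries, SubjectMeta
from .parameters import ModelParameters, ParameterBounds
from .units import M_PER_MM, PA_PER_KPA, mmhg_to_pa

__all__ = [
    "REFERENCE_HEMODYNAMICS",
    "REFERENCE_PARAMETER_STATS",
    "RADIUS_QUANTUM",
    "SAMPLING_RATE",
    "SubjectSpec",
    "CohortSpec",
    "pulse_waveform",
    "calibrate_parameters",
    "consistent_gamma",
    "representative_subject",
    "self_consistent_subject",
    "generate_subject_series",
    "sample_subject_specs",
    "generate_cohort",
]

SAMPLING_RATE = 870.0  # Hz, echo-tracking repetition frequency
RADIUS_QUANTUM = 7.8e-6  # m, smallest detectable wall movement

#: Group hemodynamics: mean and SD of SBP/DBP (mmHg) and of the inner
#: diameter at SBP/DBP (mm), age range (years) and group size.
REFERENCE_HEMODYNAMICS = {
    ("male", "young"): {
        "sbp": (114.0, 12.0), "dbp": (62.0, 8.0),
        "d_sys": (15.9, 1.2), "d_dias": (13.8, 1.4),
        "age_range": (23.0, 30.0), "n": 5,
    },
    ("female", "young"): {
        "sbp": (119.0, 14.0), "dbp": (66.0, 9.0),
        "d_sys": (15.1, 0.8), "d_dias": (13.3, 1.4),
        "age_range": (23.0, 30.0), "n": 5,
    },
    ("male", "elderly"): {
        "sbp": (134.0, 19.0), "dbp": (71.0, 9.0),
        "d_sys": (20.0, 1.7), "d_dias": (19.0, 1.9),
        "age_range": (41.0, 72.0), "n": 10,
    },
    ("female", "elderly"): {
        "sbp": (125.0, 12.0), "dbp": (65.0, 6.0),
        "d_sys": (16.8, 1.8), "d_dias": (15.8, 1.9),
        "age_range": (41.0, 72.0), "n": 10,
    },
}

#: Per-sex identified model parameters, mean and SD (clinical units:
#: c, k1 in kPa; beta in degrees; R0 in mm).
REFERENCE_PARAMETER_STATS = {
    "male": {
        "c": (131.50, 90.00), "k1": (14.18, 20.94), "k2": (196.76, 264.22),
        "beta": (42.38, 4.38), "r0": (7.80, 1.78), "lambda_z": (1.03, 0.02),
    },
    "female": {
        "c": (101.65, 63.75), "k1": (8.64, 10.00), "k2": (134.95, 175.15),
        "beta": (42.31, 3.82), "r0": (6.77, 1.23), "lambda_z": (1.03, 0.02),
    },
}

#: Mean group ages used for the representative subjects (years).
_ELDERLY_MEAN_AGE = {"male": 58.6, "female": 59.0}


def pulse_waveform(phase, upstroke: float = 0.3, tau: float = 0.25):
    """Normalised beat shape w(phase) with w(0)=0, max w=1, w(1)=0.

    Raised-cosine upstroke over the first ``upstroke`` fraction of the
    cycle (zero slope at foot and peak), then a Gaussian-like relaxation
    normalised to return to zero at end of cycle.  The exact shape is a
    modelling convenience: the analysis uses only the pressure-radius
    relation after phase averaging.
    """
    phase = np.asarray(phase, dtype=float)
    w = np.empty_like(phase)
    up = phase < upstroke
    w[up] = 0.5 * (1.0 - np.cos(np.pi * phase[up] / upstroke))
    s = phase[~up] - upstroke
    # Gaussian decay (zero slope at the peak), renormalised to reach 0 at
    # end of cycle so consecutive beats join continuously
    g = np.exp(-((s / tau) ** 2))
    g_end = math.exp(-(((1.0 - upstroke) / tau) ** 2))
    w[~up] = (g - g_end) / (1.0 - g_end)
    return w


@dataclass
class SubjectSpec:
    """Everything needed to synthesise one subject's recording."""

    id: str
    sex: str
    age: float
    kappa_true: ModelParameters
    r_dias: float  # m
    r_sys: float  # m
    heart_rate: float = 1.0  # Hz
    n_beats: int = 9
    noise_radius_rel: float = 0.01
    noise_pressure_rel: float = 0.01
    delay_samples: int = 0
    seed: int = 0
    sampling_rate: float = SAMPLING_RATE
    target_sbp: float | None = None  # Pa, for bookkeeping
    target_dbp: float | None = None

    def __post_init__(self):
        if not (self.r_sys > self.r_dias > 0):
            raise ValueError("need r_sys > r_dias > 0")
        if self.n_beats < 3:
            raise ValueError("need at least 3 beats")


class CalibrationError(RuntimeError):
    """No admissible (R0, c, k1) reproduces the requested hemodynamics."""


def _stress_bases(r0, r0_unloaded, lambda_z, beta_deg, k2, area):
    """Circumferential stress per unit c (iso) and per unit k1 (aniso)."""
    lt = mechanics.midwall_stretch(r0, r0_unloaded, lambda_z, area)
    cb2 = np.cos(np.deg2rad(beta_deg)) ** 2
    sb2 = 1.0 - cb2
    i4 = lt**2 * cb2 + lambda_z**2 * sb2
    a = 2.0 * (lt**2 - (lt * lambda_z) ** -2)
    b = 4.0 * (i4 - 1.0) * np.exp(k2 * (i4 - 1.0) ** 2) * lt**2 * cb2
    return a, b


def calibrate_parameters(
    k2: float,
    beta_deg: float,
    lambda_z: float,
    r_dias: float,
    r_sys: float,
    dbp: float,
    sbp: float,
    area: float,
    f_aniso_sys: float = 0.25,
    bounds: ParameterBounds | None = None,
) -> ModelParameters:
    """Solve (R0, c, k1) so the forward model hits the target hemodynamics.

    Given the shape parameters (k2, beta, lambda_z) and targets - diastolic
    and systolic radii and pressures plus the anisotropic share of the
    circumferential stress at systole - the remaining parameters follow
    from equilibrium:  for a trial R0 the pair (c, k1) solves a 2x2 linear
    system (the stresses are linear in c and k1), and R0 is found by a 1-D
    root search so the systolic anisotropic load fraction matches
    ``f_aniso_sys``.  This is how synthetic subjects are made mutually
    consistent: the identified stiffness parameters in cohort tables
    scatter over decades, so drawing all six independently of the
    pressures and diameters would produce non-physiological loops.
    """
    bounds = bounds or ParameterBounds.default()
    s_theta_d = (4.0 * np.pi * r_dias**2 + area) * dbp / (2.0 * area)
    s_theta_s = (4.0 * np.pi * r_sys**2 + area) * sbp / (2.0 * area)

    def solve_ck(r0_unloaded):
        with np.errstate(over="ignore", invalid="ignore"):
            a_d, b_d = _stress_bases(r_dias, r0_unloaded, lambda_z, beta_deg, k2, area)
            a_s, b_s = _stress_bases(r_sys, r0_unloaded, lambda_z, beta_deg, k2, area)
            det = a_d * b_s - a_s * b_d
            if det == 0 or not np.isfinite(det):
                return np.nan, np.nan, np.nan
            c = (s_theta_d * b_s - s_theta_s * b_d) / det
            k1 = (a_d * s_theta_s - a_s * s_theta_d) / det
            frac = k1 * b_s / s_theta_s
        return c, k1, frac

    def objective(r0_unloaded):
        c, k1, frac = solve_ck(r0_unloaded)
        return frac - f_aniso_sys

    # Scan from large R0 (small stretch) downward so the bracket found
    # first is the physiological branch; the mid-wall stretch also has a
    # small-R0 branch with stretches ~2 that is rejected this way.
    grid = np.linspace(1.2 * r_dias, 1.05e-3, 160)
    prev = None
    bracket = None
    for r0u in grid:
        c, k1, frac = solve_ck(r0u)
        if not np.isfinite(frac) or c <= 0 or k1 <= 0:
            prev = None
            continue
        val = frac - f_aniso_sys
        if prev is not None and prev[1] * val <= 0:
            bracket = (r0u, prev[0])
            break
        prev = (r0u, val)
    if bracket is None:
        raise CalibrationError(
            "no unloaded radius yields positive stiffnesses with the "
            "requested anisotropic fraction"
        )
    r0_hat = brentq(objective, *bracket, xtol=1e-10)
    c, k1, _ = solve_ck(r0_hat)
    kappa = ModelParameters(
        c=float(c), k1=float(k1), k2=float(k2), beta_deg=float(beta_deg),
        r0_unloaded=float(r0_hat), lambda_z=float(lambda_z),
    )
    if not bounds.contains(kappa):
        raise CalibrationError(f"calibrated parameters leave the fitting box: {kappa}")
    return kappa


def consistent_gamma(kappa: ModelParameters, area: float, p_ref: float = 13.3e3) -> float:
    """Stress ratio sigma_z/sigma_theta of the model at the reference pressure.

    Using this value (instead of the population constant 0.59) when
    computing the axial force makes the longitudinal Laplace stresses of a
    synthetic subject consistent with its own generating parameters, which
    isolates parameter-recovery tests from the deliberate population-level
    gamma approximation.
    """
    r_ref = mechanics.solve_radius(kappa, area, p_ref)
    dec = mechanics.constitutive_stresses(r_ref, kappa, area)
    return float(dec.sigma_z_tot / dec.sigma_theta_tot)


def representative_subject(
    sex: str = "male",
    noise_radius_rel: float = 0.0,
    noise_pressure_rel: float = 0.0,
    delay_samples: int = 0,
    seed: int = 0,
    subject_id: str | None = None,
) -> SubjectSpec:
    """A representative subject from per-sex mean parameters.

    The parameter vector is the per-sex tabulated mean; the diastolic and
    systolic radii are obtained by inverting the forward model at the
    elderly-group mean DBP and SBP, so pressures are matched exactly and
    the radii fall where the mean model puts them.  Noise-free by default.
    """
    stats = REFERENCE_PARAMETER_STATS[sex]
    kappa = ModelParameters.from_clinical(
        c_kpa=stats["c"][0], k1_kpa=stats["k1"][0], k2=stats["k2"][0],
        beta_deg=stats["beta"][0], r0_mm=stats["r0"][0],
        lambda_z=stats["lambda_z"][0],
    )
    age = _ELDERLY_MEAN_AGE[sex]
    area = mechanics.area_from_age(age, sex)
    hemo = REFERENCE_HEMODYNAMICS[(sex, "elderly")]
    dbp = mmhg_to_pa(hemo["dbp"][0])
    sbp = mmhg_to_pa(hemo["sbp"][0])
    r_dias = mechanics.solve_radius(kappa, area, dbp)
    r_sys = mechanics.solve_radius(kappa, area, sbp)
    return SubjectSpec(
        id=subject_id or f"representative_{sex}",
        sex=sex,
        age=age,
        kappa_true=kappa,
        r_dias=r_dias,
        r_sys=r_sys,
        noise_radius_rel=noise_radius_rel,
        noise_pressure_rel=noise_pressure_rel,
        delay_samples=delay_samples,
        seed=seed,
        target_sbp=sbp,
        target_dbp=dbp,
    )


def self_consistent_subject(
    sex: str = "male",
    noise_radius_rel: float = 0.0,
    noise_pressure_rel: float = 0.0,
    seed: int = 0,
) -> SubjectSpec:
    """A subject whose generating model is consistent with the axial-force
    construction, for parameter/stress-curve recovery experiments.

    The tabulated mean parameters are not exactly compatible with a
    pressure-independent axial force at the reference stress ratio, so a
    loop generated from them carries an irreducible longitudinal model
    error (as real data do).  For recovery experiments a generating model
    *within* reach of the identification is wanted instead: the
    representative subject is fitted once, and the fitted parameters -
    whose longitudinal stresses track a constant-force Laplace reference
    by construction - become ``kappa_true`` of a fresh subject with the
    same pressure targets.
    """
    from .identification import HGOWallModel
    from .preprocessing import LoopPreprocessor

    base = representative_subject(sex)
    series = generate_subject_series(base)
    loop = LoopPreprocessor().transform(series)
    model = HGOWallModel().fit(loop)
    kappa = model.kappa_
    area = model.area_
    return SubjectSpec(
        id=f"self_consistent_{sex}",
        sex=sex,
        age=base.age,
        kappa_true=kappa,
        r_dias=mechanics.solve_radius(kappa, area, base.target_dbp),
        r_sys=mechanics.solve_radius(kappa, area, base.target_sbp),
        noise_radius_rel=noise_radius_rel,
        noise_pressure_rel=noise_pressure_rel,
        seed=seed,
        target_sbp=base.target_sbp,
        target_dbp=base.target_dbp,
    )


def generate_subject_series(
    spec: SubjectSpec, area: float | None = None
) -> PressureRadiusSeries:
    """Synthesise the multi-beat recording for one subject.

    The clean radius waveform is ``r_dias + (r_sys - r_dias) w(phase)``;
    the clean pressure follows from the forward model (monotonicity of the
    pressure-radius relation over the excursion is verified).  Then, in
    order: multiplicative Gaussian noise per channel, radius quantisation
    to the echo-tracker resolution, and an integer-sample delay of the
    pressure channel.  Deterministic for a fixed seed.
    """
    if area is None:
        area = mechanics.area_from_age(spec.age, spec.sex)
    if not ParameterBounds.default().contains(spec.kappa_true):
        raise ValueError("kappa_true outside the standard fitting box")
    # monotonicity check of the forward model over the radius excursion
    r_grid = np.linspace(spec.r_dias, spec.r_sys, 64)
    with np.errstate(over="ignore", invalid="ignore"):
        p_grid = mechanics.pressure_from_radius(r_grid, spec.kappa_true, area)
    if not (np.all(np.isfinite(p_grid)) and np.all(np.diff(p_grid) > 0)):
        raise ValueError(
            "forward model is not finite and monotonically increasing over "
            "[r_dias, r_sys]; choose different kappa_true"
        )

    n = int(round(spec.sampling_rate * spec.n_beats / spec.heart_rate))
    t = np.arange(n) / spec.sampling_rate
    phase = (t * spec.heart_rate) % 1.0
    w = pulse_waveform(phase)
    r_clean = spec.r_dias + (spec.r_sys - spec.r_dias) * w
    p_clean = mechanics.pressure_from_radius(r_clean, spec.kappa_true, area)

    rng = np.random.default_rng(spec.seed)
    radius = r_clean * (1.0 + spec.noise_radius_rel * rng.standard_normal(n))
    pressure = p_clean * (1.0 + spec.noise_pressure_rel * rng.standard_normal(n))
    radius = np.round(radius / RADIUS_QUANTUM) * RADIUS_QUANTUM
    d = int(spec.delay_samples)
    if d > 0:
        pressure = np.concatenate([np.full(d, pressure[0]), pressure[:-d]])
    elif d < 0:
        pressure = np.concatenate([pressure[-d:], np.full(-d, pressure[-1])])
    return PressureRadiusSeries(
        time=t,
        pressure=pressure,
        radius=radius,
        sampling_rate=spec.sampling_rate,
        subject=SubjectMeta(id=spec.id, sex=spec.sex, age=spec.age),
    )


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic cohort.

    Defaults reproduce the reference population: 30 subjects, 15 male,
    group sizes 5/5/10/10 across sex and young/elderly, with group
    hemodynamics drawn from the tabulated means and SDs.
    """

    group_sizes: dict = field(
        default_factory=lambda: {
            ("male", "young"): 5,
            ("female", "young"): 5,
            ("male", "elderly"): 10,
            ("female", "elderly"): 10,
        }
    )
    master_seed: int = 0
    noise_radius_rel: float = 0.01
    noise_pressure_rel: float = 0.01
    n_beats: int = 9
    heart_rate: float = 1.0
    max_delay_samples: int = 30
    f_aniso_sys_range: tuple = (0.15, 0.35)
    hemodynamics: dict = field(default_factory=lambda: dict(REFERENCE_HEMODYNAMICS))
    parameter_stats: dict = field(
        default_factory=lambda: dict(REFERENCE_PARAMETER_STATS)
    )
    max_attempts: int = 100


def _lognormal_from_moments(rng, mean, sd):
    var_ln = math.log(1.0 + (sd / mean) ** 2)
    mu_ln = math.log(mean) - 0.5 * var_ln
    return float(rng.lognormal(mu_ln, math.sqrt(var_ln)))


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=1000):
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def sample_subject_specs(spec: CohortSpec) -> list[SubjectSpec]:
    """Draw the per-subject specifications (no waveform synthesis yet).

    Ages are uniform in the group range; pressures and diameters are drawn
    from the group normal distributions (truncated to physiological order:
    SBP > DBP, systolic > diastolic diameter); the shape parameters
    (k2 log-normal; beta, lambda_z truncated normal) come from the per-sex
    parameter statistics, and (R0, c, k1) are calibrated so the forward
    model reproduces the drawn pressures at the drawn radii.  Infeasible
    draws are rejected and resampled, up to ``max_attempts`` per subject.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    bounds = ParameterBounds.default()
    specs: list[SubjectSpec] = []
    idx = 0
    for (sex, group), n_subj in spec.group_sizes.items():
        hemo = spec.hemodynamics[(sex, group)]
        pstats = spec.parameter_stats[sex]
        for j in range(n_subj):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            subject_seed = int(rng.integers(2**31 - 1))
            last_err = None
            # Pressures and age are drawn once per subject so the group
            # SBP/DBP marginals stay unbiased; only the diameters and
            # shape parameters are renegotiated when a draw is mechanically
            # infeasible for every unloaded radius.
            age = rng.uniform(*hemo["age_range"])
            sbp = _truncated_normal(rng, *hemo["sbp"], 70.0, 260.0)
            dbp = _truncated_normal(rng, *hemo["dbp"], 30.0, sbp - 25.0)
            for _ in range(spec.max_attempts):
                d_sys = _truncated_normal(rng, *hemo["d_sys"], 6.0, 40.0)
                d_dias = _truncated_normal(
                    rng, *hemo["d_dias"], 5.0, d_sys - 0.3
                )
                k2 = _lognormal_from_moments(rng, *pstats["k2"])
                k2 = float(np.clip(k2, bounds.lower[2], bounds.upper[2]))
                beta = _truncated_normal(rng, *pstats["beta"], 5.0, 80.0)
                lam_z = _truncated_normal(rng, *pstats["lambda_z"], 1.0, 1.15)
                f_aniso = rng.uniform(*spec.f_aniso_sys_range)
                area = mechanics.area_from_age(age, sex)
                try:
                    kappa = calibrate_parameters(
                        k2=k2, beta_deg=beta, lambda_z=lam_z,
                        r_dias=d_dias / 2.0 * M_PER_MM,
                        r_sys=d_sys / 2.0 * M_PER_MM,
                        dbp=mmhg_to_pa(dbp), sbp=mmhg_to_pa(sbp),
                        area=area, f_aniso_sys=f_aniso,
                    )
                except CalibrationError as err:
                    last_err = err
                    continue
                specs.append(
                    SubjectSpec(
                        id=f"syn{idx:03d}_{sex}_{group}",
                        sex=sex,
                        age=float(age),
                        kappa_true=kappa,
                        r_dias=d_dias / 2.0 * M_PER_MM,
                        r_sys=d_sys / 2.0 * M_PER_MM,
                        heart_rate=spec.heart_rate,
                        n_beats=spec.n_beats,
                        noise_radius_rel=spec.noise_radius_rel,
                        noise_pressure_rel=spec.noise_pressure_rel,
                        delay_samples=int(rng.integers(0, spec.max_delay_samples + 1)),
                        seed=subject_seed,
                        target_sbp=mmhg_to_pa(sbp),
                        target_dbp=mmhg_to_pa(dbp),
                    )
                )
                break
            else:
                raise CalibrationError(
                    f"subject {idx} infeasible after {spec.max_attempts} "
                    f"attempts: {last_err}"
                )
            idx += 1
    return specs


def generate_cohort(spec: CohortSpec) -> tuple[list[PressureRadiusSeries], pd.DataFrame]:
    """Synthesise a full cohort: recordings plus a metadata table.

    The metadata table carries the demographics, the generating ("true")
    parameters in clinical units and the pressure targets, for use in
    recovery experiments.  Deterministic for a fixed master seed.
    """
    subject_specs = sample_subject_specs(spec)
    series_list = [generate_subject_series(s) for s in subject_specs]
    rows = []
    for s in subject_specs:
        rows.append(
            {
                "id": s.id,
                "sex": s.sex,
                "age": s.age,
                "c_kpa": s.kappa_true.c / PA_PER_KPA,
                "k1_kpa": s.kappa_true.k1 / PA_PER_KPA,
                "k2": s.kappa_true.k2,
                "beta_deg": s.kappa_true.beta_deg,
                "r0_mm": s.kappa_true.r0_unloaded / M_PER_MM,
                "lambda_z": s.kappa_true.lambda_z,
                "r_dias_mm": s.r_dias / M_PER_MM,
                "r_sys_mm": s.r_sys / M_PER_MM,
                "target_sbp_pa": s.target_sbp,
                "target_dbp_pa": s.target_dbp,
                "delay_samples": s.delay_samples,
                "seed": s.seed,
            }
        )
    return series_list, pd.DataFrame(rows)
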