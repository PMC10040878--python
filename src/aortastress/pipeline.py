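"""Per-subject orchestration and cohort summaries.

``run_subject`` executes the full chain for one recording - filter, align,
average, axial force from the reference stress ratio, identification,
derived metrics, optional sensitivity - and returns a flat result row in
reporting units (mmHg, kPa, mm).  ``run_batch`` maps it over a directory,
continuing past per-subject failures.  ``summarize_cohort`` produces the
descriptive group statistics (mean +/- SD by sex and the 40-year age
threshold) and per-sex ordinary least-squares regressions of every metric
on age with the squared Pearson correlation.
"""

from __future__ import annotations

import dataclasses
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import mechanics, metrics
from .containers import PressureRadiusSeries, SubjectMeta
from .identification import HGOWallModel
from .io import read_subject_series
from .parameters import ParameterBounds
from .preprocessing import align_channels, lowpass_filter, segment_and_average
from .sensitivity import sensitivity_analysis
from .units import M_PER_MM, PA_PER_KPA, pa_to_mmhg

logger = logging.getLogger("aortastress")

__all__ = ["AnalysisConfig", "run_subject", "run_batch", "summarize_cohort", "CohortSummary"]

#: Age threshold (years) splitting the cohort into young/elderly groups.
AGE_THRESHOLD = 40.0


@dataclass
class AnalysisConfig:
    """Flat configuration for the per-subject pipeline.

    Every run can write the resolved configuration next to its outputs for
    provenance (see :meth:`to_yaml`).
    """

    cutoff_hz: float = 15.0
    filter_order: int = 4
    max_lag_s: float = 0.1
    n_grid: int = 100
    gamma: float = 0.59
    p_ref_kpa: float = 13.3
    tol: float = 1e-5
    n_multistart: int = 8
    seed: int = 0
    run_sensitivity: bool = False
    stress_eval: str = "loop_radii"  # or "model_inversion" for SBP/DBP
    bounds_lower: list | None = None  # clinical units, optional override
    bounds_upper: list | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def parameter_bounds(self) -> ParameterBounds | None:
        if self.bounds_lower is None and self.bounds_upper is None:
            return None
        default = ParameterBounds.default()
        lower = default.lower.copy()
        upper = default.upper.copy()
        scale = np.array([PA_PER_KPA, PA_PER_KPA, 1.0, 1.0, M_PER_MM, 1.0])
        if self.bounds_lower is not None:
            lower = np.asarray(self.bounds_lower, float) * scale
        if self.bounds_upper is not None:
            upper = np.asarray(self.bounds_upper, float) * scale
        return ParameterBounds(lower, upper)


def _decomposition_row(prefix: str, dec) -> dict:
    def kpa(v):
        return float(np.asarray(v)) / PA_PER_KPA

    return {
        f"sigma_theta_iso_{prefix}_kpa": kpa(dec.sigma_theta_iso),
        f"sigma_theta_aniso_{prefix}_kpa": kpa(dec.sigma_theta_aniso),
        f"sigma_theta_tot_{prefix}_kpa": kpa(dec.sigma_theta_tot),
        f"sigma_z_iso_{prefix}_kpa": kpa(dec.sigma_z_iso),
        f"sigma_z_aniso_{prefix}_kpa": kpa(dec.sigma_z_aniso),
        f"sigma_z_tot_{prefix}_kpa": kpa(dec.sigma_z_tot),
    }


def run_subject(
    source: PressureRadiusSeries | str | Path,
    config: AnalysisConfig | None = None,
    subject: SubjectMeta | None = None,
) -> dict:
    """Run the full analysis for one subject and return the result row.

    ``source`` is either an in-memory series or a path to a subject CSV.
    Stage timings and the parameters used are logged to the package
    logger.
    """
    config = config or AnalysisConfig()
    t0 = _time.perf_counter()
    if isinstance(source, (str, Path)):
        series = read_subject_series(source, subject=subject)
    else:
        series = source
        if subject is not None:
            series = dataclasses.replace(series, subject=subject)
    meta = series.subject
    if meta is None:
        raise ValueError("subject metadata (id, sex, age) is required")
    logger.info("subject %s: %d samples at %.0f Hz", meta.id, series.n_samples,
                series.sampling_rate)

    filtered = lowpass_filter(series, cutoff=config.cutoff_hz, order=config.filter_order)
    aligned = align_channels(filtered, max_lag=config.max_lag_s)
    loop = segment_and_average(aligned, n_grid=config.n_grid)
    t1 = _time.perf_counter()
    logger.info(
        "subject %s: preprocessing done (%d beats averaged, %.2f s)",
        meta.id, loop.n_beats_used, t1 - t0,
    )

    model = HGOWallModel(
        gamma=config.gamma,
        p_ref=config.p_ref_kpa * PA_PER_KPA,
        bounds=config.parameter_bounds(),
        tol=config.tol,
        n_multistart=config.n_multistart,
        random_state=config.seed,
    )
    model.fit(loop, subject=meta)
    t2 = _time.perf_counter()
    logger.info(
        "subject %s: identification done (phi=%.3e Pa^2, R2_theta=%.4f, "
        "R2_z=%.4f, %.2f s)",
        meta.id, model.phi_, model.r2_theta_, model.r2_z_, t2 - t1,
    )

    hemo = metrics.hemodynamic_summary(loop)
    if config.stress_eval == "loop_radii":
        at_sbp = model.decompose(hemo.r_at_sbp)
        at_dbp = model.decompose(hemo.r_at_dbp)
    elif config.stress_eval == "model_inversion":
        at_sbp = metrics.stress_at_pressure(model.kappa_, model.area_, hemo.sbp, loop)
        at_dbp = metrics.stress_at_pressure(model.kappa_, model.area_, hemo.dbp, loop)
    else:
        raise ValueError(f"unknown stress_eval mode {config.stress_eval!r}")
    at_map = metrics.stress_at_pressure(model.kappa_, model.area_, hemo.map, loop)
    derived = metrics.pulsatile_and_fractions(at_sbp, at_dbp)

    kappa = model.kappa_
    row: dict = {
        "id": meta.id,
        "sex": meta.sex,
        "age": meta.age,
        "n_beats_used": loop.n_beats_used,
        "delay_corrected_samples": aligned.delay_corrected_samples,
        "area_mm2": model.area_ / 1e-6,
        "gamma": config.gamma,
        "p_ref_kpa": config.p_ref_kpa,
        "r_ref_mm": model.r_ref_ / M_PER_MM,
        "axial_force_n": model.force_,
        "c_kpa": kappa.c / PA_PER_KPA,
        "k1_kpa": kappa.k1 / PA_PER_KPA,
        "k2": kappa.k2,
        "beta_deg": kappa.beta_deg,
        "r0_mm": kappa.r0_unloaded / M_PER_MM,
        "lambda_z": kappa.lambda_z,
        "phi_pa2": model.phi_,
        "r2_theta": model.r2_theta_,
        "r2_z": model.r2_z_,
        "converged": model.converged_,
        "sbp_mmhg": pa_to_mmhg(hemo.sbp),
        "dbp_mmhg": pa_to_mmhg(hemo.dbp),
        "map_mmhg": pa_to_mmhg(hemo.map),
        "pp_mmhg": pa_to_mmhg(hemo.pp),
        "r_at_sbp_mm": hemo.r_at_sbp / M_PER_MM,
        "r_at_dbp_mm": hemo.r_at_dbp / M_PER_MM,
    }
    row.update(_decomposition_row("sbp", at_sbp))
    row.update(_decomposition_row("dbp", at_dbp))
    row.update(_decomposition_row("pp", derived.pulsatile))
    row["sigma_theta_tot_map_kpa"] = float(np.asarray(at_map.sigma_theta_tot)) / PA_PER_KPA
    row["sigma_z_tot_map_kpa"] = float(np.asarray(at_map.sigma_z_tot)) / PA_PER_KPA
    for label, fracs in (
        ("sbp", derived.fractions_sbp),
        ("dbp", derived.fractions_dbp),
        ("pp", derived.fractions_pulsatile),
    ):
        for direction in ("theta", "z"):
            row[f"f_{direction}_iso_{label}"] = fracs[direction].iso
            row[f"f_{direction}_aniso_{label}"] = fracs[direction].aniso

    if config.run_sensitivity:
        report = sensitivity_analysis(kappa, loop, model.area_, model.force_)
        for e in report.entries:
            row[f"sens_{e.parameter}_{e.direction}_pct"] = e.percent_change
    t3 = _time.perf_counter()
    logger.info("subject %s: derived metrics done (%.2f s total)", meta.id, t3 - t0)
    return row


def run_batch(
    sources: list,
    config: AnalysisConfig | None = None,
    subjects: list[SubjectMeta] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Run many subjects, continuing past failures.

    Returns the result table and a list of ``(identifier, reason)`` for
    subjects that failed a stage.
    """
    rows = []
    failures: list[tuple[str, str]] = []
    for i, source in enumerate(sources):
        subject = subjects[i] if subjects is not None else None
        ident = str(getattr(subject, "id", None) or source)
        try:
            rows.append(run_subject(source, config=config, subject=subject))
        except Exception as err:  # noqa: BLE001 - batch must continue
            logger.error("subject %s failed: %s", ident, err)
            failures.append((ident, str(err)))
    return pd.DataFrame(rows), failures


@dataclass
class CohortSummary:
    """Descriptive statistics and age regressions for a cohort."""

    group_stats: pd.DataFrame  # mean/SD per (sex, age group) per metric
    regressions: pd.DataFrame  # per (sex, metric): slope, intercept, r2


def summarize_cohort(rows: pd.DataFrame, min_group_size: int = 2) -> CohortSummary:
    """Group mean +/- SD tables and per-sex age regressions.

    Groups are sex crossed with the strict 40-year age threshold
    (``young`` below, ``elderly`` at or above).  Regressions are ordinary
    least squares of each numeric metric on age within each sex; ``r2``
    is the squared Pearson correlation.  Groups smaller than
    ``min_group_size`` are omitted with a warning.
    """
    if "age" not in rows.columns or "sex" not in rows.columns:
        raise ValueError("result rows must contain 'age' and 'sex' columns")
    df = rows.copy()
    df["age_group"] = np.where(df["age"] < AGE_THRESHOLD, "young", "elderly")
    metric_cols = [
        c
        for c in df.columns
        if c not in ("id", "sex", "age_group")
        and pd.api.types.is_numeric_dtype(df[c])
    ]

    stat_records = []
    for (sex, age_group), sub in df.groupby(["sex", "age_group"], sort=True):
        if len(sub) < min_group_size:
            logger.warning(
                "group (%s, %s) has %d subject(s); omitted from summary",
                sex, age_group, len(sub),
            )
            continue
        for col in metric_cols:
            stat_records.append(
                {
                    "sex": sex,
                    "age_group": age_group,
                    "metric": col,
                    "n": int(sub[col].notna().sum()),
                    "mean": float(sub[col].mean()),
                    "sd": float(sub[col].std(ddof=1)),
                }
            )

    reg_records = []
    for sex, sub in df.groupby("sex", sort=True):
        if len(sub) < max(min_group_size, 3):
            continue
        for col in metric_cols:
            if col == "age":
                continue
            mask = sub[col].notna()
            if mask.sum() < 3 or sub.loc[mask, col].nunique() < 2:
                continue
            res = sps.linregress(sub.loc[mask, "age"], sub.loc[mask, col])
            reg_records.append(
                {
                    "sex": sex,
                    "metric": col,
                    "slope": float(res.slope),
                    "intercept": float(res.intercept),
                    "r2": float(res.rvalue**2),
                    "n": int(mask.sum()),
                }
            )
    return CohortSummary(
        group_stats=pd.DataFrame(stat_records),
        regressions=pd.DataFrame(reg_records),
    )
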