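"""CSV input/output in the dialect the pipeline reads and writes.

Per-subject recordings travel as CSV with columns ``time_s``,
``pressure_mmHg`` and ``radius_mm`` (header required); cohort metadata and
result tables are plain CSV with documented headers.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PressureRadiusSeries, SubjectMeta
from .units import M_PER_MM, mmhg_to_pa, pa_to_mmhg

REQUIRED_COLUMNS = ("time_s", "pressure_mmHg", "radius_mm")

# generous physiological plausibility ranges used only for warnings
_PRESSURE_RANGE_MMHG = (20.0, 300.0)
_RADIUS_RANGE_MM = (2.0, 30.0)


def read_subject_series(
    path: str | Path, subject: SubjectMeta | None = None
) -> PressureRadiusSeries:
    """Read one subject's recording from CSV.

    Validates required columns, strictly increasing time and plausible
    unit ranges (out-of-range channels draw a warning, since unit mix-ups
    are the most common acquisition-file defect).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    time = df["time_s"].to_numpy(dtype=float)
    pressure_mmhg = df["pressure_mmHg"].to_numpy(dtype=float)
    radius_mm = df["radius_mm"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    for name, values, (lo, hi) in (
        ("pressure_mmHg", pressure_mmhg, _PRESSURE_RANGE_MMHG),
        ("radius_mm", radius_mm, _RADIUS_RANGE_MM),
    ):
        if values.min() < lo or values.max() > hi:
            warnings.warn(
                f"{path}: {name} outside plausible range [{lo}, {hi}]; "
                "check units",
                RuntimeWarning,
                stacklevel=2,
            )
    dt = np.median(np.diff(time))
    return PressureRadiusSeries(
        time=time,
        pressure=mmhg_to_pa(pressure_mmhg),
        radius=radius_mm * M_PER_MM,
        sampling_rate=1.0 / dt,
        subject=subject,
    )


def write_subject_series(path: str | Path, series: PressureRadiusSeries) -> None:
    """Write a recording in the same CSV dialect the reader accepts."""
    df = pd.DataFrame(
        {
            "time_s": series.time,
            "pressure_mmHg": pa_to_mmhg(series.pressure),
            "radius_mm": series.radius / M_PER_MM,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Cohort metadata table (id, sex, age, optional true parameters)."""
    df = pd.read_csv(path)
    for col in ("id", "sex", "age"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata must contain column {col!r}")
    return df
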