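"""Unit conversions used at the I/O boundary.

Everything inside the package is SI (m, Pa, N, s).  Clinical units
(mmHg, kPa, mm) appear only when reading or writing data, following the
convention 1 mmHg = 133.32 Pa.
"""

from __future__ import annotations

PA_PER_MMHG: float = 133.32
"""Pascal per millimetre of mercury."""

PA_PER_KPA: float = 1.0e3
M_PER_MM: float = 1.0e-3
M2_PER_MM2: float = 1.0e-6


def mmhg_to_pa(value):
    """Convert pressure from mmHg to Pa."""
    return value * PA_PER_MMHG


def pa_to_mmhg(value):
    """Convert pressure from Pa to mmHg."""
    return value / PA_PER_MMHG


def convert_pressure(value, direction: str):
    """Convert pressure between mmHg and Pa.

    Parameters
    ----------
    value : float or array
        Pressure value(s).
    direction : {"mmHg->Pa", "Pa->mmHg"}
        Conversion direction.
    """
    if direction == "mmHg->Pa":
        return mmhg_to_pa(value)
    if direction == "Pa->mmHg":
        return pa_to_mmhg(value)
    raise ValueError(
        f"unknown direction {direction!r}; expected 'mmHg->Pa' or 'Pa->mmHg'"
    )
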