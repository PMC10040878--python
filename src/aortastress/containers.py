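"""In-memory containers for measured and preprocessed signals."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SubjectMeta:
    """Identity and demographics of one subject."""

    id: str
    sex: str  # "male" | "female"
    age: float  # years

    def __post_init__(self):
        from .parameters import VALID_SEXES

        if self.sex not in VALID_SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {VALID_SEXES}")
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass
class PressureRadiusSeries:
    """Synchronised intra-aortic pressure and inner-radius recording.

    Attributes
    ----------
    time : ndarray
        Sample times (s), strictly increasing on a uniform grid.
    pressure : ndarray
        Lumen pressure (Pa).
    radius : ndarray
        Inner radius (m), positive.
    sampling_rate : float
        Samples per second; must be consistent with the time grid.
    subject : SubjectMeta or None
        Demographics, when known.
    delay_corrected_samples : int
        Integer-sample shift already applied to the pressure channel by
        the alignment stage (bookkeeping only).
    """

    time: np.ndarray
    pressure: np.ndarray
    radius: np.ndarray
    sampling_rate: float
    subject: SubjectMeta | None = None
    delay_corrected_samples: int = 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValueError("series needs at least two samples")
        if self.pressure.size != n or self.radius.size != n:
            raise ValueError("time, pressure and radius must have equal lengths")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.radius <= 0):
            raise ValueError("radius must be positive")
        dt = np.median(np.diff(self.time))
        if not np.isclose(dt, 1.0 / self.sampling_rate, rtol=1e-2):
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with time grid "
                f"(median dt {dt:.6g} s)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class AveragedLoop:
    """One cycle-averaged pressure-radius loop.

    The first sample sits at the diastolic foot.  Arrays have equal length
    (``n_grid`` of the averaging stage).
    """

    pressure: np.ndarray  # Pa
    radius: np.ndarray  # m
    n_beats_used: int
    subject: SubjectMeta | None = field(default=None)

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.pressure.size != self.radius.size:
            raise ValueError("pressure and radius must have equal lengths")
        if self.pressure.size < 2:
            raise ValueError("averaged loop needs at least two samples")

    @property
    def n_samples(self) -> int:
        return int(self.pressure.size)

    def radius_at(self, pressure: float) -> float:
        """Inner radius where the loop crosses ``pressure`` (Pa).

        A loop generally crosses a given pressure twice (inflation and
        deflation limb); the mean of all linear-interpolated crossings is
        returned, which is the natural single-radius summary of a narrow
        loop.  Raises ``ValueError`` outside the loop's pressure range.
        """
        p = self.pressure
        r = self.radius
        pmin, pmax = float(p.min()), float(p.max())
        if pressure < pmin or pressure > pmax:
            raise ValueError(
                f"pressure {pressure:.1f} Pa outside loop range [{pmin:.1f}, {pmax:.1f}]"
            )
        # closed polygon: include wrap-around segment
        p_ext = np.append(p, p[0])
        r_ext = np.append(r, r[0])
        crossings = []
        for i in range(p_ext.size - 1):
            p0, p1 = p_ext[i], p_ext[i + 1]
            if (p0 - pressure) * (p1 - pressure) <= 0 and p1 != p0:
                t = (pressure - p0) / (p1 - p0)
                crossings.append(r_ext[i] + t * (r_ext[i + 1] - r_ext[i]))
        if not crossings:
            # pressure equals a flat extremum
            return float(r[np.argmin(np.abs(p - pressure))])
        return float(np.mean(crossings))
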