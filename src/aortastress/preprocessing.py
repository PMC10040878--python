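"""Signal processing: filter, delay-align and cycle-average raw recordings.

The measured channels (intra-aortic pressure and echo-tracked inner radius,
sampled together at ~870 Hz over 8-10 heartbeats) are turned into a single
averaged pressure-radius loop in three stages:

1. zero-phase low-pass filtering (4th-order Butterworth, 15 Hz cut-off,
   applied forward-backward so no phase lag distorts the loop; the
   effective magnitude response is the Butterworth response squared),
2. integer-sample delay correction of the pressure channel against the
   radius channel by cross-correlation,
3. beat segmentation at diastolic feet and pointwise phase averaging onto
   a fixed grid.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AveragedLoop, PressureRadiusSeries

__all__ = [
    "lowpass_filter",
    "align_channels",
    "segment_and_average",
    "LoopPreprocessor",
]


def lowpass_filter(
    series: PressureRadiusSeries, cutoff: float = 15.0, order: int = 4
) -> PressureRadiusSeries:
    """Zero-phase Butterworth low-pass of both channels.

    Both channels are filtered identically; the DC level is preserved
    (unit gain at zero frequency).  The cut-off must lie below Nyquist.
    """
    nyquist = series.sampling_rate / 2.0
    if not cutoff < nyquist:
        raise ValueError(
            f"cut-off {cutoff} Hz must be below Nyquist ({nyquist} Hz)"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=series.sampling_rate, output="sos")
    return dataclasses.replace(
        series,
        pressure=signal.sosfiltfilt(sos, series.pressure),
        radius=signal.sosfiltfilt(sos, series.radius),
    )


def align_channels(
    series: PressureRadiusSeries, max_lag: float = 0.1
) -> PressureRadiusSeries:
    """Correct the measurement-chain delay between pressure and radius.

    The integer-sample lag maximising the cross-correlation between the
    (mean-removed) pressure and radius channels is estimated over
    ``+-max_lag`` seconds and the pressure channel is shifted accordingly;
    both channels are truncated to the overlapping span.  Ties are broken
    toward the smallest ``|lag|`` (then toward the earlier lag).  A
    degenerate (constant) channel yields zero lag with a warning.
    """
    max_samples = int(round(max_lag * series.sampling_rate))
    if max_samples >= series.n_samples - 1:
        raise ValueError("max_lag must be shorter than the record")
    p = series.pressure - series.pressure.mean()
    r = series.radius - series.radius.mean()
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        warnings.warn(
            "constant channel: delay cannot be estimated, assuming zero lag",
            RuntimeWarning,
            stacklevel=2,
        )
        return dataclasses.replace(series, delay_corrected_samples=0)
    lags = np.arange(-max_samples, max_samples + 1)
    corr = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = p[lag:], r[: r.size - lag]
        else:
            a, b = p[:lag], r[-lag:]
        corr[i] = np.dot(a, b) / max(a.size, 1)
    best = corr.max()
    candidates = lags[corr >= best - 1e-12 * abs(best)]
    # smallest |lag| first, negative preferred on exact ties
    lag = int(min(candidates, key=lambda s: (abs(s), s)))
    if lag == 0:
        return dataclasses.replace(series, delay_corrected_samples=0)
    if lag > 0:
        pressure = series.pressure[lag:]
        radius = series.radius[: series.radius.size - lag]
        time = series.time[: series.time.size - lag]
    else:
        pressure = series.pressure[:lag]
        radius = series.radius[-lag:]
        time = series.time[-lag:]
    return dataclasses.replace(
        series,
        time=time,
        pressure=pressure,
        radius=radius,
        delay_corrected_samples=lag,
    )


def _diastolic_feet(
    pressure: np.ndarray,
    sampling_rate: float,
    min_separation: float,
    percentile: float,
) -> np.ndarray:
    """Indices of diastolic feet: local pressure minima below the given
    percentile, separated by at least ``min_separation`` seconds."""
    threshold = np.percentile(pressure, percentile)
    feet, _ = signal.find_peaks(
        -pressure,
        height=-threshold,
        distance=max(int(round(min_separation * sampling_rate)), 1),
    )
    return feet


def segment_and_average(
    series: PressureRadiusSeries,
    n_grid: int = 100,
    min_separation: float = 0.4,
    foot_percentile: float = 25.0,
) -> AveragedLoop:
    """Segment into beats at diastolic feet and average by cardiac phase.

    Beats are delimited by consecutive diastolic feet on the pressure
    channel (sharper than radius minima); partial beats before the first
    and after the last foot are discarded.  Each beat is resampled to
    ``n_grid`` points by linear interpolation on normalised phase and the
    beats are averaged pointwise.  At least three complete beats are
    required.
    """
    feet = _diastolic_feet(
        series.pressure, series.sampling_rate, min_separation, foot_percentile
    )
    n_beats = max(feet.size - 1, 0)
    if n_beats < 3:
        raise ValueError(
            f"only {n_beats} complete beats detected; at least 3 are required"
        )
    phase = np.linspace(0.0, 1.0, n_grid)
    p_beats = np.empty((n_beats, n_grid))
    r_beats = np.empty((n_beats, n_grid))
    for k in range(n_beats):
        i0, i1 = feet[k], feet[k + 1]
        t = series.time[i0 : i1 + 1]
        local = (t - t[0]) / (t[-1] - t[0])
        p_beats[k] = np.interp(phase, local, series.pressure[i0 : i1 + 1])
        r_beats[k] = np.interp(phase, local, series.radius[i0 : i1 + 1])
    return AveragedLoop(
        pressure=p_beats.mean(axis=0),
        radius=r_beats.mean(axis=0),
        n_beats_used=n_beats,
        subject=series.subject,
    )


class LoopPreprocessor(TransformerMixin, BaseEstimator):
    """Filter -> align -> average, as a stateless scikit-learn transformer.

    Parameters
    ----------
    cutoff : float
        Low-pass cut-off frequency (Hz).
    order : int
        Butterworth filter order.
    max_lag : float
        Maximum channel delay searched (s); keep below one cardiac period.
    n_grid : int
        Number of phase samples of the averaged loop.
    min_separation : float
        Minimum spacing between diastolic feet (s).
    foot_percentile : float
        Pressure percentile below which feet are accepted.
    """

    def __init__(
        self,
        cutoff: float = 15.0,
        order: int = 4,
        max_lag: float = 0.1,
        n_grid: int = 100,
        min_separation: float = 0.4,
        foot_percentile: float = 25.0,
    ):
        self.cutoff = cutoff
        self.order = order
        self.max_lag = max_lag
        self.n_grid = n_grid
        self.min_separation = min_separation
        self.foot_percentile = foot_percentile

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: PressureRadiusSeries) -> AveragedLoop:
        filtered = lowpass_filter(X, cutoff=self.cutoff, order=self.order)
        aligned = align_channels(filtered, max_lag=self.max_lag)
        return segment_and_average(
            aligned,
            n_grid=self.n_grid,
            min_separation=self.min_separation,
            foot_percentile=self.foot_percentile,
        )
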