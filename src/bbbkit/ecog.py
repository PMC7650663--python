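"""Spectral quantification of post-stimulation cortical depression from ECoG.

A single-channel electrocorticography trace sampled at 200 Hz is band-limited
to 1-40 Hz with a zero-phase Butterworth filter.  Three features summarize
each analysis interval:

* mean spectral power, ``MSP = (1/df) * integral S(f) df`` over the analysis
  band (``S(f)`` is the power spectral density, the Fourier transform of the
  signal's autocorrelation, estimated by Welch averaging);
* dominant frequency, the argmax of ``S(f)``;
* signal energy, the discrete ``integral |x(t)|^2 dt`` (sum of squared
  samples).

A quiescent stretch of the pre-stimulation baseline serves as the reference;
per-minute post-onset intervals are expressed as percent change from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .exceptions import FlatSpectrumWarning, InvalidInputError

__all__ = [
    "ECoGTrace",
    "PowerSpectrum",
    "SpectralFeatures",
    "FeatureShift",
    "bandpass",
    "spectrum",
    "features",
    "select_quiescence",
    "interval_shifts",
    "shifts_table",
]


@dataclass(frozen=True)
class ECoGTrace:
    """A single-channel ECoG recording (samples in microvolts)."""

    samples: np.ndarray
    fs: float
    band: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise InvalidInputError("samples must be finite")
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if self.band is not None and self.fs <= 2 * self.band[1]:
            raise InvalidInputError("sampling rate must exceed twice the band edge")
        object.__setattr__(self, "samples", x)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def slice_seconds(self, start_s: float, end_s: float) -> "ECoGTrace":
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        if not 0 <= i0 < i1 <= self.samples.size:
            raise InvalidInputError("slice outside recording")
        return replace(self, samples=self.samples[i0:i1])


@dataclass(frozen=True)
class PowerSpectrum:
    """Power spectral density restricted to the analysis band.

    ``df`` is the analysis bandwidth (band width, Hz) that normalizes the
    mean-spectral-power integral.
    """

    freqs: np.ndarray
    power: np.ndarray
    df: float


@dataclass(frozen=True)
class SpectralFeatures:
    msp: float            # mean spectral power, uV^2/Hz
    dominant_freq: float  # Hz
    energy: float         # sum of squared samples, uV^2 * samples


@dataclass(frozen=True)
class FeatureShift:
    """Percent change of one feature in one post-onset 1-min interval."""

    interval_start: float  # minutes from stimulation onset
    feature: str           # "msp" | "energy" | "df"
    pct_change: float
    truncated: bool = False


def bandpass(trace: ECoGTrace, low: float, high: float, order: int = 4) -> ECoGTrace:
    """Zero-phase Butterworth band-pass; removes DC and out-of-band content."""
    if not 0 < low < high < trace.fs / 2:
        raise InvalidInputError("band must satisfy 0 < low < high < fs/2")
    sos = spsig.butter(order, [low, high], btype="bandpass", fs=trace.fs,
                       output="sos")
    y = spsig.sosfiltfilt(sos, trace.samples)
    return ECoGTrace(samples=y, fs=trace.fs, band=(low, high))


def spectrum(trace: ECoGTrace, segment_s: float = 2.0) -> PowerSpectrum:
    """Welch power spectral density (Hann segments, 50% overlap).

    Equivalent, for stationary signals, to Fourier-transforming the
    autocorrelation; the estimate is restricted to the trace's analysis band.
    """
    nper = int(round(segment_s * trace.fs))
    if trace.samples.size < nper:
        raise InvalidInputError("trace shorter than one spectral segment")
    freqs, power = spsig.welch(
        trace.samples, fs=trace.fs, window="hann", nperseg=nper,
        noverlap=nper // 2, detrend="constant",
    )
    lo, hi = trace.band if trace.band is not None else (0.0, trace.fs / 2)
    sel = (freqs >= lo) & (freqs <= hi)
    freqs, power = freqs[sel], power[sel]
    if freqs.size < 2:
        raise InvalidInputError("analysis band contains fewer than two bins")
    return PowerSpectrum(freqs=freqs, power=power, df=float(freqs[-1] - freqs[0]))


def features(trace: ECoGTrace, segment_s: float = 2.0) -> SpectralFeatures:
    """MSP, dominant frequency, and signal energy of a band-limited trace."""
    spec = spectrum(trace, segment_s=segment_s)
    msp = float(np.trapezoid(spec.power, spec.freqs) / spec.df)
    if np.ptp(spec.power) == 0:
        warnings.warn(
            "flat spectrum; dominant frequency tie-broken to lowest bin",
            FlatSpectrumWarning,
            stacklevel=2,
        )
    dominant = float(spec.freqs[int(spec.power.argmax())])
    energy = float(np.sum(trace.samples**2))
    return SpectralFeatures(msp=msp, dominant_freq=dominant, energy=energy)


def select_quiescence(
    trace: ECoGTrace, window_min: float, step_min: float = 1.0
) -> tuple[float, float]:
    """Pick the quiescent baseline window (automated stand-in for the
    protocol's manual selection).

    The baseline is cut into 1-min sub-intervals; among contiguous windows of
    ``window_min`` minutes (stepped by ``step_min``), the one minimizing the
    variance of sub-interval energies is returned as ``(start_s, end_s)``.
    """
    total_min = trace.duration_s / 60.0
    if window_min <= 0 or window_min > total_min:
        raise InvalidInputError("window_min exceeds the recording length")
    spm = int(round(60 * trace.fs))  # samples per minute
    n_sub = int(trace.duration_s // 60)
    energies = np.array([
        np.sum(trace.samples[i * spm : (i + 1) * spm] ** 2) for i in range(n_sub)
    ])
    w = int(round(window_min))
    if w > n_sub:
        raise InvalidInputError("window_min exceeds the number of whole minutes")
    step = max(1, int(round(step_min)))
    starts = range(0, n_sub - w + 1, step)
    variances = [energies[s : s + w].var() for s in starts]
    best = list(starts)[int(np.argmin(variances))]
    return best * 60.0, (best + w) * 60.0


def interval_shifts(
    trace: ECoGTrace,
    quiescence: tuple[float, float],
    onset_s: float,
    interval_s: float = 60.0,
    min_interval_s: float = 10.0,
    segment_s: float = 2.0,
) -> list[FeatureShift]:
    """Percent feature change of each post-onset 1-min interval vs quiescence.

    Baseline features come from the whole quiescence window.  Intervals that
    run past the end of the recording are computed on the available portion
    (if at least ``min_interval_s`` long) and flagged as truncated.
    """
    q0, q1 = quiescence
    if not q1 <= onset_s:
        raise InvalidInputError("quiescence must precede stimulation onset")
    if not 0 <= onset_s < trace.duration_s:
        raise InvalidInputError("onset outside recording")
    base = features(trace.slice_seconds(q0, q1), segment_s=segment_s)
    baseline = {"msp": base.msp, "energy": base.energy, "df": base.dominant_freq}
    # energy baseline is compared per unit time so intervals of different
    # length than the quiescence window remain comparable
    q_dur = q1 - q0
    shifts: list[FeatureShift] = []
    t = onset_s
    while t < trace.duration_s - min_interval_s:
        end = min(t + interval_s, trace.duration_s)
        truncated = end - t < interval_s
        f = features(trace.slice_seconds(t, end), segment_s=segment_s)
        vals = {
            "msp": f.msp,
            "energy": f.energy * (q_dur / (end - t)),
            "df": f.dominant_freq,
        }
        start_min = (t - onset_s) / 60.0
        for name in ("msp", "energy", "df"):
            ref = baseline[name]
            pct = 100.0 * (vals[name] - ref) / ref if ref != 0 else np.nan
            shifts.append(
                FeatureShift(
                    interval_start=start_min,
                    feature=name,
                    pct_change=float(pct),
                    truncated=truncated,
                )
            )
        t += interval_s
    return shifts


def shifts_table(shifts: list[FeatureShift]) -> pd.DataFrame:
    """Long-format table of per-interval feature shifts."""
    return pd.DataFrame(
        {
            "interval_start_min": [s.interval_start for s in shifts],
            "feature": [s.feature for s in shifts],
            "pct_change": [s.pct_change for s in shifts],
            "truncated": [s.truncated for s in shifts],
        }
    )
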