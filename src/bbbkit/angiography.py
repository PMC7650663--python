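"""Permeability-index scoring of time-lapse fluorescent angiography.

A tracer is injected intravenously while the exposed cortex is imaged.  The
stack is resized, registered, and segmented into a binary vessel map and the
extravascular (EV) parenchyma; a primary vessel supplies the vascular input
function (VIF).  Two permeability-index (PI) variants are computed:

* clearing tracers (e.g. sodium fluorescein): the time-average of the EV/VIF
  intensity ratio over the clearance window,
  ``PI = (1/T) * integral_{t_cr}^{t_end} I_EV(t) / I_VIF(t) dt``,
  where ``t_cr`` is the first post-peak time at which the VIF derivative
  enters the band (-1, 0] a.u./s and ``T = t_end - t_cr``;
* accumulating tracers (high-molecular-weight proteins that do not clear):
  the ratio of mean MWU ranks of the weighted intensity-histogram vectors
  ``x_i * f_i`` of the EV and vessel compartments.

Blood-brain barrier dysfunction (BBBD) is called when the percent PI change
from baseline exceeds 3 standard deviations of the change seen under sham
stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label
from skimage.morphology import remove_small_holes
from skimage.registration import phase_cross_correlation
from skimage.transform import resize_local_mean

from . import stats
from .exceptions import (
    DegenerateHistogramWarning,
    DivisionGuardError,
    InvalidInputError,
    RegistrationError,
    RegistrationFallbackWarning,
    SegmentationError,
    WindowNotFoundError,
)

__all__ = [
    "AngioSeries",
    "CompartmentMasks",
    "ITCurve",
    "ClearanceWindow",
    "PIResult",
    "resize_frames",
    "register_series",
    "segment_vessels",
    "select_primary_vessel",
    "compartment_curves",
    "subtract_background",
    "find_clearance_window",
    "pi_clearance",
    "pi_histogram",
    "pi_shift",
    "call_bbbd",
    "pixel_pi_map",
    "pixel_bbbd_map",
]

CLEARING = "clearing"
ACCUMULATING = "accumulating"


@dataclass(frozen=True)
class AngioSeries:
    """Registered time-lapse fluorescence frames.

    frames : (T, H, W) non-negative intensity array, arbitrary units.
    times : strictly increasing acquisition times in seconds.
    frame_rate : frames per second (5/s for clearing, 1/s for accumulating
        tracers under the acquisition protocol).
    tracer_mode : ``"clearing"`` or ``"accumulating"``.
    """

    frames: np.ndarray
    times: np.ndarray
    frame_rate: float
    tracer_mode: str

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        times = np.asarray(self.times, dtype=float)
        if frames.ndim != 3:
            raise InvalidInputError("frames must be a (time, height, width) array")
        if times.ndim != 1 or times.size != frames.shape[0]:
            raise InvalidInputError("times must match the time dimension of frames")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.tracer_mode not in (CLEARING, ACCUMULATING):
            raise InvalidInputError(
                f"tracer_mode must be {CLEARING!r} or {ACCUMULATING!r}"
            )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class CompartmentMasks:
    """Binary vessel / extravascular / primary-vessel maps on the frame grid."""

    vessel: np.ndarray
    extravascular: np.ndarray
    primary_vessel: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        vessel = np.asarray(self.vessel, dtype=bool)
        ev = np.asarray(self.extravascular, dtype=bool)
        if vessel.shape != ev.shape:
            raise InvalidInputError("vessel and extravascular masks must share a grid")
        if np.any(vessel & ev):
            raise InvalidInputError("vessel and extravascular masks must be disjoint")
        object.__setattr__(self, "vessel", vessel)
        object.__setattr__(self, "extravascular", ev)
        if self.primary_vessel is not None:
            pv = np.asarray(self.primary_vessel, dtype=bool)
            if pv.shape != vessel.shape:
                raise InvalidInputError("primary_vessel must share the mask grid")
            if np.any(pv & ~vessel):
                raise InvalidInputError("primary_vessel must be a subset of vessel")
            object.__setattr__(self, "primary_vessel", pv)


@dataclass(frozen=True)
class ITCurve:
    """Mean compartment fluorescence versus time (an intensity-time curve)."""

    t: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise InvalidInputError("t and intensity must be equal-length vectors")
        if not np.all(np.isfinite(y)):
            raise InvalidInputError("intensity must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class ClearanceWindow:
    """Integration window of the clearance-phase PI. ``T = t_end - t_cr``."""

    t_cr: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_cr < self.t_end:
            raise InvalidInputError("t_cr must precede t_end")

    @property
    def T(self) -> float:
        return self.t_end - self.t_cr


@dataclass(frozen=True)
class PIResult:
    """A permeability index with the mode it was computed under."""

    pi: float
    mode: str  # "clearance" or "histogram"
    window: Optional[ClearanceWindow] = None


# ---------------------------------------------------------------------------
# preprocessing

def resize_frames(series: AngioSeries, side: int) -> AngioSeries:
    """Downsample every frame to ``side x side`` by local averaging.

    Integer decimation factors use an exact block mean; other geometries fall
    back to local-mean resampling.  Upsampling is rejected.
    """
    if side < 2:
        raise InvalidInputError("target side must be at least 2 pixels")
    t, h, w = series.frames.shape
    if side > h or side > w:
        raise InvalidInputError("upsampling is not supported")
    if h % side == 0 and w % side == 0:
        fh, fw = h // side, w // side
        out = (
            series.frames.reshape(t, side, fh, side, fw)
            .mean(axis=(2, 4))
        )
    else:
        out = np.stack(
            [resize_local_mean(f, (side, side)) for f in series.frames]
        )
    return replace(series, frames=out)


def register_series(
    series: AngioSeries,
    reference_index: Optional[int] = None,
    max_error: float = 0.9,
) -> tuple[AngioSeries, np.ndarray]:
    """Rigidly (translation-only) align every frame to a reference frame.

    The reference defaults to the brightest frame (peak vascular filling).
    Shifts are estimated by phase correlation and applied by linear
    interpolation.  Frames whose registration error exceeds ``max_error``
    (e.g. pure noise) fall back to the identity with a warning; an all-zero
    frame raises :class:`RegistrationError`.

    Returns the registered series and the per-frame (row, col) shifts that
    were applied.
    """
    frames = series.frames
    if reference_index is None:
        reference_index = int(frames.mean(axis=(1, 2)).argmax())
    if not 0 <= reference_index < frames.shape[0]:
        raise InvalidInputError("reference_index out of range")
    ref = frames[reference_index]
    out = np.empty_like(frames, dtype=float)
    shifts = np.zeros((frames.shape[0], 2))
    for i, frame in enumerate(frames):
        if not np.any(frame):
            raise RegistrationError(f"frame {i} is all zero; cannot register")
        if i == reference_index:
            out[i] = frame
            continue
        shift, error, _ = phase_cross_correlation(
            ref, frame, upsample_factor=10, normalization=None
        )
        if error > max_error:
            warnings.warn(
                f"frame {i}: registration error {error:.3f} exceeds "
                f"{max_error}; identity transform used",
                RegistrationFallbackWarning,
                stacklevel=2,
            )
            out[i] = frame
            continue
        shifts[i] = shift
        out[i] = ndimage.shift(frame.astype(float), shift, order=1, mode="nearest")
    return replace(series, frames=out), shifts


def segment_vessels(
    series: AngioSeries,
    window_size: int = 25,
    rel_offset: float = 0.05,
    min_object_px: int = 4,
    max_hole_px: int = 16,
    guard_px: int = 2,
) -> CompartmentMasks:
    """Segment vessels on the peak-filling frame.

    Pipeline: median (3x3) noise filtration -> local-window adaptive
    threshold (Gaussian-weighted local mean plus an offset of ``rel_offset``
    times the frame's dynamic range, so bright vessels stand out from the
    parenchyma) -> morphological hole filling -> removal of speckle objects.
    The extravascular compartment is the field minus the vessel mask dilated
    by ``guard_px`` pixels: the perivascular guard band absorbs
    partial-volume pixels whose compartment assignment would otherwise
    fluctuate between acquisitions.
    """
    idx = int(series.frames.mean(axis=(1, 2)).argmax())
    img = np.asarray(series.frames[idx], dtype=float)
    if img.max() == img.min():
        raise SegmentationError("peak frame is uniform; no vessels separable")
    den = ndimage.median_filter(img, size=3)
    offset = -rel_offset * float(den.max() - den.min())
    thr = threshold_local(den, block_size=window_size, method="gaussian",
                          offset=offset)
    mask = den > thr
    # fill dropouts inside vessels without swallowing parenchyma islands
    # enclosed by crossing vessel branches
    mask = remove_small_holes(mask, max_size=max_hole_px)
    lab, n = ndimage.label(mask)
    if n:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        keep = np.flatnonzero(sizes >= min_object_px)
        mask = np.isin(lab, keep)
    if not mask.any():
        raise SegmentationError("no pixels above the adaptive threshold")
    if mask.mean() > 0.95:
        raise SegmentationError(
            "vessel mask covers the whole field; no extravascular compartment"
        )
    guarded = ndimage.binary_dilation(mask, iterations=guard_px) if guard_px else mask
    return CompartmentMasks(vessel=mask, extravascular=~guarded)


def select_primary_vessel(
    masks: CompartmentMasks,
    roi: Optional[np.ndarray] = None,
    erode_px: int = 1,
) -> CompartmentMasks:
    """Attach the primary-vessel ROI used as the vascular input function.

    With an explicit ``roi`` the primary vessel is ``roi & vessel`` (the
    manual selection of the protocol); without one, the largest connected
    vessel component is used as an automated stand-in.  The selection is
    eroded by ``erode_px`` pixels so the VIF samples the vessel lumen core
    rather than partial-volume boundary pixels, which would dilute its
    amplitude (the erosion is skipped when it would empty the mask).
    """
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        pv = roi & masks.vessel
        if not pv.any():
            raise InvalidInputError("ROI does not intersect the vessel mask")
    else:
        lab = label(masks.vessel, connectivity=2)
        if lab.max() == 0:
            raise SegmentationError("vessel mask is empty")
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        pv = lab == sizes.argmax()
    if erode_px:
        core = ndimage.binary_erosion(pv, iterations=erode_px)
        if core.any():
            pv = core
    return CompartmentMasks(
        vessel=masks.vessel, extravascular=masks.extravascular, primary_vessel=pv
    )


def subtract_background(series: AngioSeries, n_frames: int) -> AngioSeries:
    """Subtract the mean of the first ``n_frames`` pre-injection frames.

    Removes camera dark level and tissue autofluorescence so compartment
    ratios reflect tracer signal only.  Output frames may be negative where
    noise dips below the pre-injection level.
    """
    if not 1 <= n_frames < series.frames.shape[0]:
        raise InvalidInputError("n_frames must leave at least one frame")
    bg = series.frames[:n_frames].mean(axis=0)
    return replace(series, frames=series.frames - bg)


# ---------------------------------------------------------------------------
# intensity-time curves and PI

def compartment_curves(
    series: AngioSeries, masks: CompartmentMasks
) -> tuple[ITCurve, ITCurve]:
    """Per-frame mean intensity over the primary vessel (VIF) and EV masks."""
    pv = masks.primary_vessel if masks.primary_vessel is not None else masks.vessel
    if not pv.any() or not masks.extravascular.any():
        raise InvalidInputError("compartment masks must be non-empty")
    flat = series.frames.reshape(series.frames.shape[0], -1)
    # matrix product against normalized indicator weights: one BLAS pass
    weights = np.stack(
        [pv.ravel() / pv.sum(), masks.extravascular.ravel() / masks.extravascular.sum()],
        axis=1,
    ).astype(flat.dtype, copy=False)
    means = flat @ weights
    vif = ITCurve(t=series.times, intensity=means[:, 0].astype(float))
    ev = ITCurve(t=series.times, intensity=means[:, 1].astype(float))
    return vif, ev


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y.astype(float)
    return ndimage.uniform_filter1d(y.astype(float), size=width, mode="nearest")


def find_clearance_window(
    vif: ITCurve,
    band: tuple[float, float] = (-1.0, 0.0),
    smooth_width: int = 5,
    normalize: bool = False,
) -> ClearanceWindow:
    """Locate the clearance-phase window on a clearing-tracer VIF.

    The VIF is smoothed with a ``smooth_width``-sample moving average; its
    derivative (central differences, a.u./s, optionally on the peak-normalized
    curve) is scanned after the global maximum.  ``t_cr`` is the first
    post-maximum sample at which the derivative has settled into the band
    ``(band[0], band[1]]`` — i.e. the first in-band sample after the
    derivative's last excursion below the band (the brief pass through the
    band at the peak itself, before the steep clearance drop, is not the
    clearance phase).  ``t_end`` is the last sample time.
    """
    y = _smooth(vif.intensity, smooth_width)
    if normalize:
        peak = y.max()
        if peak <= 0:
            raise InvalidInputError("VIF must have a positive peak to normalize")
        y = y / peak
    i_max = int(y.argmax())
    if i_max >= y.size - 1:
        raise WindowNotFoundError("VIF maximum is at the last sample")
    deriv = np.gradient(y, vif.t)
    lo, hi = band
    post = np.arange(i_max + 1, y.size)
    below = post[deriv[post] <= lo]
    start = int(below[-1]) + 1 if below.size else i_max + 1
    post = post[post >= start]
    ok = post[(deriv[post] > lo) & (deriv[post] <= hi)]
    ok = ok[ok < y.size - 1]
    if ok.size == 0:
        raise WindowNotFoundError(
            f"no post-maximum sample with derivative in ({lo}, {hi}]"
        )
    return ClearanceWindow(t_cr=float(vif.t[ok[0]]), t_end=float(vif.t[-1]))


def pi_clearance(ev: ITCurve, vif: ITCurve, window: ClearanceWindow) -> PIResult:
    """Clearance-phase permeability index.

    ``PI = (1/T) * integral_{t_cr}^{t_end} I_EV(t)/I_VIF(t) dt`` by
    trapezoidal quadrature on the native sample grid.
    """
    if ev.t.shape != vif.t.shape or not np.allclose(ev.t, vif.t):
        raise InvalidInputError("EV and VIF curves must share a time grid")
    eps = 1e-9 * max(1.0, abs(window.t_end))  # float-safe window edges
    sel = (vif.t >= window.t_cr - eps) & (vif.t <= window.t_end + eps)
    if sel.sum() < 2:
        raise InvalidInputError("window contains fewer than two samples")
    v = vif.intensity[sel]
    if np.any(v <= 0):
        raise DivisionGuardError("VIF is non-positive inside the clearance window")
    ratio = ev.intensity[sel] / v
    pi = float(np.trapezoid(ratio, vif.t[sel]) / window.T)
    return PIResult(pi=pi, mode="clearance", window=window)


def _weighted_histogram_vector(
    values: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Weighted intensity vector x_i * f_i over occupied histogram bins."""
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    freqs = counts[occupied] / counts.sum()
    return centers[occupied] * freqs


def pi_histogram(
    series: AngioSeries,
    masks: CompartmentMasks,
    frame_index: int = -1,
    bins: int = 64,
) -> PIResult:
    """Accumulating-tracer permeability index from signal histograms.

    On the chosen frame (default: last, after accumulation), per-compartment
    relative-frequency histograms over ``bins`` equal-width bins spanning the
    pooled intensity range are formed, the weighted vectors ``x_i * f_i``
    (bin center times relative frequency) are jointly MWU-ranked, and
    ``PI = mean rank(EV) / mean rank(vessel)``.
    """
    if series.tracer_mode != ACCUMULATING:
        raise InvalidInputError("pi_histogram requires an accumulating tracer")
    pv = masks.primary_vessel if masks.primary_vessel is not None else masks.vessel
    img = np.asarray(series.frames[frame_index], dtype=float)
    ev_px = img[masks.extravascular]
    v_px = img[pv]
    if ev_px.size == 0 or v_px.size == 0:
        raise InvalidInputError("both compartments must be non-empty")
    pooled = np.concatenate([ev_px, v_px])
    # robust pooled range: raw min/max ride on single extreme noise pixels,
    # which would jitter the bin grid between acquisitions
    lo, hi = np.percentile(pooled, [0.5, 99.5])
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    ev_px = np.clip(ev_px, lo, hi)
    v_px = np.clip(v_px, lo, hi)
    w_ev = _weighted_histogram_vector(ev_px, edges)
    w_v = _weighted_histogram_vector(v_px, edges)
    for name, w in (("extravascular", w_ev), ("vessel", w_v)):
        if w.size == 1:
            warnings.warn(
                f"{name} compartment occupies a single intensity bin",
                DegenerateHistogramWarning,
                stacklevel=2,
            )
    ranked_ev, ranked_v = stats.mwu_rank(w_ev, w_v)
    return PIResult(pi=stats.mean_rank_ratio(ranked_ev, ranked_v), mode="histogram")


def pi_shift(post: PIResult, baseline: PIResult) -> float:
    """Percent PI change from baseline: ``100 * (post - baseline) / baseline``."""
    if post.mode != baseline.mode:
        raise InvalidInputError("PI results must share a mode to compare")
    if baseline.pi == 0:
        raise InvalidInputError("baseline PI is zero; shift undefined")
    return 100.0 * (post.pi - baseline.pi) / baseline.pi


def call_bbbd(shift: float, null: stats.ShamNull, n_sd: float = 3.0) -> bool:
    """BBB dysfunction call: shift exceeds the sham null by more than 3 SD."""
    return stats.classify_exceedance(shift, null, n_sd=n_sd)


# ---------------------------------------------------------------------------
# end-to-end convenience

def analyze_acquisition(
    series: AngioSeries,
    masks: Optional[CompartmentMasks] = None,
    background_frames: Optional[int] = None,
    window: Optional[ClearanceWindow] = None,
    roi: Optional[np.ndarray] = None,
) -> tuple[PIResult, CompartmentMasks]:
    """Run the full PI pipeline on one acquisition.

    When ``masks`` is given (e.g. segmented on the baseline acquisition of
    the same imaged field) it is reused, which is how paired baseline/post
    comparisons should be scored: the compartments of a field do not change
    between acquisitions, only the tracer kinetics do.  Otherwise vessels are
    segmented on this acquisition's peak frame.  Clearing-mode series are
    background-subtracted using ``background_frames`` pre-injection frames
    (default: the first 2 s); the clearance window may likewise be supplied
    to reuse a window already located on a paired acquisition.
    """
    if masks is None:
        masks = segment_vessels(series)
        masks = select_primary_vessel(masks, roi=roi)
    if series.tracer_mode == CLEARING:
        n_bg = background_frames or max(1, int(round(series.frame_rate * 2)))
        corrected = subtract_background(series, n_bg)
        vif, ev = compartment_curves(corrected, masks)
        if window is None:
            # ~5 s of smoothing: the clearance time constant is two orders
            # of magnitude longer, so the derivative estimate steadies with
            # negligible bias on the exponential tail
            width = max(5, int(round(5.0 * series.frame_rate)))
            window = find_clearance_window(vif, smooth_width=width)
        return pi_clearance(ev, vif, window), masks
    return pi_histogram(series, masks), masks


def trial_pi_shift(
    baseline: AngioSeries,
    post: AngioSeries,
    masks: Optional[CompartmentMasks] = None,
    background_frames: Optional[int] = None,
    roi: Optional[np.ndarray] = None,
) -> tuple[float, PIResult, PIResult]:
    """Percent PI shift of a baseline/post acquisition pair of one field.

    Segmentation — and, for clearing tracers, the clearance window, a
    property of the shared tracer kinetics — are determined once on the
    baseline and applied to both acquisitions.
    """
    pi_base, masks = analyze_acquisition(
        baseline, masks=masks, background_frames=background_frames, roi=roi
    )
    pi_post, _ = analyze_acquisition(
        post, masks=masks, background_frames=background_frames,
        window=pi_base.window,
    )
    return pi_shift(pi_post, pi_base), pi_base, pi_post


# ---------------------------------------------------------------------------
# per-pixel overlay variant

def pixel_pi_map(
    series: AngioSeries, vif: ITCurve, window: ClearanceWindow
) -> np.ndarray:
    """Per-pixel clearance PI map (each pixel's curve against the shared VIF)."""
    eps = 1e-9 * max(1.0, abs(window.t_end))
    sel = (series.times >= window.t_cr - eps) & (series.times <= window.t_end + eps)
    v = vif.intensity[sel]
    if np.any(v <= 0):
        raise DivisionGuardError("VIF is non-positive inside the clearance window")
    ratio = series.frames[sel] / v[:, None, None]
    return np.trapezoid(ratio, series.times[sel], axis=0) / window.T


def pixel_bbbd_map(
    shift_map: np.ndarray,
    null_mean: np.ndarray | float,
    null_sd: np.ndarray | float,
    n_sd: float = 3.0,
) -> np.ndarray:
    """Pixelwise 3-SD rule against a pixelwise (or pooled scalar) sham null."""
    return np.asarray(shift_map) > np.asarray(null_mean) + n_sd * np.asarray(null_sd)
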