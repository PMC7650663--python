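"""Safety-endpoint detection on rodent brain MRI.

Two voxelwise procedures quantify structural and vascular abnormality:

* T2 hyperintensity (edema): brain voxels whose own intensity AND mean 3x3
  in-plane environmental intensity exceed the distribution of a contralateral
  control region by an MWU-rank criterion;
* DCE-based BBB dysfunction: after registration and pre-contrast subtraction
  of a 7-scan dynamic contrast-enhanced T1 series, an ordinary least-squares
  line is fitted per voxel to the post-contrast enhancement.  A voxel is
  flagged when the slope is statistically significant (p < 0.05), positive,
  and both its own slope and its 3x3 environmental mean slope exceed the
  slope distribution of the temporal muscle (a tissue without a blood-brain
  barrier) by the same rank criterion.

Each detection yields a relative volume: flagged voxels / brain voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from skimage.registration import phase_cross_correlation

from . import stats
from .exceptions import InvalidInputError, RegistrationError, SegmentationError

__all__ = [
    "Volume3D",
    "DCESeries",
    "SlopeMap",
    "DetectionMap",
    "segment_brain",
    "t2_detect",
    "dce_preprocess",
    "voxel_slopes",
    "bbbd_detect",
    "relative_volume",
    "group_compare",
]


@dataclass(frozen=True)
class Volume3D:
    """A 3D intensity volume with an optional brain mask.

    Axes are (slice, row, column); the "3x3 environment" of a voxel is its
    in-plane 8-neighborhood plus itself.  ``hemisphere_split`` is the sagittal
    plane index along the last axis.
    """

    voxels: np.ndarray
    brain_mask: Optional[np.ndarray] = None
    hemisphere_split: Optional[int] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise InvalidInputError("voxels must be a 3D array")
        object.__setattr__(self, "voxels", v)
        if self.brain_mask is not None:
            m = np.asarray(self.brain_mask, dtype=bool)
            if m.shape != v.shape:
                raise InvalidInputError("brain_mask must match the voxel grid")
            object.__setattr__(self, "brain_mask", m)


@dataclass(frozen=True)
class DCESeries:
    """An ordered dynamic contrast-enhanced T1 series.

    ``scans`` is a (n_scans, z, y, x) array; contrast is administered after
    scan ``contrast_index`` (1-based count of pre-contrast scans, default 1).
    ``enhancement`` holds post-contrast minus pre-contrast volumes once
    preprocessed.
    """

    scans: np.ndarray
    times: np.ndarray
    contrast_index: int = 1
    brain_mask: Optional[np.ndarray] = None
    muscle_mask: Optional[np.ndarray] = None
    enhancement: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        scans = np.asarray(self.scans, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if scans.ndim != 4:
            raise InvalidInputError("scans must be a (n_scans, z, y, x) array")
        if times.size != scans.shape[0]:
            raise InvalidInputError("times must match the number of scans")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("scan times must be increasing")
        n_post = scans.shape[0] - self.contrast_index
        if n_post < 3:
            raise InvalidInputError("need at least 3 post-contrast scans")
        object.__setattr__(self, "scans", scans)
        object.__setattr__(self, "times", times)


@dataclass(frozen=True)
class SlopeMap:
    """Per-voxel enhancement slope and significance (a.u./scan)."""

    slope: np.ndarray
    p_value: np.ndarray
    muscle_mask: np.ndarray


@dataclass(frozen=True)
class DetectionMap:
    """Binary detection over the brain with its relative volume (fraction)."""

    flagged: np.ndarray
    relative_volume: float
    kind: str  # "t2_hyperintense" | "bbbd"


# ---------------------------------------------------------------------------
# segmentation

def _border_shell(shape: tuple[int, ...], width: int = 2) -> np.ndarray:
    shell = np.ones(shape, dtype=bool)
    shell[width:-width, width:-width, width:-width] = False
    return shell


def segment_brain(
    volume: Volume3D,
    seed_fraction: float = 0.25,
    support_percentiles: tuple[float, float] = (1.0, 99.0),
) -> Volume3D:
    """Histogram-based brain segmentation.

    A central ellipsoid seeds the brain signal histogram and the outer border
    shell seeds the peripheral histogram; voxels are kept when their intensity
    lies within the brain-histogram support and outside the peripheral
    support.  The brain support is one-sided (lower bound only) so that
    hyperintense pathology remains part of the brain mask.  The largest
    connected component is retained; border-shell voxels are excluded by
    construction.
    """
    v = volume.voxels
    zc, yc, xc = (np.asarray(v.shape) - 1) / 2.0
    zz, yy, xx = np.ogrid[: v.shape[0], : v.shape[1], : v.shape[2]]
    central = (
        ((zz - zc) / (seed_fraction * v.shape[0])) ** 2
        + ((yy - yc) / (seed_fraction * v.shape[1])) ** 2
        + ((xx - xc) / (seed_fraction * v.shape[2])) ** 2
    ) <= 1.0
    shell = _border_shell(v.shape)
    lo_p, hi_p = support_percentiles
    b_lo = np.percentile(v[central], lo_p)
    p_lo, p_hi = np.percentile(v[shell], [lo_p, hi_p])
    in_brain = v >= b_lo
    in_periph = (v >= p_lo) & (v <= p_hi)
    mask = in_brain & ~in_periph & ~shell
    if not mask.any():
        raise SegmentationError(
            "brain and peripheral signal ranges are not separable"
        )
    lab, n = ndimage.label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = lab == sizes.argmax()
    return replace(volume, brain_mask=mask)


# ---------------------------------------------------------------------------
# environmental means and rank criterion

def _environment_mean(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked 3x3 in-plane (self + 8-neighbor) mean of ``values``.

    Voxels outside ``mask`` contribute neither to their neighbors' means nor
    receive one.
    """
    m = mask.astype(float)
    num = ndimage.uniform_filter(np.where(mask, values, 0.0), size=(1, 3, 3))
    den = ndimage.uniform_filter(m, size=(1, 3, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        env = num / den
    env[~mask] = 0.0
    return env


def _rank_exceeds(
    values: np.ndarray, control: np.ndarray, q: float
) -> np.ndarray:
    """MWU-rank exceedance: value above the q-th rank quantile of control."""
    if control.size == 0:
        raise InvalidInputError("control sample is empty")
    thr = np.quantile(control, q)
    return values > thr


def t2_detect(
    volume: Volume3D,
    control_region: Optional[np.ndarray] = None,
    q: float = 0.95,
    rule: str = "quantile",
) -> DetectionMap:
    """Detect hyperintense (edema-like) voxels against a contralateral control.

    A voxel is flagged when BOTH its own intensity and its 3x3 in-plane
    environmental mean exceed the control distribution by the MWU-rank
    criterion.  ``control_region`` defaults to the brain voxels of the
    hemisphere on the low side of ``hemisphere_split`` (lesions placed inside
    the control hemisphere lower sensitivity; supply an explicit control to
    avoid that).  ``rule`` selects the rank-quantile criterion (default) or a
    per-voxel one-sided MWU test of the voxel's 9-sample environment against
    the control sample at level ``1 - q``.
    """
    if volume.brain_mask is None:
        raise InvalidInputError("volume must be brain-segmented first")
    brain = volume.brain_mask
    v = volume.voxels
    if control_region is None:
        if volume.hemisphere_split is None:
            raise InvalidInputError(
                "need hemisphere_split or an explicit control region"
            )
        xs = np.arange(v.shape[2])
        control_region = brain & (xs[None, None, :] < volume.hemisphere_split)
    control_region = np.asarray(control_region, dtype=bool)
    if not control_region.any():
        raise InvalidInputError("control region is empty")
    env = _environment_mean(v, brain)
    if rule == "quantile":
        self_ok = _rank_exceeds(v, v[control_region], q)
        env_ok = _rank_exceeds(env, env[control_region], q)
    elif rule == "mwu":
        p_map = _env_mwu_pmap(v, brain, control_region)
        self_ok = _rank_exceeds(v, v[control_region], q)
        env_ok = p_map < (1.0 - q)
    else:
        raise InvalidInputError(f"unknown rule {rule!r}")
    flagged = brain & self_ok & env_ok
    return DetectionMap(
        flagged=flagged,
        relative_volume=float(flagged.sum() / brain.sum()),
        kind="t2_hyperintense",
    )


def _env_mwu_pmap(
    values: np.ndarray, mask: np.ndarray, control_region: np.ndarray
) -> np.ndarray:
    """One-sided (greater) MWU p-value of each voxel's 3x3 environment sample
    against the control sample, vectorized via the normal approximation."""
    control = np.sort(values[control_region])
    m = control.size
    # environment samples: stack the 9 in-plane neighbors of every voxel
    padded = np.pad(values, ((0, 0), (1, 1), (1, 1)), mode="edge")
    pmask = np.pad(mask, ((0, 0), (1, 1), (1, 1)), mode="constant")
    env_vals, env_valid = [], []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            env_vals.append(
                padded[:, 1 + dy : padded.shape[1] - 1 + dy,
                       1 + dx : padded.shape[2] - 1 + dx]
            )
            env_valid.append(
                pmask[:, 1 + dy : pmask.shape[1] - 1 + dy,
                      1 + dx : pmask.shape[2] - 1 + dx]
            )
    env_vals = np.stack(env_vals)      # (9, z, y, x)
    env_valid = np.stack(env_valid)
    below = np.searchsorted(control, env_vals, side="left")
    upto = np.searchsorted(control, env_vals, side="right")
    # U contribution of each environment member vs control, with tie halving
    u_each = below + 0.5 * (upto - below)
    u = np.where(env_valid, u_each, 0.0).sum(axis=0)
    n = env_valid.sum(axis=0).astype(float)
    mu = n * m / 2.0
    sigma = np.sqrt(n * m * (n + m + 1) / 12.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - mu - 0.5) / sigma
    p = sps.norm.sf(z)
    p[~mask] = 1.0
    return p


# ---------------------------------------------------------------------------
# DCE pipeline

def dce_preprocess(series: DCESeries, segment: bool = True) -> DCESeries:
    """Register all scans to the first, segment the brain, and subtract the
    pre-contrast scan to form per-voxel enhancement time-series."""
    scans = series.scans
    ref = scans[0]
    registered = np.empty_like(scans)
    registered[0] = ref
    for i in range(1, scans.shape[0]):
        if not np.any(scans[i]):
            raise RegistrationError(f"scan {i} is all zero; cannot register")
        shift, _, _ = phase_cross_correlation(
            ref, scans[i], upsample_factor=4, normalization=None
        )
        registered[i] = ndimage.shift(scans[i], shift, order=1, mode="nearest")
    brain_mask = series.brain_mask
    if segment and brain_mask is None:
        brain_mask = segment_brain(Volume3D(voxels=registered[0])).brain_mask
    pre = registered[: series.contrast_index].mean(axis=0)
    enhancement = registered[series.contrast_index :] - pre
    return replace(
        series, scans=registered, brain_mask=brain_mask, enhancement=enhancement
    )


def voxel_slopes(series: DCESeries) -> SlopeMap:
    """Per-voxel OLS slope of post-contrast enhancement versus scan index.

    The regression runs over the post-contrast enhancement values against the
    (dimensionless) scan index.  Two-sided p-values come from the slope
    t-statistic with ``n - 2`` degrees of freedom; a perfectly flat voxel
    (zero slope, zero residual) gets p = 1 by convention, a perfectly linear
    nonzero slope gets p = 0.
    """
    if series.enhancement is None:
        raise InvalidInputError("series must be preprocessed (dce_preprocess)")
    y = series.enhancement  # (n_post, z, y, x)
    n = y.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 post-contrast points")
    x = np.arange(1, n + 1, dtype=float)
    xm = x - x.mean()
    sxx = float(np.sum(xm**2))
    ym = y - y.mean(axis=0)
    slope = np.tensordot(xm, ym, axes=(0, 0)) / sxx
    resid = ym - slope[None] * xm[:, None, None, None]
    sse = np.sum(resid**2, axis=0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sse / df / sxx)
        t = slope / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    exact = sse <= 0
    p = np.where(exact, np.where(slope == 0, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    muscle = series.muscle_mask
    if muscle is None:
        muscle = np.zeros(slope.shape, dtype=bool)
    return SlopeMap(slope=slope, p_value=p, muscle_mask=np.asarray(muscle, bool))


def bbbd_detect(
    slopes: SlopeMap,
    brain: Volume3D,
    q: float = 0.95,
    p_threshold: float = 0.05,
    fdr_correct: bool = False,
) -> DetectionMap:
    """Multi-criteria BBB-dysfunction voxel classifier.

    Flags brain voxels satisfying ALL of: significant regression
    (p < ``p_threshold``), positive slope (accumulation rather than washout),
    and own + 3x3 environmental mean slope above the temporal-muscle slope
    distribution by the MWU-rank criterion at quantile ``q``.  Per-voxel
    p-values are uncorrected by default (the per-voxel decision rule);
    ``fdr_correct=True`` applies Benjamini-Hochberg across brain voxels.
    """
    if brain.brain_mask is None:
        raise InvalidInputError("brain volume must be segmented")
    if not slopes.muscle_mask.any():
        raise InvalidInputError("muscle mask is empty")
    bm = brain.brain_mask
    p_value = slopes.p_value
    if fdr_correct:
        p_value = np.ones_like(p_value)
        p_value[bm] = sps.false_discovery_control(slopes.p_value[bm])
    muscle_slopes = slopes.slope[slopes.muscle_mask]
    env = _environment_mean(slopes.slope, bm | slopes.muscle_mask)
    muscle_env = env[slopes.muscle_mask]
    flagged = (
        bm
        & (p_value < p_threshold)
        & (slopes.slope > 0)
        & _rank_exceeds(slopes.slope, muscle_slopes, q)
        & _rank_exceeds(env, muscle_env, q)
    )
    return DetectionMap(
        flagged=flagged,
        relative_volume=float(flagged.sum() / bm.sum()),
        kind="bbbd",
    )


def relative_volume(detection: DetectionMap, brain: Volume3D) -> float:
    """Flagged-to-brain voxel count ratio, as a percentage."""
    if brain.brain_mask is None or not brain.brain_mask.any():
        raise InvalidInputError("brain mask is empty")
    if np.any(detection.flagged & ~brain.brain_mask):
        raise InvalidInputError("flagged voxels must lie inside the brain mask")
    return 100.0 * detection.flagged.sum() / brain.brain_mask.sum()


def group_compare(real_volumes, sham_volumes) -> dict:
    """Unpaired two-tailed Mann-Whitney comparison of relative volumes.

    Returns the test statistic and p-value together with group means +/- SEM.
    """
    real = np.asarray(real_volumes, dtype=float)
    sham = np.asarray(sham_volumes, dtype=float)
    stat, p = stats.two_sample_test(real, sham, paired=False)
    return {
        "statistic": stat,
        "p_value": p,
        "real_mean": float(real.mean()),
        "real_sem": float(sps.sem(real)) if real.size > 1 else float("nan"),
        "sham_mean": float(sham.mean()),
        "sham_sem": float(sps.sem(sham)) if sham.size > 1 else float("nan"),
    }
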