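"""Particle morphometry for hot-stage microscopy image series.

A biomass particle sitting on a heated stage is imaged every few seconds
while the stage ramps from ambient to pyrolysis temperatures.  This module
segments the particle in every frame, converts pixel counts into an area
trajectory relative to the first frame, smooths the trajectory against
temperature with a penalized cubic spline, and locates the two landmark
temperatures of interest: the point of maximum shrinkage rate (the most
negative derivative of the smoothed trajectory) and, where present, a
swelling peak where the particle transiently grows beyond its initial size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.registration import phase_cross_correlation

from .exceptions import (
    CannotInitializeTrackError,
    DegenerateImageError,
    InsufficientDataError,
)
from .smoothing import PenalizedSplineSmoother

__all__ = [
    "ThermalImageSeries",
    "AreaTrajectory",
    "TransitionReport",
    "SegmentationResult",
    "isodata_threshold",
    "segment_particles",
    "extract_trajectory",
    "fit_trajectory_smoother",
    "detect_transitions",
    "register_translation",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ThermalImageSeries:
    """Registered grayscale frames stamped with acquisition time and stage
    temperature.

    Frames are row-major with origin at the top-left; all frames share one
    shape.  Time must be strictly increasing and temperature non-decreasing
    (a monotone heating ramp).
    """

    frames: list[np.ndarray]
    time_s: np.ndarray
    temperature_C: np.ndarray
    pixel_size: float | None = None  # um per pixel, optional

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        if not (len(self.frames) == self.time_s.size == self.temperature_C.size):
            raise ValueError("frames, time_s and temperature_C must have equal length")
        if self.frames:
            shape = self.frames[0].shape
            if any(f.shape != shape for f in self.frames):
                raise ValueError("all frames must share one shape")
        if self.time_s.size > 1:
            if not np.all(np.diff(self.time_s) > 0):
                raise ValueError("time_s must be strictly increasing")
            if not np.all(np.diff(self.temperature_C) >= 0):
                raise ValueError("temperature_C must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class AreaTrajectory:
    """Per-frame particle area, relative to the first frame, with an optional
    smooth fit and its temperature derivative."""

    temperature_C: np.ndarray
    time_s: np.ndarray
    area_px: np.ndarray  # NaN where the particle was lost
    relative_area: np.ndarray
    smooth_fit: np.ndarray | None = None
    band_low: np.ndarray | None = None
    band_high: np.ndarray | None = None
    d_dT: np.ndarray | None = None
    smoother: PenalizedSplineSmoother | None = field(default=None, repr=False)


@dataclass
class TransitionReport:
    """Landmark temperatures extracted from a smoothed area trajectory."""

    T_max_shrink_rate: float
    T_swell_peak: float | None
    swell_magnitude: float
    shrink_onset_window: tuple[float, float]


@dataclass
class SegmentationResult:
    """Per-frame label masks plus particle areas and empty-frame flags."""

    labels: list[np.ndarray]
    areas: list[dict[int, int]]  # label -> pixel count, holes filled
    empty_frames: list[bool]


# ---------------------------------------------------------------------------
# thresholding and segmentation
# ---------------------------------------------------------------------------

def isodata_threshold(image: np.ndarray, tol: float = 0.5, max_iter: int = 500) -> float:
    """Iterative intermeans (IsoData) threshold.

    Starting from the global mean, iterate ``t <- (mean(I <= t) + mean(I > t)) / 2``
    until the update is smaller than ``tol`` intensity levels.  Deterministic;
    equivariant to intensity shifts and (up to the stopping tolerance)
    to positive rescaling.
    """
    vals = np.asarray(image, dtype=float).ravel()
    if vals.size == 0 or vals.max() == vals.min():
        raise DegenerateImageError("image has no intensity contrast")
    t = float(vals.mean())
    for _ in range(max_iter):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            # threshold drifted past the data range; nudge back to the mean
            t = float(vals.mean())
            continue
        t_new = 0.5 * (float(lo.mean()) + float(hi.mean()))
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    return t


def segment_particles(
    series: ThermalImageSeries,
    polarity: str = "dark",
    min_area_px: int = 25,
) -> SegmentationResult:
    """Threshold and label particles in every frame.

    Each frame is binarized with the IsoData threshold, the requested polarity
    side is kept (``"dark"`` for dark particles on a bright background,
    ``"bright"`` for the reverse), 8-connected components smaller than
    ``min_area_px`` are discarded and internal holes are filled, so reported
    areas are silhouette areas.  A frame in which nothing survives yields an
    empty mask and a warning flag rather than an error.
    """
    if polarity not in ("dark", "bright"):
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    labels_out: list[np.ndarray] = []
    areas_out: list[dict[int, int]] = []
    empty: list[bool] = []
    for frame in series.frames:
        t = isodata_threshold(frame)
        mask = frame <= t if polarity == "dark" else frame > t
        lab = measure.label(mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        keep = np.flatnonzero(counts >= min_area_px)
        keep = keep[keep != 0]
        kept_mask = np.isin(lab, keep)
        kept_mask = ndimage.binary_fill_holes(kept_mask)
        lab = measure.label(kept_mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        areas = {int(i): int(counts[i]) for i in range(1, counts.size)}
        if not areas:
            warnings.warn("no particle survived filtering in a frame", stacklevel=2)
        labels_out.append(lab)
        areas_out.append(areas)
        empty.append(not areas)
    return SegmentationResult(labels=labels_out, areas=areas_out, empty_frames=empty)


def _centroid(lab: np.ndarray, label: int) -> np.ndarray:
    return np.array(ndimage.center_of_mass(lab == label))


def extract_trajectory(
    seg: SegmentationResult,
    series: ThermalImageSeries,
    tracking: str = "largest",
) -> AreaTrajectory:
    """Reduce per-frame masks to one relative-area trajectory.

    ``tracking`` selects which area is followed across frames:

    - ``"largest"`` — the largest connected component per frame;
    - ``"nearest-centroid"`` — the component whose centroid is closest to the
      previously tracked one;
    - ``"sum"`` — total area of all retained particles (matches measuring a
      whole field of arranged particles at once).

    Frames where the particle is lost contribute NaN, not zero, so the
    smoother can skip them.
    """
    if tracking not in ("largest", "nearest-centroid", "sum"):
        raise ValueError(f"unknown tracking mode {tracking!r}")
    if not seg.areas or not seg.areas[0]:
        raise CannotInitializeTrackError("first frame contains no particle")

    areas = np.full(len(seg.labels), np.nan)
    prev_centroid: np.ndarray | None = None
    for i, (lab, frame_areas) in enumerate(zip(seg.labels, seg.areas)):
        if not frame_areas:
            continue
        if tracking == "sum":
            areas[i] = float(sum(frame_areas.values()))
            continue
        if tracking == "largest" or prev_centroid is None:
            label = max(frame_areas, key=frame_areas.__getitem__)
        else:
            label = min(
                frame_areas,
                key=lambda l: float(np.sum((_centroid(lab, l) - prev_centroid) ** 2)),
            )
        areas[i] = float(frame_areas[label])
        if tracking == "nearest-centroid":
            prev_centroid = _centroid(lab, label)

    return AreaTrajectory(
        temperature_C=series.temperature_C.copy(),
        time_s=series.time_s.copy(),
        area_px=areas,
        relative_area=areas / areas[0],
    )


# ---------------------------------------------------------------------------
# smoothing and transition detection
# ---------------------------------------------------------------------------

def fit_trajectory_smoother(
    traj: AreaTrajectory,
    basis_dim: int = 20,
    ci_bootstrap_B: int = 200,
    seed: int | None = 0,
) -> AreaTrajectory:
    """Fit a penalized cubic regression spline of relative area on temperature.

    The penalty weight is chosen by generalized cross-validation.  A pointwise
    95% confidence band is obtained by case-resampling bootstrap with
    ``ci_bootstrap_B`` replicates (``0`` disables the band).  The derivative
    ``d_dT`` comes from analytic differentiation of the fitted spline.
    """
    x = traj.temperature_C
    y = traj.relative_area
    if np.sum(np.isfinite(x) & np.isfinite(y)) < 10:
        raise InsufficientDataError("need at least 10 non-missing points")
    sm = PenalizedSplineSmoother(n_basis=basis_dim).fit(x, y)
    fit = sm.predict(x)
    band = sm.bootstrap_band(x, y, x, n_boot=ci_bootstrap_B, seed=seed)
    lo, hi = band if band is not None else (None, None)
    return replace(
        traj,
        smooth_fit=fit,
        band_low=lo,
        band_high=hi,
        d_dT=sm.derivative(x),
        smoother=sm,
    )


def detect_transitions(
    traj: AreaTrajectory,
    swell_margin: float = 0.01,
    interior_trim: float = 0.05,
    n_grid: int = 2001,
) -> TransitionReport:
    """Locate the maximum-shrinkage-rate temperature and any swelling peak.

    Both landmarks are read off the fitted spline evaluated on a dense
    temperature grid restricted to the interior ``1 - 2*interior_trim`` of the
    observed range (spline fits are least reliable at the boundary).  A
    swelling peak is only reported when the smoothed trajectory exceeds
    ``1 + swell_margin``.
    """
    if traj.smoother is None or traj.smooth_fit is None:
        raise ValueError("trajectory has no smooth fit; run fit_trajectory_smoother")
    t = traj.temperature_C[np.isfinite(traj.temperature_C)]
    lo, hi = float(t.min()), float(t.max())
    span = hi - lo
    grid = np.linspace(lo + interior_trim * span, hi - interior_trim * span, n_grid)
    fit = traj.smoother.predict(grid)
    dfit = traj.smoother.derivative(grid)

    i_min = int(np.nanargmin(dfit))
    T_shrink = float(grid[i_min])
    d_min = float(dfit[i_min])

    below_half = np.flatnonzero(dfit < 0.5 * d_min)
    window = (
        (float(grid[below_half[0]]), float(grid[below_half[-1]]))
        if below_half.size
        else (T_shrink, T_shrink)
    )

    swell = fit > 1.0 + swell_margin
    if np.any(swell):
        i_swell = int(np.nanargmax(np.where(swell, fit, -np.inf)))
        T_swell: float | None = float(grid[i_swell])
        swell_mag = float(fit[i_swell] - 1.0)
    else:
        T_swell = None
        swell_mag = 0.0

    return TransitionReport(
        T_max_shrink_rate=T_shrink,
        T_swell_peak=T_swell,
        swell_magnitude=swell_mag,
        shrink_onset_window=window,
    )


# ---------------------------------------------------------------------------
# plumbing
# ---------------------------------------------------------------------------

def register_translation(reference: np.ndarray, moving: np.ndarray) -> tuple[float, float]:
    """Rigid translation (row, col) that registers ``moving`` onto
    ``reference``, by phase correlation with 0.1 px upsampling.  Provided as
    a convenience for series that are not already registered; the analysis
    assumes registered input."""
    shift, _, _ = phase_cross_correlation(reference, moving, upsample_factor=10)
    return float(shift[0]), float(shift[1])
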