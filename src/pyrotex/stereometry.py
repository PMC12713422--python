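"""Surface reconstruction and roughness analysis from SEM tilt pairs.

Two micrographs of the same field taken at a known relative specimen tilt
encode surface relief as parallax: a point at height ``z`` above the tilt
axis shifts laterally by ``2 z sin(theta/2)`` between the two views.  This
module recovers that disparity by normalized-cross-correlation block
matching with parabolic sub-pixel refinement, converts it to a height map,
levels the map by least-squares plane removal, and derives the standard
areal roughness parameters (Rq, Sp, Sv) plus a detector for the sub-micron
bio-oil droplets that decorate heat-treated biomass surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label

from .exceptions import DegenerateGeometryError, ResolutionError

__all__ = [
    "TiltPair",
    "HeightMap",
    "RoughnessReport",
    "DropletReport",
    "compute_disparity",
    "disparity_to_height",
    "level_plane",
    "roughness_params",
    "detect_droplets",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TiltPair:
    """Two grayscale views of one field separated by ``tilt_angle`` degrees
    about ``tilt_axis`` ('rows' means parallax displaces points along rows,
    i.e. horizontally)."""

    image_a: np.ndarray
    image_b: np.ndarray
    tilt_angle: float  # degrees, total angular separation
    tilt_axis: str = "rows"
    pixel_size: float = 1.0  # um / px

    def __post_init__(self) -> None:
        if self.image_a.shape != self.image_b.shape:
            raise ValueError("tilt-pair images must share one shape")
        if not 0 < self.tilt_angle < 45:
            raise ValueError("tilt_angle must lie in (0, 45) degrees")
        if self.tilt_axis not in ("rows", "cols"):
            raise ValueError("tilt_axis must be 'rows' or 'cols'")


@dataclass
class HeightMap:
    """Surface elevation grid in micrometres with per-pixel validity flags."""

    z: np.ndarray  # um
    pixel_size: float  # um / px
    levelled: bool = False
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.z)


@dataclass
class RoughnessReport:
    rq: float  # RMS height, um
    sp: float  # maximum peak height, um
    sv: float  # maximum valley depth (positive), um
    n_valid: int


@dataclass
class DropletReport:
    droplets: list[dict]  # centroid (row, col) px, equivalent_diameter_nm, height_um
    coverage_class: str  # 'sparse' | 'coated'
    sub500_count: int
    footprint_fraction: float


# ---------------------------------------------------------------------------
# disparity
# ---------------------------------------------------------------------------

def _local_ncc_stack(
    a: np.ndarray, b: np.ndarray, shifts: np.ndarray, axis: int, block_size: int
) -> np.ndarray:
    """NCC between a and b displaced by each shift, over a square block."""
    size = block_size
    mean_a = ndimage.uniform_filter(a, size)
    var_a = ndimage.uniform_filter(a * a, size) - mean_a**2
    std_a = np.sqrt(np.clip(var_a, 0, None))
    out = np.full((shifts.size,) + a.shape, -2.0)
    for k, d in enumerate(shifts):
        b_sh = np.full_like(b, np.nan)
        if d == 0:
            b_sh[...] = b
        elif axis == 1:
            if d > 0:
                b_sh[:, :-d] = b[:, d:]
            else:
                b_sh[:, -d:] = b[:, :d]
        else:
            if d > 0:
                b_sh[:-d, :] = b[d:, :]
            else:
                b_sh[-d:, :] = b[:d, :]
        valid = np.isfinite(b_sh)
        b_f = np.where(valid, b_sh, 0.0)
        mean_b = ndimage.uniform_filter(b_f, size)
        var_b = ndimage.uniform_filter(b_f * b_f, size) - mean_b**2
        std_b = np.sqrt(np.clip(var_b, 0, None))
        cov = ndimage.uniform_filter(a * b_f, size) - mean_a * mean_b
        denom = std_a * std_b
        ncc = np.where(denom > 1e-12, cov / np.where(denom > 1e-12, denom, 1.0), -2.0)
        # any NaN inside the block poisons the estimate; shrink validity
        frac = ndimage.uniform_filter(valid.astype(float), size)
        ncc = np.where(frac > 0.999, ncc, -2.0)
        out[k] = ncc
    return out


def compute_disparity(
    pair: TiltPair,
    block_size: int = 11,
    search_range: int = 16,
    corr_threshold: float = 0.5,
    recenter: bool = True,
    smooth_sigma: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel displacement along the tilt axis between the two views.

    The returned disparity ``d`` satisfies ``image_b(x + d) ≈ image_a(x)``.
    For each candidate integer shift the zero-normalized cross-correlation
    over a ``block_size``-square window is computed; the per-pixel maximum is
    refined to sub-pixel precision by a parabolic fit through the correlation
    peak and its two neighbours.  Pixels whose peak correlation falls below
    ``corr_threshold``, whose peak sits at the search bound, or which lie
    within half a block of the image border are flagged invalid (NaN
    disparity).

    With symmetric ``±d/2`` view geometry the raw match at pixel ``x``
    estimates the disparity of the surface point midway along the
    displacement, i.e. ``d(x + d/2)``; when ``recenter`` is on (default) the
    field is resampled at ``x - d/2`` to undo that first-order offset.
    ``smooth_sigma`` applies a validity-weighted Gaussian post-filter (in px)
    to suppress matching noise; 0 disables it.
    """
    if block_size % 2 == 0:
        raise ValueError("block_size must be odd")
    a = np.asarray(pair.image_a, dtype=float)
    b = np.asarray(pair.image_b, dtype=float)
    axis = 1 if pair.tilt_axis == "rows" else 0
    shifts = np.arange(-search_range, search_range + 1)
    ncc = _local_ncc_stack(a, b, shifts, axis, block_size)

    best = np.argmax(ncc, axis=0)
    peak = np.take_along_axis(ncc, best[None], axis=0)[0]
    valid = (peak >= corr_threshold) & (best > 0) & (best < shifts.size - 1)

    disparity = shifts[best].astype(float)
    # parabolic refinement where the peak has two neighbours
    idx = np.clip(best, 1, shifts.size - 2)
    c0 = np.take_along_axis(ncc, idx[None], axis=0)[0]
    cm = np.take_along_axis(ncc, (idx - 1)[None], axis=0)[0]
    cp = np.take_along_axis(ncc, (idx + 1)[None], axis=0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = cm - 2 * c0 + cp
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (cm - cp) / denom, 0.0)
    delta = np.clip(np.nan_to_num(delta), -1.0, 1.0)

    # blocks overlapping the border see reflected padding; distrust them
    half = block_size // 2
    border = np.zeros_like(valid)
    border[half:-half or None, half:-half or None] = True
    valid &= border

    disparity = np.where(valid, shifts[idx] + delta, np.nan)

    if recenter:
        dfill = np.where(valid, disparity, 0.0)
        rr, cc = np.mgrid[0 : a.shape[0], 0 : a.shape[1]].astype(float)
        if axis == 1:
            coords = np.array([rr, cc - dfill / 2.0])
        else:
            coords = np.array([rr - dfill / 2.0, cc])
        recentred = ndimage.map_coordinates(dfill, coords, order=1, mode="nearest")
        src_ok = ndimage.map_coordinates(
            valid.astype(float), coords, order=1, mode="nearest"
        )
        valid = valid & (src_ok > 0.999)
        disparity = np.where(valid, recentred, np.nan)

    if smooth_sigma > 0:
        dfill = np.where(valid, disparity, 0.0)
        w = valid.astype(float)
        num = ndimage.gaussian_filter(dfill, smooth_sigma)
        den = ndimage.gaussian_filter(w, smooth_sigma)
        smoothed = num / np.where(den > 1e-9, den, 1.0)
        disparity = np.where(valid, smoothed, np.nan)
    return disparity, valid


def disparity_to_height(
    disparity: np.ndarray, tilt_angle: float, pixel_size: float
) -> HeightMap:
    """Symmetric small-angle parallax model: ``z = d * s / (2 sin(theta/2))``.

    Invalid (NaN) disparities propagate to invalid heights.
    """
    if not 0 < tilt_angle < 45:
        raise ValueError("tilt_angle must lie in (0, 45) degrees")
    z = np.asarray(disparity, dtype=float) * pixel_size / (
        2.0 * np.sin(np.deg2rad(tilt_angle) / 2.0)
    )
    return HeightMap(z=z, pixel_size=pixel_size, levelled=False)


def level_plane(hmap: HeightMap) -> HeightMap:
    """Subtract the least-squares best-fit plane over valid pixels."""
    z = np.asarray(hmap.z, dtype=float)
    valid = hmap.valid_mask & np.isfinite(z)
    if int(valid.sum()) < 3:
        raise DegenerateGeometryError("need >= 3 valid pixels to level")
    rows, cols = np.nonzero(valid)
    A = np.column_stack([cols.astype(float), rows.astype(float), np.ones(rows.size)])
    coef, *_ = np.linalg.lstsq(A, z[valid], rcond=None)
    if rows.size >= 3:
        # collinearity check: rank of the design must be 3
        if np.linalg.matrix_rank(A) < 3:
            raise DegenerateGeometryError("valid pixels are collinear")
    cc, rr = np.meshgrid(np.arange(z.shape[1], dtype=float),
                         np.arange(z.shape[0], dtype=float))
    plane = coef[0] * cc + coef[1] * rr + coef[2]
    out = z - plane
    return replace(hmap, z=out, levelled=True, valid_mask=valid)


def roughness_params(hmap: HeightMap) -> RoughnessReport:
    """Areal roughness: Rq (RMS height), Sp (max peak), Sv (max valley depth)."""
    if not hmap.levelled:
        raise ValueError("height map must be levelled first")
    z = hmap.z[hmap.valid_mask & np.isfinite(hmap.z)]
    if z.size == 0:
        raise DegenerateGeometryError("no valid pixels")
    return RoughnessReport(
        rq=float(np.sqrt(np.mean(z**2))),
        sp=float(np.max(z)),
        sv=float(-np.min(z)),
        n_valid=int(z.size),
    )


# ---------------------------------------------------------------------------
# droplets
# ---------------------------------------------------------------------------

def detect_droplets(
    hmap: HeightMap,
    min_height: float = 0.05,
    diameter_cutoff_nm: float = 500.0,
    coverage_cutoff: float = 0.2,
    highpass_window_px: int = 41,
) -> DropletReport:
    """Find droplet-like protrusions on a levelled height map.

    The map is high-passed by subtracting a median-smoothed copy (window much
    larger than a droplet), local maxima above ``min_height`` um are taken as
    droplet apices, each is grown to its half-maximum contour, and the
    equivalent-circle diameter of that footprint is reported in nm.  The
    surface is classed ``"coated"`` when the union of droplet footprints
    covers more than ``coverage_cutoff`` of the valid area.
    """
    if not hmap.levelled:
        raise ValueError("height map must be levelled first")
    cutoff_px = diameter_cutoff_nm / 1000.0 / hmap.pixel_size
    if cutoff_px < 3:
        raise ResolutionError(
            f"diameter cutoff {diameter_cutoff_nm} nm spans {cutoff_px:.1f} px; "
            "need >= 3 px"
        )
    z = np.where(hmap.valid_mask, hmap.z, np.nan)
    filled = np.where(np.isfinite(z), z, np.nanmedian(z))
    hp = filled - ndimage.median_filter(filled, size=highpass_window_px)

    peaks = peak_local_max(hp, min_distance=2, threshold_abs=min_height, exclude_border=False)
    droplets: list[dict] = []
    footprint = np.zeros(hp.shape, dtype=bool)
    for r, c in peaks:
        h = hp[r, c]
        region = cc_label(hp > 0.5 * h, connectivity=2)
        mask = region == region[r, c]
        # a region claimed by a taller, already-recorded peak is skipped
        if footprint[r, c]:
            continue
        area_px = int(mask.sum())
        eq_diam_um = 2.0 * np.sqrt(area_px / np.pi) * hmap.pixel_size
        droplets.append(
            {
                "centroid": (int(r), int(c)),
                "equivalent_diameter_nm": float(eq_diam_um * 1000.0),
                "height_um": float(h),
            }
        )
        footprint |= mask
    n_valid = int(np.sum(hmap.valid_mask))
    frac = float(footprint[hmap.valid_mask].sum()) / max(n_valid, 1)
    sub500 = sum(d["equivalent_diameter_nm"] < diameter_cutoff_nm for d in droplets)
    return DropletReport(
        droplets=droplets,
        coverage_class="coated" if frac > coverage_cutoff else "sparse",
        sub500_count=int(sub500),
        footprint_fraction=frac,
    )
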