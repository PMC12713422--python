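"""Synthetic study generators with known ground truth.

Every downstream stage of the package (morphometry, stereometry, Raman
scoring) is exercised on data produced here, so each generator returns its
ground truth alongside the rendered artifact:

- thermal area trajectories with an optional Gaussian swelling bump near one
  temperature and a logistic shrinkage sigmoid centered at another, rendered
  into image series of a dark particle on a bright background;
- Gaussian-random-field rough surfaces at a prescribed RMS height, with
  optional linear fissures and hemispherical droplets, rendered into
  Lambertian-shaded tilt pairs whose true disparity field is the small-angle
  parallax of the height field;
- composite Raman spectra (per-species signature bands with areas
  proportional to composition, a polynomial fluorescence background, and
  white noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .exceptions import BandWindowError, HeatingProfileError
from .morphometry import ThermalImageSeries
from .raman import BandTable, RamanSpectrum, default_band_table
from .stereometry import HeightMap, TiltPair, level_plane, roughness_params

__all__ = [
    "ShrinkagePreset",
    "SurfaceSpec",
    "SpectrumSpec",
    "PRESETS",
    "REFERENCE_COMPOSITION",
    "DEFAULT_BAND_STRENGTHS",
    "true_relative_area",
    "true_area_derivative",
    "generate_area_trajectory",
    "render_image_series",
    "generate_height_map",
    "render_tilt_pair",
    "generate_spectrum",
]


# ---------------------------------------------------------------------------
# area trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShrinkagePreset:
    """Parametric shape of a particle's relative-area trajectory.

    The trajectory is ``1 + swell_amp * bump(T) - loss * sigmoid(T)`` shifted
    so it equals exactly 1 at the ramp start; the bump is a Gaussian centered
    at ``T_swell`` (absent when ``T_swell`` is None), the loss a logistic
    sigmoid centered at ``T_shrink`` with scale ``shrink_width`` and
    asymptotic floor ``final_area_frac``.
    """

    name: str
    T_shrink: float  # degC, center of the sigmoidal area loss
    shrink_width: float  # degC, logistic scale
    final_area_frac: float  # asymptotic relative area, in (0, 1]
    T_swell: float | None = None  # degC, center of the swelling bump
    swell_amp: float = 0.0  # fractional area gain at the bump peak
    swell_width: float = 20.0  # degC, Gaussian sigma of the bump
    noise_sd: float = 0.0  # relative-area units

    def __post_init__(self) -> None:
        if not 0 < self.final_area_frac <= 1:
            raise ValueError("final_area_frac must lie in (0, 1]")
        if self.shrink_width <= 0:
            raise ValueError("shrink_width must be positive")
        if self.swell_amp < 0:
            raise ValueError("swell_amp must be >= 0")
        if self.swell_amp > 0 and self.T_swell is None:
            raise ValueError("swelling requires T_swell")


#: Per-anatomical-fraction trajectory presets.  All fractions lose area
#: through a sigmoid whose steepest point sits at 375 degC; the cambium and
#: branch fractions additionally swell transiently around 250 degC.  The
#: final area fractions are plausible placeholders, not calibrated values.
PRESETS: dict[str, ShrinkagePreset] = {
    "needles": ShrinkagePreset("needles", 375.0, 14.0, 0.45, noise_sd=0.02),
    "bark": ShrinkagePreset("bark", 375.0, 16.0, 0.55, noise_sd=0.02),
    "cambium": ShrinkagePreset(
        "cambium", 375.0, 12.0, 0.30, T_swell=250.0, swell_amp=0.08, noise_sd=0.02
    ),
    "whitewood": ShrinkagePreset("whitewood", 375.0, 12.0, 0.35, noise_sd=0.02),
    "branch": ShrinkagePreset(
        "branch", 375.0, 13.0, 0.40, T_swell=250.0, swell_amp=0.05, noise_sd=0.02
    ),
}


def _raw_area(T: np.ndarray, p: ShrinkagePreset) -> np.ndarray:
    out = -(1.0 - p.final_area_frac) * expit((T - p.T_shrink) / p.shrink_width)
    if p.T_swell is not None and p.swell_amp > 0:
        out = out + p.swell_amp * np.exp(-0.5 * ((T - p.T_swell) / p.swell_width) ** 2)
    return out


def true_relative_area(T: np.ndarray, preset: ShrinkagePreset, T_start: float = 22.0) -> np.ndarray:
    """Noise-free relative area at temperature T, exactly 1 at ``T_start``."""
    T = np.asarray(T, dtype=float)
    return 1.0 + _raw_area(T, preset) - _raw_area(np.asarray(T_start, dtype=float), preset)


def true_area_derivative(T: np.ndarray, preset: ShrinkagePreset) -> np.ndarray:
    """Analytic dA/dT of the noise-free trajectory (oracle for tests)."""
    T = np.asarray(T, dtype=float)
    s = expit((T - preset.T_shrink) / preset.shrink_width)
    out = -(1.0 - preset.final_area_frac) * s * (1.0 - s) / preset.shrink_width
    if preset.T_swell is not None and preset.swell_amp > 0:
        u = (T - preset.T_swell) / preset.swell_width
        out = out - preset.swell_amp * u / preset.swell_width * np.exp(-0.5 * u**2)
    return out


def generate_area_trajectory(
    preset: ShrinkagePreset,
    T_start: float = 22.0,
    T_end: float = 500.0,
    rate_C_per_min: float = 5.0,
    frame_interval_s: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sampled area trajectory along a linear heating ramp.

    Frames are taken every ``frame_interval_s`` seconds from ramp start until
    the stage reaches ``T_end``; the default ramp (22 to 500 degC at
    5 degC/min, 30 s frames) yields 192 frames.  Returns a table with
    columns ``time_s, temperature_C, true_relative_area, relative_area``
    (the last with additive Gaussian noise of the preset's ``noise_sd``).
    """
    if rate_C_per_min <= 0:
        raise HeatingProfileError("heating rate must be positive")
    t_total = (T_end - T_start) / rate_C_per_min * 60.0
    times = np.arange(0.0, t_total + 1e-9, frame_interval_s)
    temps = T_start + rate_C_per_min * times / 60.0
    true = true_relative_area(temps, preset, T_start=T_start)
    rng = np.random.default_rng(seed)
    noisy = true + rng.normal(0.0, preset.noise_sd, size=true.shape)
    return pd.DataFrame(
        {
            "time_s": times,
            "temperature_C": temps,
            "true_relative_area": true,
            "relative_area": noisy,
        }
    )


# ---------------------------------------------------------------------------
# image-series rendering
# ---------------------------------------------------------------------------

def render_image_series(
    trajectory: pd.DataFrame,
    shape_seed: int = 0,
    frame_shape: tuple[int, int] = (256, 256),
    base_radius_frac: float = 0.30,
    background_level: float = 220.0,
    particle_level: float = 60.0,
    intensity_noise_sd: float = 6.0,
) -> ThermalImageSeries:
    """Render a trajectory into frames of one dark particle on a bright field.

    The particle is a mildly irregular blob (random low-order Fourier
    perturbation of a disk, fixed by ``shape_seed``) whose linear scale is
    ``sqrt(relative_area)``, so its pixel area tracks the trajectory exactly
    up to boundary-pixel rounding.  The ``relative_area`` column (noisy by
    default) drives the rendering.
    """
    rng = np.random.default_rng(shape_seed)
    rows, cols = frame_shape
    r0 = base_radius_frac * min(rows, cols)
    # fixed blob shape: rho(theta) = 1 + sum_k a_k cos(k theta + phi_k)
    ks = np.arange(2, 6)
    amps = rng.normal(0.0, 0.02, size=ks.size)
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)

    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    r_px = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    shape_fn = 1.0 + sum(a * np.cos(k * theta + ph) for a, k, ph in zip(amps, ks, phases))

    rel = np.clip(np.asarray(trajectory.get("relative_area", pd.Series(dtype=float))), 0.0, None)
    max_scale = np.sqrt(rel.max()) if rel.size else 0.0
    if r0 * max_scale * (1.0 + np.abs(amps).sum()) >= min(rows, cols) / 2.0:
        raise ValueError("requested particle area exceeds the frame")

    frames: list[np.ndarray] = []
    for k, a in enumerate(rel):
        radius = r0 * np.sqrt(a) * shape_fn
        mask = r_px <= radius
        img = np.full(frame_shape, background_level, dtype=float)
        img[mask] = particle_level
        img += rng.normal(0.0, intensity_noise_sd, size=frame_shape)
        frames.append(np.clip(img, 0, 255).astype(np.uint8))
    times = trajectory["time_s"].to_numpy(dtype=float) if len(trajectory) else np.empty(0)
    temps = trajectory["temperature_C"].to_numpy(dtype=float) if len(trajectory) else np.empty(0)
    return ThermalImageSeries(frames=frames, time_s=times, temperature_C=temps)


# ---------------------------------------------------------------------------
# rough surfaces and tilt pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of a synthetic rough surface."""

    grid_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5  # um / px
    target_rq: float = 5.0  # um, RMS height after plane levelling
    correlation_length: float = 25.0  # um, e^-1 half-width of the autocorrelation
    n_fissures: int = 0
    fissure_depth: float = 0.0  # um
    fissure_width: float = 1.0  # um, Gaussian half-width of the groove profile
    n_droplets: int = 0
    droplet_diameter_range: tuple[float, float] = (200.0, 400.0)  # nm

    def __post_init__(self) -> None:
        if self.target_rq < 0:
            raise ValueError("target_rq must be >= 0")
        if self.fissure_depth < 0:
            raise ValueError("fissure_depth must be >= 0")
        if self.droplet_diameter_range[0] > self.droplet_diameter_range[1]:
            raise ValueError("droplet_diameter_range must be (low, high)")


def generate_height_map(spec: SurfaceSpec, seed: int = 0) -> tuple[HeightMap, dict]:
    """Gaussian random field surface with prescribed levelled RMS height.

    White noise is smoothed with a Gaussian kernel sized so the field's
    autocorrelation is ``exp(-r^2 / correlation_length^2)``, the best-fit
    plane is removed and the residual rescaled to ``target_rq`` exactly.
    Fissures are then carved as straight grooves with a Gaussian cross
    profile, and droplets added as hemispherical caps; both are logged in the
    returned ground-truth dict (droplet diameters in nm).
    """
    rng = np.random.default_rng(seed)
    rows, cols = spec.grid_shape
    ell_px = spec.correlation_length / spec.pixel_size
    z = rng.standard_normal((rows, cols))
    if ell_px > 0:
        z = ndimage.gaussian_filter(z, sigma=ell_px / 2.0, mode="wrap")
    # level, then rescale residual roughness to the target
    hm = level_plane(HeightMap(z=z, pixel_size=spec.pixel_size))
    rq = roughness_params(hm).rq
    z = hm.z * (spec.target_rq / rq) if rq > 0 else np.zeros_like(hm.z)

    truth: dict = {"target_rq": spec.target_rq, "fissures": [], "droplets": []}

    yy, xx = np.mgrid[0:rows, 0:cols]
    for _ in range(spec.n_fissures):
        r0 = rng.uniform(0.2, 0.8, size=2) * np.array([rows, cols])
        angle = rng.uniform(0, np.pi)
        n_vec = np.array([np.sin(angle), -np.cos(angle)])  # unit normal to the line
        dist_px = (yy - r0[0]) * n_vec[0] + (xx - r0[1]) * n_vec[1]
        w_px = spec.fissure_width / spec.pixel_size
        z = z - spec.fissure_depth * np.exp(-((dist_px / w_px) ** 2))
        truth["fissures"].append(
            {"point": r0.tolist(), "angle_rad": float(angle), "depth_um": spec.fissure_depth}
        )

    margin = 0.1
    for _ in range(spec.n_droplets):
        d_nm = rng.uniform(*spec.droplet_diameter_range)
        r_um = d_nm / 2000.0
        r_px = r_um / spec.pixel_size
        cy = rng.uniform(margin * rows, (1 - margin) * rows)
        cx = rng.uniform(margin * cols, (1 - margin) * cols)
        rr2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cap = np.sqrt(np.clip(r_px**2 - rr2, 0.0, None)) * spec.pixel_size
        z = z + cap
        truth["droplets"].append(
            {"center": (float(cy), float(cx)), "diameter_nm": float(d_nm)}
        )

    return HeightMap(z=z, pixel_size=spec.pixel_size, levelled=False), truth


def render_tilt_pair(
    hmap: HeightMap,
    tilt_angle: float = 15.0,
    illumination: tuple[float, float] = (135.0, 55.0),  # azimuth, elevation degrees
    texture_sd: float = 0.4,
    texture_corr_px: float = 1.2,
    seed: int = 0,
) -> tuple[TiltPair, np.ndarray]:
    """Render a height map into a Lambertian-shaded stereo pair.

    Both views show the same surface radiance (shading times a fine-grained
    albedo texture tied to surface points, emulating SEM surface texture),
    laterally displaced by ``± disparity/2`` along the tilt axis where the
    true disparity is ``z * 2 sin(tilt_angle/2) / pixel_size`` pixels.  The
    exact disparity field is returned alongside the pair for oracle tests.
    """
    if tilt_angle <= 0 or tilt_angle >= 45:
        raise ValueError("tilt_angle must lie in (0, 45) degrees")
    z = np.asarray(hmap.z, dtype=float)
    s = hmap.pixel_size
    disparity = z * 2.0 * np.sin(np.deg2rad(tilt_angle) / 2.0) / s

    # Lambertian shading from the surface normal field
    gy, gx = np.gradient(z, s)
    az, el = np.deg2rad(illumination[0]), np.deg2rad(illumination[1])
    light = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    shade = np.clip((-gx * light[0] - gy * light[1] + light[2]) / norm, 0.0, None)

    rng = np.random.default_rng(seed)
    albedo = rng.standard_normal(z.shape)
    if texture_corr_px > 0:
        albedo = ndimage.gaussian_filter(albedo, texture_corr_px, mode="wrap")
        albedo /= max(albedo.std(), 1e-12)
    radiance = shade * (1.0 + texture_sd * albedo)

    rows, cols = z.shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)

    def _view(sign: float) -> np.ndarray:
        coords = np.array([rr, cc + sign * disparity / 2.0])
        return ndimage.map_coordinates(radiance, coords, order=3, mode="nearest")

    image_a = _view(+1.0)
    image_b = _view(-1.0)
    pair = TiltPair(
        image_a=image_a,
        image_b=image_b,
        tilt_angle=tilt_angle,
        tilt_axis="rows",
        pixel_size=s,
    )
    return pair, disparity


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------

#: Relative Raman cross-sections per signature band.  Aromatic lignin modes
#: (notably the 1600 cm^-1 ring stretch) scatter far more strongly than
#: carbohydrate skeletal modes, which is why lignin dominates raw wood
#: spectra; values are order-of-magnitude literature-informed choices.
DEFAULT_BAND_STRENGTHS: dict[tuple[str, float], float] = {
    ("cellulose", 380.0): 0.8,
    ("cellulose", 1100.0): 1.4,
    ("hemicellulose", 440.0): 0.5,
    ("hemicellulose", 520.0): 0.6,
    ("hemicellulose", 890.0): 0.7,
    ("hemicellulose", 1460.0): 0.9,
    ("lignin", 1210.0): 0.7,
    ("lignin", 1270.0): 1.0,
    ("lignin", 1330.0): 1.1,
    ("lignin", 1600.0): 3.0,
    ("resin", 1660.0): 1.5,
    ("resin", 1740.0): 0.9,
}

#: Reference mass fractions (cellulose, hemicellulose, lignin, resin) per
#: anatomical fraction, standing in for a wet-chemistry assay table.  Values
#: are typical for pine tissues.
REFERENCE_COMPOSITION = pd.DataFrame(
    {
        "cellulose": [0.30, 0.25, 0.35, 0.42, 0.38],
        "hemicellulose": [0.25, 0.20, 0.30, 0.26, 0.28],
        "lignin": [0.30, 0.45, 0.25, 0.28, 0.30],
        "resin": [0.06, 0.04, 0.03, 0.02, 0.03],
    },
    index=pd.Index(["needles", "bark", "cambium", "whitewood", "branch"], name="fraction"),
)


@dataclass(frozen=True)
class SpectrumSpec:
    """Parameters of one synthetic Raman acquisition."""

    composition: dict[str, float] = field(default_factory=dict)  # mass fractions
    wavenumber_start: float = 300.0
    wavenumber_end: float = 1800.0
    wavenumber_step: float = 1.0
    peak_width: float = 5.0  # cm^-1 Gaussian sigma per band
    background_coeffs: tuple[float, ...] = (0.0,)  # polynomial in (w - w_start)/1000
    noise_sd: float = 0.0  # intensity units
    matrix_strength: float = 0.0  # amplitude of the shared band continuum
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavenumber_step <= 0:
            raise ValueError("wavenumber grid must be strictly increasing")
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition entries must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(
            self.wavenumber_start, self.wavenumber_end + self.wavenumber_step / 2,
            self.wavenumber_step,
        )


_MATRIX_TEMPLATE_SEED = 977  # one fixed continuum shared by every spectrum


def _matrix_template(w: np.ndarray, avoid_centers: list[float]) -> np.ndarray:
    """Composition-independent lignocellulose band continuum, peak height 1.

    Real biomass spectra are crowded with overlapping skeletal and C-H modes
    common to all tissues; the narrow signature bands ride on top of that
    continuum and carry only a minor share of the total intensity.  The
    template is a fixed pseudo-random sum of broad Gaussians kept clear of
    the signature band centers (so local-background band integration is
    unaffected), identical for every sample of a study.
    """
    rng = np.random.default_rng(_MATRIX_TEMPLATE_SEED)
    centers = rng.uniform(w[0] + 20.0, w[-1] - 20.0, 60)
    sigmas = rng.uniform(10.0, 22.0, 60)
    amps = rng.lognormal(0.0, 0.5, 60)
    y = np.zeros_like(w)
    for c, s, a in zip(centers, sigmas, amps):
        if any(abs(c - b) < 25.0 for b in avoid_centers):
            continue
        y += a * np.exp(-0.5 * ((w - c) / s) ** 2)
    return y / y.max()


def generate_spectrum(
    spec: SpectrumSpec,
    bands: BandTable | None = None,
    band_strengths: dict[tuple[str, float], float] | None = None,
    meta: dict | None = None,
) -> tuple[RamanSpectrum, dict]:
    """Composite spectrum: signature bands + fluorescence background + noise.

    Each band is a unit-area Gaussian scaled by ``composition[species] *
    band_strength``; the fluorescence background is a polynomial in the
    scaled wavenumber; noise is white Gaussian.  With ``matrix_strength`` >
    0 a fixed composition-independent band continuum (see
    :func:`_matrix_template`) is added, emulating the shared skeletal-mode
    structure of lignocellulose.  The returned ground-truth dict logs every
    band's true area.
    """
    bands = bands if bands is not None else default_band_table()
    strengths = band_strengths if band_strengths is not None else DEFAULT_BAND_STRENGTHS
    w = spec.grid
    intensity = np.zeros_like(w)
    truth_areas: dict[str, dict[float, float]] = {}
    for sp, centers in bands.bands.items():
        conc = float(spec.composition.get(sp, 0.0))
        truth_areas[sp] = {}
        for c in centers:
            if not w[0] <= c <= w[-1]:
                raise BandWindowError(
                    f"band {sp}@{c} cm^-1 lies outside the grid [{w[0]}, {w[-1]}]"
                )
            area = conc * strengths.get((sp, c), 1.0)
            truth_areas[sp][c] = area
            if area > 0:
                intensity += (
                    area
                    / (spec.peak_width * np.sqrt(2 * np.pi))
                    * np.exp(-0.5 * ((w - c) / spec.peak_width) ** 2)
                )
    if spec.matrix_strength > 0:
        all_centers = [c for cs in bands.bands.values() for c in cs]
        intensity = intensity + spec.matrix_strength * _matrix_template(w, all_centers)
    x = (w - spec.wavenumber_start) / 1000.0
    background = np.polynomial.polynomial.polyval(x, spec.background_coeffs)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=w.shape) if spec.noise_sd > 0 else 0.0
    spectrum = RamanSpectrum(
        wavenumber=w,
        intensity=intensity + background + noise,
        meta=meta or {},
        state="raw",
    )
    truth = {"band_areas": truth_areas, "composition": dict(spec.composition)}
    return spectrum, truth
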