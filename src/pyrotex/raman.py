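"""Surface-oriented composition scoring from Raman spectra.

Raman spectra of lignocellulosic biomass sit on a broad fluorescence
background and vary in overall gain between acquisitions.  The workflow here
is: (1) estimate and subtract the background by asymmetric least squares,
(2) normalize each spectrum to unit mean intensity so replicates can be
pooled, (3) integrate a narrow (2 cm^-1 by default) window around each
signature band of each macromolecular species after removing a local linear
background anchored on both sides of the band, (4) sum band intensities into
one score per species, (5) average scores over replicates, and (6) map
scores to mass fractions through a per-species linear calibration fitted on
ambient-temperature samples with known (wet-chemistry) composition.  The
frozen calibration is then applied to heat-treated samples to estimate their
remaining cellulose, hemicellulose, lignin and resin content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import linregress

from .exceptions import (
    BandWindowError,
    CannotNormalizeError,
    InsufficientDataError,
    SpectrumStateError,
)

__all__ = [
    "RamanSpectrum",
    "BandTable",
    "SpeciesScore",
    "CalibrationModel",
    "SPECIES",
    "default_band_table",
    "subtract_baseline",
    "normalize_mean",
    "integrate_band",
    "species_scores",
    "aggregate_replicates",
    "calibrate",
    "estimate_heated_composition",
]

SPECIES = ("cellulose", "hemicellulose", "lignin", "resin")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RamanSpectrum:
    """Single-replicate spectrum with processing-state bookkeeping.

    ``state`` advances strictly raw -> baseline_subtracted -> normalized; the
    processing functions enforce the order so scores are always computed on
    background-free, gain-normalized intensities.
    """

    wavenumber: np.ndarray  # cm^-1, strictly increasing
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)  # sample id, fraction, temperature, replicate
    state: str = "raw"
    baseline: np.ndarray | None = None  # stored for audit after subtraction

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity must have equal length")
        if self.wavenumber.size > 1 and not np.all(np.diff(self.wavenumber) > 0):
            raise ValueError("wavenumber must be strictly increasing")


@dataclass
class BandTable:
    """Signature-band centers per species plus integration geometry.

    ``integration_half_width`` of 1 cm^-1 gives the default 2 cm^-1 window.
    The local background under each band is a straight line between the mean
    intensities of two anchor windows of width ``background_anchor_width``
    centered ``background_anchor_offset`` cm^-1 on either side of the band.
    """

    bands: dict[str, list[float]]
    integration_half_width: float = 1.0
    background_anchor_offset: float = 8.0
    background_anchor_width: float = 2.0

    def __post_init__(self) -> None:
        counts = {"cellulose": 2, "hemicellulose": 4, "lignin": 4, "resin": 2}
        for sp, n in counts.items():
            got = self.bands.get(sp, [])
            if len(got) != n:
                raise ValueError(f"{sp} must list exactly {n} bands, got {len(got)}")
            if len(set(got)) != len(got) or any(c <= 0 for c in got):
                raise ValueError(f"{sp} band centers must be positive and distinct")
        if {380.0, 1100.0} - set(self.bands["cellulose"]):
            raise ValueError("cellulose bands must include 380 and 1100 cm^-1")


def default_band_table() -> BandTable:
    """Band assignments used throughout the package.

    The two cellulose bands (380 and 1100 cm^-1) are canonical; the
    hemicellulose, lignin and resin centers are literature-informed
    placeholders chosen to be mutually well separated, and should be replaced
    with instrument-specific assignments for real data.
    """
    return BandTable(
        bands={
            "cellulose": [380.0, 1100.0],
            "hemicellulose": [440.0, 520.0, 890.0, 1460.0],
            "lignin": [1210.0, 1270.0, 1330.0, 1600.0],
            "resin": [1660.0, 1740.0],
        }
    )


@dataclass
class SpeciesScore:
    species: str
    total_intensity: float
    per_band: dict[float, float]
    negative_bands: list[float] = field(default_factory=list)
    se: float | None = None
    n_replicates: int = 1


@dataclass
class CalibrationModel:
    """Frozen per-species linear maps from Raman score to mass fraction,
    fitted on ambient-temperature samples only."""

    slope: dict[str, float]
    intercept: dict[str, float]
    goodness: dict[str, float]  # Pearson r on the calibration set

    def estimate(self, species: str, score: float, se: float | None = None):
        if species not in self.slope:
            raise KeyError(f"species {species!r} missing from calibration model")
        est = self.slope[species] * score + self.intercept[species]
        est_se = abs(self.slope[species]) * se if se is not None else None
        return est, est_se


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def subtract_baseline(
    spec: RamanSpectrum, lam: float = 1e5, p: float = 0.01, n_iter: int = 10
) -> RamanSpectrum:
    """Asymmetric-least-squares fluorescence background subtraction.

    The baseline minimizes a weighted least-squares criterion with a
    second-difference smoothness penalty ``lam``; points above the current
    baseline get the small weight ``p`` so the fit hugs the underside of the
    peaks (Eilers-style asymmetric least squares).
    """
    if spec.state != "raw":
        raise SpectrumStateError(f"expected raw spectrum, got state={spec.state!r}")
    y = spec.intensity
    n = y.size
    if n < 50:
        raise InsufficientDataError("spectrum must have at least 50 points")
    D = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2), format="csc")
    DDt = lam * (D @ D.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w, format="csc")
        z = spsolve(W + DDt, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return replace(spec, intensity=y - z, state="baseline_subtracted", baseline=z)


def normalize_mean(spec: RamanSpectrum) -> RamanSpectrum:
    """Divide by the mean intensity over the full recorded range, so pooled
    replicates are free of acquisition-gain differences."""
    if spec.state != "baseline_subtracted":
        raise SpectrumStateError(
            f"expected baseline_subtracted spectrum, got state={spec.state!r}"
        )
    m = float(np.mean(spec.intensity))
    if m <= 0 or not np.isfinite(m):
        raise CannotNormalizeError("mean intensity must be positive")
    return replace(spec, intensity=spec.intensity / m, state="normalized")


# ---------------------------------------------------------------------------
# band integration and scoring
# ---------------------------------------------------------------------------

_FINE_STEP = 0.1  # cm^-1; resampling grid for integration


def _window_mean(w: np.ndarray, i: np.ndarray, lo: float, hi: float) -> float:
    fine = np.arange(lo, hi + _FINE_STEP / 2, _FINE_STEP)
    return float(np.mean(np.interp(fine, w, i)))


def integrate_band(
    spec: RamanSpectrum,
    center: float,
    half_width: float = 1.0,
    anchor_offset: float = 8.0,
    anchor_width: float = 2.0,
) -> float:
    """Local-background-corrected integral of a narrow band.

    The spectrum is linearly interpolated to a uniform 0.1 cm^-1 grid over
    ``center ± half_width``; the local background is the straight line
    between the mean intensities of two anchor windows at
    ``center ± anchor_offset`` (width ``anchor_width``); the returned value is
    the trapezoidal integral of intensity minus background over the window.
    Negative values are legitimate (over-subtracted background) and returned
    as-is.
    """
    if spec.state != "normalized":
        raise SpectrumStateError(f"expected normalized spectrum, got {spec.state!r}")
    w, i = spec.wavenumber, spec.intensity
    lo_needed = center - max(half_width, anchor_offset + anchor_width / 2)
    hi_needed = center + max(half_width, anchor_offset + anchor_width / 2)
    if lo_needed < w[0] or hi_needed > w[-1]:
        raise BandWindowError(
            f"band at {center} cm^-1: window/anchors [{lo_needed:.1f}, "
            f"{hi_needed:.1f}] exceed recorded range [{w[0]:.1f}, {w[-1]:.1f}]"
        )
    x_lo = center - anchor_offset
    x_hi = center + anchor_offset
    bg_lo = _window_mean(w, i, x_lo - anchor_width / 2, x_lo + anchor_width / 2)
    bg_hi = _window_mean(w, i, x_hi - anchor_width / 2, x_hi + anchor_width / 2)

    fine = np.arange(center - half_width, center + half_width + _FINE_STEP / 2, _FINE_STEP)
    y = np.interp(fine, w, i)
    bg = bg_lo + (bg_hi - bg_lo) * (fine - x_lo) / (x_hi - x_lo)
    return float(np.trapezoid(y - bg, fine))


def species_scores(spec: RamanSpectrum, table: BandTable) -> list[SpeciesScore]:
    """Per-species total signature-band intensity for one replicate."""
    out: list[SpeciesScore] = []
    for sp in SPECIES:
        per_band: dict[float, float] = {}
        negative: list[float] = []
        for center in table.bands[sp]:
            v = integrate_band(
                spec,
                center,
                half_width=table.integration_half_width,
                anchor_offset=table.background_anchor_offset,
                anchor_width=table.background_anchor_width,
            )
            per_band[center] = v
            if v < 0:
                negative.append(center)
        out.append(
            SpeciesScore(
                species=sp,
                total_intensity=float(sum(per_band.values())),
                per_band=per_band,
                negative_bands=negative,
            )
        )
    return out


def aggregate_replicates(replicate_scores: list[list[SpeciesScore]]) -> list[SpeciesScore]:
    """Mean and standard error of species scores over replicates.

    ``se = sd / sqrt(n)`` with the sample (ddof=1) standard deviation; with a
    single replicate the SE is undefined and reported as ``None``.
    """
    if not replicate_scores:
        raise InsufficientDataError("no replicates to aggregate")
    out: list[SpeciesScore] = []
    for sp in SPECIES:
        vals = np.array(
            [next(s.total_intensity for s in rep if s.species == sp) for rep in replicate_scores]
        )
        n = vals.size
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else None
        out.append(
            SpeciesScore(
                species=sp,
                total_intensity=float(vals.mean()),
                per_band={},
                se=se,
                n_replicates=n,
            )
        )
    return out


# ---------------------------------------------------------------------------
# calibration against reference composition
# ---------------------------------------------------------------------------

def calibrate(
    ambient_scores: pd.DataFrame, reference: pd.DataFrame
) -> CalibrationModel:
    """Fit per-species OLS lines mapping ambient Raman score to mass fraction.

    Both inputs are indexed by anatomical fraction; ``ambient_scores`` holds
    one score column per species, ``reference`` one mass-fraction column per
    species.  At least 3 fractions common to both are required.  A negative
    score-composition correlation is reported (and warned about), not hidden.
    """
    common = ambient_scores.index.intersection(reference.index)
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >= 3 fractions with scores and reference values, got {len(common)}"
        )
    slope: dict[str, float] = {}
    intercept: dict[str, float] = {}
    goodness: dict[str, float] = {}
    for sp in SPECIES:
        res = linregress(
            ambient_scores.loc[common, sp].to_numpy(dtype=float),
            reference.loc[common, sp].to_numpy(dtype=float),
        )
        slope[sp] = float(res.slope)
        intercept[sp] = float(res.intercept)
        goodness[sp] = float(res.rvalue)
        if res.rvalue < 0:
            warnings.warn(
                f"{sp}: score and reference composition are anti-correlated "
                f"(r={res.rvalue:.2f})",
                stacklevel=2,
            )
    return CalibrationModel(slope=slope, intercept=intercept, goodness=goodness)


def estimate_heated_composition(
    model: CalibrationModel, heated_scores: pd.DataFrame, score_se: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Apply the frozen ambient calibration to heat-treated samples.

    Returns a frame with one estimated mass fraction per species (columns)
    per sample (rows), plus ``<species>_se`` columns when score SEs are
    given (propagated as ``|slope| * se``).  Estimates below the ambient
    reference — or below zero — are kept as-is: an apparent deficit is the
    degradation signal, not an artifact to clip.
    """
    out = pd.DataFrame(index=heated_scores.index)
    for sp in SPECIES:
        if sp not in model.slope:
            raise KeyError(f"species {sp!r} missing from calibration model")
        out[sp] = model.slope[sp] * heated_scores[sp] + model.intercept[sp]
        if score_se is not None and sp in score_se:
            out[f"{sp}_se"] = abs(model.slope[sp]) * score_se[sp]
    return out
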