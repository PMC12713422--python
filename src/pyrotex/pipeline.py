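"""Study orchestration: manifests, the three analysis arms, demo data.

A study manifest lists samples by anatomical fraction and treatment
temperature together with the on-disk inputs available for each analysis arm
(heating image series, SEM tilt pair, Raman replicate spectra).  The runner
executes every arm for which inputs are present, isolates per-sample
failures, derives all randomness from the single manifest seed, and emits a
combined per-fraction/per-temperature report with full provenance, so an
identical manifest and seed reproduce the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import morphometry as morph
from . import raman
from . import stereometry as stereo
from . import synthetic

__version__ = "0.1.0"

FRACTIONS = ("needles", "bark", "cambium", "whitewood", "branch", "mixed")
DEFAULT_TEMPERATURES = (22.0, 250.0, 375.0)

#: Multiplicative composition change applied to the reference mass fractions
#: at each quench temperature in the demo study: early cellulose/resin loss
#: by 250 degC, marked cellulose/hemicellulose/resin loss (and mild lignin
#: loss) by 375 degC.
DEGRADATION_FACTORS: dict[float, dict[str, float]] = {
    22.0: {},
    250.0: {"cellulose": 0.85, "resin": 0.70},
    375.0: {"cellulose": 0.60, "hemicellulose": 0.65, "lignin": 0.90, "resin": 0.50},
}

DEFAULT_CONFIG: dict = {
    "morphometry": {
        "polarity": "dark",
        "min_area_px": 25,
        "tracking": "largest",
        "basis_dim": 20,
        "ci_bootstrap_B": 200,
        "swell_margin": 0.01,
        "interior_trim": 0.05,
    },
    "stereometry": {
        "block_size": 15,
        "search_range": 16,
        "corr_threshold": 0.5,
        "droplet_min_height": 0.05,
        "droplet_diameter_cutoff_nm": 500.0,
        "droplet_coverage_cutoff": 0.2,
        "droplet_highpass_window_px": 41,
    },
    "raman": {"baseline_lam": 1e5, "baseline_p": 0.01},
    "allowed_temperatures": list(DEFAULT_TEMPERATURES),
}


def derive_seed(base: int, *parts) -> int:
    """Stable sub-seed from the study seed and a string key (< 2**31)."""
    text = f"{base}|" + "|".join(map(str, parts))
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}) or {})
        else:
            out[k] = override.get(k, v)
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class StudyManifest:
    samples: list[dict]
    seed: int = 0
    config: dict = field(default_factory=dict)
    reference_composition: str | None = None
    root: Path = Path(".")

    def __post_init__(self) -> None:
        allowed_T = set(
            _merge(DEFAULT_CONFIG, self.config).get(
                "allowed_temperatures", DEFAULT_TEMPERATURES
            )
        )
        for s in self.samples:
            if s["fraction"] not in FRACTIONS:
                raise ValueError(f"unknown fraction {s['fraction']!r}")
            if float(s["temperature_C"]) not in allowed_T:
                raise ValueError(
                    f"temperature {s['temperature_C']} not in allowed set {sorted(allowed_T)}"
                )

    @classmethod
    def from_yaml(cls, path: Path | str) -> "StudyManifest":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        return cls(
            samples=data.get("samples", []),
            seed=int(data.get("seed", 0)),
            config=data.get("config", {}) or {},
            reference_composition=data.get("reference_composition"),
            root=path.parent,
        )

    def to_yaml(self, path: Path | str) -> None:
        data = {
            "seed": self.seed,
            "config": self.config,
            "reference_composition": self.reference_composition,
            "samples": self.samples,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class StudyReport:
    table: pd.DataFrame
    failures: list[dict]
    provenance: dict

    def write(self, out_dir: Path | str) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "report.csv", index=False, float_format="%.10g")
        rows = json.loads(self.table.to_json(orient="records"))
        pio.write_json(
            out / "report.json",
            {"provenance": self.provenance, "rows": rows, "failures": self.failures},
        )
        return out


# ---------------------------------------------------------------------------
# arms
# ---------------------------------------------------------------------------

def _morph_arm(sample: dict, root: Path, cfg: dict, seed: int) -> dict:
    series = pio.read_image_series(
        root / sample["images"],
        root / sample["templog"] if sample.get("templog") else None,
    )
    seg = morph.segment_particles(
        series, polarity=cfg["polarity"], min_area_px=cfg["min_area_px"]
    )
    traj = morph.extract_trajectory(seg, series, tracking=cfg["tracking"])
    traj = morph.fit_trajectory_smoother(
        traj,
        basis_dim=cfg["basis_dim"],
        ci_bootstrap_B=cfg["ci_bootstrap_B"],
        seed=seed,
    )
    rep = morph.detect_transitions(
        traj, swell_margin=cfg["swell_margin"], interior_trim=cfg["interior_trim"]
    )
    return {
        "T_max_shrink_rate": rep.T_max_shrink_rate,
        "T_swell_peak": rep.T_swell_peak,
        "swell_magnitude": rep.swell_magnitude,
        "shrink_onset_lo": rep.shrink_onset_window[0],
        "shrink_onset_hi": rep.shrink_onset_window[1],
    }


def _reconstruct(pair, cfg: dict):
    disp, _ = stereo.compute_disparity(
        pair,
        block_size=cfg["block_size"],
        search_range=cfg["search_range"],
        corr_threshold=cfg["corr_threshold"],
    )
    hmap = stereo.disparity_to_height(disp, pair.tilt_angle, pair.pixel_size)
    return stereo.level_plane(hmap)


def _stereo_arm(sample: dict, root: Path, cfg: dict) -> dict:
    """Roughness from the survey-magnification pair; droplets from the
    dedicated high-magnification pair when present (sub-um droplets are not
    resolvable against cell-scale relief at survey magnification)."""
    pair = pio.read_tilt_pair(
        root / sample["tilt_a"], root / sample["tilt_b"], root / sample["tilt_meta"]
    )
    hmap = _reconstruct(pair, cfg)
    rough = stereo.roughness_params(hmap)
    out = {
        "rq_um": rough.rq,
        "sp_um": rough.sp,
        "sv_um": rough.sv,
        "n_valid_px": rough.n_valid,
    }
    if sample.get("droplet_a"):
        dmap = _reconstruct(
            pio.read_tilt_pair(
                root / sample["droplet_a"],
                root / sample["droplet_b"],
                root / sample["droplet_meta"],
            ),
            cfg,
        )
    else:
        dmap = hmap
    drop = stereo.detect_droplets(
        dmap,
        min_height=cfg["droplet_min_height"],
        diameter_cutoff_nm=cfg["droplet_diameter_cutoff_nm"],
        coverage_cutoff=cfg["droplet_coverage_cutoff"],
        highpass_window_px=cfg["droplet_highpass_window_px"],
    )
    out.update(
        {
            "droplet_count": len(drop.droplets),
            "sub500_count": drop.sub500_count,
            "coverage_class": drop.coverage_class,
        }
    )
    return out


def _raman_arm(sample: dict, root: Path, cfg: dict) -> dict:
    table = raman.default_band_table()
    per_rep = []
    for p in sample["spectra"]:
        s = pio.read_spectrum(root / p)
        s = raman.subtract_baseline(s, lam=cfg["baseline_lam"], p=cfg["baseline_p"])
        s = raman.normalize_mean(s)
        per_rep.append(raman.species_scores(s, table))
    agg = raman.aggregate_replicates(per_rep)
    out: dict = {}
    for sc in agg:
        out[f"score_{sc.species}"] = sc.total_intensity
        out[f"score_{sc.species}_se"] = sc.se
    out["n_replicates"] = len(per_rep)
    return out


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

_ARM_COLUMNS = {
    "morphometry": [
        "T_max_shrink_rate", "T_swell_peak", "swell_magnitude",
        "shrink_onset_lo", "shrink_onset_hi",
    ],
    "stereometry": [
        "rq_um", "sp_um", "sv_um", "n_valid_px",
        "droplet_count", "sub500_count", "coverage_class",
    ],
    "raman": [f"score_{sp}" for sp in raman.SPECIES]
    + [f"score_{sp}_se" for sp in raman.SPECIES]
    + ["n_replicates"],
}


def run_study(manifest: StudyManifest) -> StudyReport:
    """Execute every available arm for every manifest sample.

    Arms are independent: a sample missing inputs for an arm simply gets
    nulls in that arm's columns, and an arm that raises is recorded in the
    failure list without stopping the run.  Ambient-temperature (22 degC)
    Raman scores are calibrated against the reference composition table (when
    given and at least three fractions are available) and the frozen
    calibration is applied to every sample's scores.
    """
    cfg = _merge(DEFAULT_CONFIG, manifest.config)
    rows: list[dict] = []
    failures: list[dict] = []
    for i, sample in enumerate(manifest.samples):
        row: dict = {
            "fraction": sample["fraction"],
            "temperature_C": float(sample["temperature_C"]),
            "replicate": sample.get("replicate", 1),
        }
        for arm_cols in _ARM_COLUMNS.values():
            row.update({c: None for c in arm_cols})
        if sample.get("images"):
            try:
                row.update(
                    _morph_arm(
                        sample, manifest.root, cfg["morphometry"],
                        seed=derive_seed(manifest.seed, "morph", i),
                    )
                )
            except Exception as exc:  # noqa: BLE001 - per-sample isolation
                failures.append({"sample": i, "arm": "morphometry", "error": str(exc)})
        if sample.get("tilt_a"):
            try:
                row.update(_stereo_arm(sample, manifest.root, cfg["stereometry"]))
            except Exception as exc:  # noqa: BLE001
                failures.append({"sample": i, "arm": "stereometry", "error": str(exc)})
        if sample.get("spectra"):
            try:
                row.update(_raman_arm(sample, manifest.root, cfg["raman"]))
            except Exception as exc:  # noqa: BLE001
                failures.append({"sample": i, "arm": "raman", "error": str(exc)})
        rows.append(row)

    schema = ["fraction", "temperature_C", "replicate"] + [
        c for cols in _ARM_COLUMNS.values() for c in cols
    ]
    table = pd.DataFrame(rows, columns=schema)
    for cols in _ARM_COLUMNS.values():
        for c in cols:
            if c != "coverage_class":
                table[c] = pd.to_numeric(table[c], errors="coerce")

    # calibration: ambient scores vs reference composition, applied everywhere
    for sp in raman.SPECIES:
        table[f"est_{sp}"] = np.nan
    if manifest.reference_composition is not None and len(table):
        try:
            reference = pd.read_csv(
                manifest.root / manifest.reference_composition, index_col="fraction"
            )
            ambient = table[
                (table["temperature_C"] == 22.0) & table["score_cellulose"].notna()
            ]
            if len(ambient):
                amb_scores = ambient.groupby("fraction")[
                    [f"score_{sp}" for sp in raman.SPECIES]
                ].mean()
                amb_scores.columns = list(raman.SPECIES)
                model = raman.calibrate(amb_scores, reference)
                for sp in raman.SPECIES:
                    scored = table[f"score_{sp}"].astype(float)
                    table[f"est_{sp}"] = model.slope[sp] * scored + model.intercept[sp]
        except Exception as exc:  # noqa: BLE001
            failures.append({"sample": None, "arm": "calibration", "error": str(exc)})

    provenance = {
        "config_hash": config_hash(cfg),
        "seed": manifest.seed,
        "version": __version__,
    }
    return StudyReport(table=table, failures=failures, provenance=provenance)


def replicate_transition_study(
    preset_name: str,
    seeds: list[int],
    noise_sd: float = 0.02,
    frame_shape: tuple[int, int] = (256, 256),
    basis_dim: int = 20,
    ci_bootstrap_B: int = 200,
    swell_margin: float = 0.01,
) -> list[morph.TransitionReport]:
    """Full morphometry round trip on freshly rendered synthetic series.

    For each seed: generate the preset's area trajectory (default ramp,
    given noise), render it into an image series, segment, track, smooth and
    detect transitions.  Returns one report per replicate.
    """
    import dataclasses

    preset = dataclasses.replace(synthetic.PRESETS[preset_name], noise_sd=noise_sd)
    reports = []
    for s in seeds:
        traj_df = synthetic.generate_area_trajectory(preset, seed=s)
        series = synthetic.render_image_series(
            traj_df, shape_seed=s, frame_shape=frame_shape
        )
        seg = morph.segment_particles(series)
        traj = morph.extract_trajectory(seg, series)
        traj = morph.fit_trajectory_smoother(
            traj, basis_dim=basis_dim, ci_bootstrap_B=ci_bootstrap_B, seed=s
        )
        reports.append(morph.detect_transitions(traj, swell_margin=swell_margin))
    return reports


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

#: Demo roughness targets (um) per fraction and temperature, qualitatively
#: following the study design: needles/cambium roughen by 250 degC,
#: whitewood (and bark mildly) by 375 degC.
_DEMO_RQ: dict[str, dict[float, float]] = {
    "needles": {22.0: 0.3, 250.0: 1.0, 375.0: 1.2},
    "bark": {22.0: 0.4, 250.0: 0.5, 375.0: 0.8},
    "cambium": {22.0: 0.3, 250.0: 1.1, 375.0: 1.3},
    "whitewood": {22.0: 0.3, 250.0: 0.4, 375.0: 1.4},
    "branch": {22.0: 0.3, 250.0: 0.5, 375.0: 1.0},
}


def make_demo_dataset(
    out_dir: Path | str,
    seed: int = 0,
    frame_shape: tuple[int, int] = (128, 128),
    frame_interval_s: float = 60.0,
    surface_shape: tuple[int, int] = (128, 128),
    n_spectrum_replicates: int = 4,
) -> StudyManifest:
    """Write a complete synthetic study (images, tilt pairs, spectra,
    reference table, manifest) under ``out_dir`` and return the manifest.

    Sized to run end-to-end in a few minutes on one CPU; all files are
    derived deterministically from ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = synthetic.REFERENCE_COMPOSITION
    ref.to_csv(out / "reference_composition.csv", float_format="%.10g")

    samples: list[dict] = []
    for fraction in ("needles", "bark", "cambium", "whitewood", "branch"):
        preset = synthetic.PRESETS[fraction]
        traj = synthetic.generate_area_trajectory(
            preset,
            frame_interval_s=frame_interval_s,
            seed=derive_seed(seed, "traj", fraction),
        )
        series = synthetic.render_image_series(
            traj,
            shape_seed=derive_seed(seed, "shape", fraction),
            frame_shape=frame_shape,
        )
        img_dir = Path(fraction) / "images"
        pio.write_image_series(out / img_dir, series)

        for temp in DEFAULT_TEMPERATURES:
            sdir = Path(fraction) / f"T{int(temp)}"
            (out / sdir).mkdir(parents=True, exist_ok=True)
            # survey-magnification surface: cell-scale relief, no droplets
            spec = synthetic.SurfaceSpec(
                grid_shape=surface_shape,
                pixel_size=0.1,
                target_rq=_DEMO_RQ[fraction][temp],
                correlation_length=2.5,
            )
            hmap, truth = synthetic.generate_height_map(
                spec, seed=derive_seed(seed, "surface", fraction, temp)
            )
            pair, _ = synthetic.render_tilt_pair(
                hmap, tilt_angle=15.0,
                seed=derive_seed(seed, "texture", fraction, temp),
            )
            pio.write_tilt_pair(out / sdir, pair)
            pio.write_json(out / sdir / "surface_truth.json", truth)

            # high-magnification field for droplet analysis: nm-scale texture
            # so sub-um droplets stand proud of the background
            n_drop, drop_pix, drop_dia = 0, 0.02, (200.0, 450.0)
            if temp == 375.0:
                if fraction == "cambium":
                    n_drop, drop_pix, drop_dia = 40, 0.04, (380.0, 490.0)
                else:
                    n_drop = 6
            elif temp == 250.0:
                n_drop = 2
            dspec = synthetic.SurfaceSpec(
                grid_shape=surface_shape,
                pixel_size=drop_pix,
                target_rq=0.01,
                correlation_length=0.25,
                n_droplets=n_drop,
                droplet_diameter_range=drop_dia,
            )
            dmap, dtruth = synthetic.generate_height_map(
                dspec, seed=derive_seed(seed, "dropsurface", fraction, temp)
            )
            dpair, _ = synthetic.render_tilt_pair(
                dmap, tilt_angle=15.0,
                seed=derive_seed(seed, "droptexture", fraction, temp),
            )
            pio.write_tilt_pair(out / sdir, dpair, stem="droplet")
            pio.write_json(out / sdir / "droplet_truth.json", dtruth)

            comp = {
                sp: float(ref.loc[fraction, sp])
                * DEGRADATION_FACTORS[temp].get(sp, 1.0)
                for sp in raman.SPECIES
            }
            spectra_paths: list[str] = []
            for rep in range(n_spectrum_replicates):
                sspec = _demo_spectrum_spec(
                    comp, seed=derive_seed(seed, "spectrum", fraction, temp, rep)
                )
                spectrum, _ = synthetic.generate_spectrum(sspec)
                p = sdir / f"spectrum_{rep}.csv"
                pio.write_spectrum(out / p, spectrum)
                spectra_paths.append(str(p))

            entry: dict = {
                "fraction": fraction,
                "temperature_C": float(temp),
                "replicate": 1,
                "tilt_a": str(sdir / "tilt_a.png"),
                "tilt_b": str(sdir / "tilt_b.png"),
                "tilt_meta": str(sdir / "tilt_meta.json"),
                "droplet_a": str(sdir / "droplet_a.png"),
                "droplet_b": str(sdir / "droplet_b.png"),
                "droplet_meta": str(sdir / "droplet_meta.json"),
                "spectra": spectra_paths,
            }
            if temp == 22.0:
                entry["images"] = str(img_dir)
                entry["templog"] = str(img_dir / "templog.csv")
            samples.append(entry)

    manifest = StudyManifest(
        samples=samples,
        seed=seed,
        config={},
        reference_composition="reference_composition.csv",
        root=out,
    )
    manifest.to_yaml(out / "manifest.yaml")
    return manifest


_STUDY_PEAK_SCALE: float | None = None


def _study_peak_scale() -> float:
    """Tallest clean signature-peak intensity of the ambient whitewood
    composition — the study's common intensity scale.

    Detector noise and the fluorescence level are properties of the
    instrument and acquisition, not of the specimen, so every synthetic
    spectrum in a study shares this one scale; per-acquisition gain
    differences are exactly what the mean normalization removes and are
    exercised separately in its own tests.
    """
    global _STUDY_PEAK_SCALE
    if _STUDY_PEAK_SCALE is None:
        comp = {
            sp: float(synthetic.REFERENCE_COMPOSITION.loc["whitewood", sp])
            for sp in raman.SPECIES
        }
        signal, _ = synthetic.generate_spectrum(
            synthetic.SpectrumSpec(composition=comp, noise_sd=0.0)
        )
        _STUDY_PEAK_SCALE = float(signal.intensity.max())
    return _STUDY_PEAK_SCALE


def _demo_spectrum_spec(
    composition: dict[str, float], seed: int, noise_frac: float = 0.05
) -> synthetic.SpectrumSpec:
    """Spectrum spec with the study-wide noise SD (``noise_frac`` of the
    common peak scale) and fluorescence background."""
    peak = _study_peak_scale()
    return synthetic.SpectrumSpec(
        composition=composition,
        background_coeffs=(2.0 * peak, 3.0 * peak, -1.5 * peak),
        noise_sd=noise_frac * peak,
        matrix_strength=1.2 * peak,
        seed=seed,
    )
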