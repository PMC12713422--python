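"""Reading and writing the plain-text/image formats used by the pipeline.

Image series are numbered PNGs plus a temperature-log CSV; height maps and
disparity fields are CSV grids with a JSON sidecar carrying the pixel size;
spectra are two-column CSVs.  All writers are deterministic (no timestamps),
so a regenerated dataset is byte-identical for the same seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .morphometry import ThermalImageSeries
from .raman import RamanSpectrum
from .stereometry import HeightMap, TiltPair

__all__ = [
    "write_image_series",
    "read_image_series",
    "write_tilt_pair",
    "read_tilt_pair",
    "write_height_map",
    "read_height_map",
    "write_spectrum",
    "read_spectrum",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.8g"


def write_json(path: Path | str, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


# -- image series -----------------------------------------------------------

def write_image_series(out_dir: Path | str, series: ThermalImageSeries) -> Path:
    """Write frames as ``frame_0000.png`` ... plus ``templog.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(series.frames):
        iio.imwrite(out / f"frame_{k:04d}.png", np.asarray(frame, dtype=np.uint8))
    pd.DataFrame(
        {
            "frame": np.arange(len(series)),
            "time_s": series.time_s,
            "temperature_C": series.temperature_C,
        }
    ).to_csv(out / "templog.csv", index=False, float_format=_FLOAT_FMT)
    return out


def read_image_series(images_dir: Path | str, templog: Path | str | None = None) -> ThermalImageSeries:
    images_dir = Path(images_dir)
    templog = Path(templog) if templog else images_dir / "templog.csv"
    log = pd.read_csv(templog)
    frames = [
        np.asarray(iio.imread(images_dir / f"frame_{int(k):04d}.png"))
        for k in log["frame"]
    ]
    return ThermalImageSeries(
        frames=frames,
        time_s=log["time_s"].to_numpy(dtype=float),
        temperature_C=log["temperature_C"].to_numpy(dtype=float),
    )


# -- tilt pairs and height maps ---------------------------------------------

def write_tilt_pair(out_dir: Path | str, pair: TiltPair, stem: str = "tilt") -> Path:
    """Write the two views as 8-bit PNGs plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo = min(pair.image_a.min(), pair.image_b.min())
    hi = max(pair.image_a.max(), pair.image_b.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    for name, img in (("a", pair.image_a), ("b", pair.image_b)):
        u8 = np.clip((img - lo) * scale, 0, 255).astype(np.uint8)
        iio.imwrite(out / f"{stem}_{name}.png", u8)
    write_json(
        out / f"{stem}_meta.json",
        {
            "tilt_angle": pair.tilt_angle,
            "tilt_axis": pair.tilt_axis,
            "pixel_size": pair.pixel_size,
        },
    )
    return out


def read_tilt_pair(
    path_a: Path | str, path_b: Path | str, meta: Path | str | dict
) -> TiltPair:
    m = meta if isinstance(meta, dict) else read_json(meta)
    return TiltPair(
        image_a=np.asarray(iio.imread(path_a), dtype=float),
        image_b=np.asarray(iio.imread(path_b), dtype=float),
        tilt_angle=float(m["tilt_angle"]),
        tilt_axis=m.get("tilt_axis", "rows"),
        pixel_size=float(m["pixel_size"]),
    )


def write_height_map(path: Path | str, hmap: HeightMap) -> None:
    """CSV grid of heights plus a ``<path>.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, hmap.z, delimiter=",", fmt=_FLOAT_FMT)
    write_json(
        path.with_suffix(path.suffix + ".json"),
        {"pixel_size": hmap.pixel_size, "levelled": bool(hmap.levelled)},
    )


def read_height_map(path: Path | str) -> HeightMap:
    path = Path(path)
    meta = read_json(path.with_suffix(path.suffix + ".json"))
    z = np.loadtxt(path, delimiter=",")
    return HeightMap(z=z, pixel_size=float(meta["pixel_size"]), levelled=bool(meta["levelled"]))


# -- spectra ----------------------------------------------------------------

def write_spectrum(path: Path | str, spec: RamanSpectrum) -> None:
    pd.DataFrame(
        {"wavenumber_cm-1": spec.wavenumber, "intensity": spec.intensity}
    ).to_csv(path, index=False, float_format="%.10g")


def read_spectrum(path: Path | str, meta: dict | None = None) -> RamanSpectrum:
    df = pd.read_csv(path, sep=None, engine="python")
    return RamanSpectrum(
        wavenumber=df.iloc[:, 0].to_numpy(dtype=float),
        intensity=df.iloc[:, 1].to_numpy(dtype=float),
        meta=meta or {},
        state="raw",
    )
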