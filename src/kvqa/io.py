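"""File formats: 48-bit TIFF film scans, grayscale projections, CSV schemas.

CSV schemas
-----------
Chamber series (one file per series; header row, no index):

* linearity:       ``time_s, charge_nC``
* inverse_square:  ``offset_mm, dose_gy``
* constancy:       ``date, dose_rate_gy_min``  (ISO 8601 dates)
* transmission:    ``thickness_mm_cu, transmission``

Flexmaps: ``angle_deg, u_mm, v_mm``.  Projection manifests:
``filename, angle_deg, offset_x_mm, offset_y_mm, offset_z_mm, focal_spot``.

Dose grids interchange as a values CSV next to a JSON header holding
``pixel_pitch_mm`` (and ``voxel_spacing_mm`` for 3-D grids stored as
stacked planes).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .core import CHAMBER_CSV_COLUMNS, ChamberReadingSeries, DoseMap, FilmScan, FlexMap

__all__ = [
    "write_film_tiff",
    "read_film_tiff",
    "write_gray_tiff",
    "read_gray_tiff",
    "write_chamber_csv",
    "read_chamber_csv",
    "write_flexmap_csv",
    "read_flexmap_csv",
    "write_dose_map",
    "read_dose_map",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def write_film_tiff(path: PathLike, scan: FilmScan) -> None:
    """Write an RGB film scan as 16-bit-per-channel TIFF with dpi metadata."""
    tifffile.imwrite(
        str(path),
        scan.pixels,
        photometric="rgb",
        resolution=(scan.dpi, scan.dpi),
        resolutionunit="INCH",
    )


def read_film_tiff(path: PathLike) -> FilmScan:
    """Read a film scan, recovering pixel values bit-exactly plus the dpi."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        dpi = 75.0
        if "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if den:
                dpi = num / den
    return FilmScan(pixels, dpi=dpi)


def write_gray_tiff(path: PathLike, image: np.ndarray) -> None:
    """Write a grayscale projection image as 16-bit TIFF."""
    data = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 0xFFFF).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_gray_tiff(path: PathLike) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


# ---------------------------------------------------------------------------
# chamber CSV
# ---------------------------------------------------------------------------

def write_chamber_csv(path: PathLike, series: ChamberReadingSeries) -> None:
    xcol, ycol = CHAMBER_CSV_COLUMNS[series.kind]
    if series.kind == "constancy":
        x = np.datetime_as_string(series.x, unit="D")
    else:
        x = series.x
    pd.DataFrame({xcol: x, ycol: series.y}).to_csv(path, index=False)


def read_chamber_csv(path: PathLike, kind: str) -> ChamberReadingSeries:
    if kind not in CHAMBER_CSV_COLUMNS:
        raise ValueError(f"unknown series kind {kind!r}")
    xcol, ycol = CHAMBER_CSV_COLUMNS[kind]
    df = pd.read_csv(path)
    missing = {xcol, ycol} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)} for kind {kind!r}")
    if kind == "constancy":
        try:
            x = pd.to_datetime(df[xcol], format="ISO8601").to_numpy().astype("datetime64[D]")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: unparseable dates in column {xcol!r}: {exc}") from exc
    else:
        x = df[xcol].to_numpy(dtype=float)
    return ChamberReadingSeries(kind, x, df[ycol].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# flexmap CSV
# ---------------------------------------------------------------------------

def write_flexmap_csv(path: PathLike, flexmap: FlexMap) -> None:
    pd.DataFrame(
        {"angle_deg": flexmap.angles, "u_mm": flexmap.u, "v_mm": flexmap.v}
    ).to_csv(path, index=False)


def read_flexmap_csv(
    path: PathLike, focal_spot: str = "large", magnification: float | None = None
) -> FlexMap:
    df = pd.read_csv(path)
    for col in ("angle_deg", "u_mm", "v_mm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing flexmap column {col!r}")
    return FlexMap(
        df["angle_deg"].to_numpy(float),
        df["u_mm"].to_numpy(float),
        df["v_mm"].to_numpy(float),
        focal_spot=focal_spot,
        magnification=magnification,
    )


# ---------------------------------------------------------------------------
# dose maps as CSV + JSON header
# ---------------------------------------------------------------------------

def write_dose_map(path_csv: PathLike, dose_map: DoseMap) -> None:
    """Write grid values as CSV with a ``.json`` sidecar giving the pitch."""
    path_csv = Path(path_csv)
    np.savetxt(path_csv, dose_map.values, delimiter=",")
    header = {"pixel_pitch_mm": dose_map.pixel_pitch, "shape": list(dose_map.shape)}
    path_csv.with_suffix(".json").write_text(json.dumps(header))


def read_dose_map(path_csv: PathLike) -> DoseMap:
    path_csv = Path(path_csv)
    header = json.loads(path_csv.with_suffix(".json").read_text())
    values = np.loadtxt(path_csv, delimiter=",")
    return DoseMap(values, header["pixel_pitch_mm"])
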