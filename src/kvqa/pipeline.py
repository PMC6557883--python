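"""Commissioning pipeline: fixture bundles, batch analyses, report tables.

A fixture bundle is a self-describing directory of film TIFFs, chamber
CSVs, projection TIFFs and a ``truth.json`` ground-truth sidecar, laid
out so every stage of the pipeline can run on it end-to-end:

.. code-block:: text

    bundle/
      truth.json
      calibration/doses.csv + cal_*.tif
      collimators/manifest.csv + <name>/depth_*.tif
      chamber/{linearity_*,inverse_square,constancy,transmission}.csv
      geometry/{flex,wl}/manifest.csv + proj_*.tif
      geometry/mag/manifest.csv + shot_*.tif
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import chamber as chamber_mod
from . import film as film_mod
from . import geometry as geometry_mod
from . import io as io_mod
from . import metrics as metrics_mod
from .core import DoseMap, FilmScan
from .synthetic import (
    BeamGroundTruth,
    FilmResponseModel,
    GeometryGroundTruth,
    generate_bb_projections,
    generate_chamber_series,
    generate_depth_series,
    generate_dose_map,
    generate_film_scan,
)

__all__ = [
    "CommissioningConfig",
    "make_fixtures",
    "load_projection_set",
    "run_relative_dosimetry",
    "run_constancy_report",
    "run_magnification",
    "run_flexmap",
    "run_winston_lutz",
    "SCENARIOS",
]

PathLike = Union[str, Path]

#: collimator sets per named scenario: (name, shape, size mm, edge sigma mm,
#: relative output) — the paper-like set is the full clinical-style bundle.
SCENARIOS: dict[str, list[tuple[str, str, float, float, float]]] = {
    "paper-like": [
        ("circ2.5", "circular", 2.5, 0.25, 0.30),
        ("circ5", "circular", 5.0, 0.30, 0.55),
        ("circ10", "circular", 10.0, 0.35, 0.75),
        ("circ25", "circular", 25.0, 0.40, 0.93),
        ("sq10x10", "square", 10.0, 0.35, 0.80),
        ("sq40x40", "square", 40.0, 0.45, 1.00),
    ],
    "minimal": [
        ("circ5", "circular", 5.0, 0.30, 0.55),
        ("sq40x40", "square", 40.0, 0.45, 1.00),
    ],
}

_CAL_DOSES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
_DEPTHS_CM = (0.0, 0.5, 1.5, 2.5, 3.5, 4.5, 5.5)
_REFERENCE_DOSE = 7.2  # Gy delivered to the reference field in 120 s


@dataclass
class CommissioningConfig:
    """Paths and conventions for a commissioning run.

    ``denominator`` selects the percent-difference convention
    ('local' = film denominator, 'reference' = published-mean
    denominator); ``rounding`` the printed decimal places.
    """

    bundle: Path
    output: Path
    reference_table: Optional[Path] = None
    denominator: str = "local"
    rounding: int = 1
    roi_mm: float = 5.0
    n_average: int = 5
    monotone_tol: float = 0.05
    filter_window: int = 5
    constancy_baseline: Optional[float] = None
    seed: int = 0
    tolerances: dict = dc_field(default_factory=lambda: {"single_pct": 3.0, "consecutive_pct": 2.0})

    def __post_init__(self) -> None:
        self.bundle = Path(self.bundle)
        self.output = Path(self.output)
        if self.reference_table is not None:
            self.reference_table = Path(self.reference_table)

    @classmethod
    def from_file(cls, path: PathLike) -> "CommissioningConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def make_fixtures(
    root: PathLike,
    seed: int = 0,
    scenario: str = "paper-like",
    film_noise_sd: float = 120.0,
    reference_ssd: float = 302.0,
    end_effect: float = 0.116,
    baseline_rate: float = 3.61,
    flex_u_amp: float = 1.2,
    flex_v_amp: float = 0.6,
    iso_wobble_amp: float = 1.0,
    n_flex_angles: int = 36,
) -> Path:
    """Write a complete synthetic commissioning bundle to ``root``.

    Deterministic for a fixed seed: the same (seed, scenario) always
    produces byte-identical files.  Returns the bundle path.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
        )
    root = Path(root)
    rng_seed = np.random.SeedSequence(seed).spawn(8)
    sub_seed = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seed]

    model = FilmResponseModel(noise_sd=film_noise_sd)
    truth: dict = {
        "scenario": scenario,
        "seed": seed,
        "film_response": {"a": model.a, "b": model.b, "c": model.c, "noise_sd": film_noise_sd},
        "collimators": {},
    }

    # --- calibration films -------------------------------------------------
    cal_dir = root / "calibration"
    cal_dir.mkdir(parents=True, exist_ok=True)
    cal_truth = BeamGroundTruth(shape="square", nominal_size=40.0, edge_sigma=0.45, dose_cax=1.0)
    rows = []
    for i, dose in enumerate(_CAL_DOSES):
        if dose > 0:
            dmap = generate_dose_map(cal_truth, 45.0, 25.4 / 75.0).scaled(dose)
        else:
            dmap = DoseMap(np.zeros_like(generate_dose_map(cal_truth, 45.0, 25.4 / 75.0).values), 25.4 / 75.0)
        for rep in range(3):
            scan = generate_film_scan(dmap, model, seed=sub_seed[0] + 100 * i + rep)
            name = f"cal_d{i}_r{rep}.tif"
            io_mod.write_film_tiff(cal_dir / name, scan)
            rows.append({"dose_gy": dose, "filename": name})
    pd.DataFrame(rows).to_csv(cal_dir / "doses.csv", index=False)
    truth["calibration_doses"] = list(_CAL_DOSES)

    # --- per-collimator depth stacks ---------------------------------------
    col_dir = root / "collimators"
    col_dir.mkdir(exist_ok=True)
    manifest = []
    for j, (name, shape, size, sigma, rof) in enumerate(SCENARIOS[scenario]):
        bt = BeamGroundTruth(
            shape=shape,
            nominal_size=size,
            edge_sigma=sigma,
            dose_cax=_REFERENCE_DOSE * rof,
            flatness_dome=0.02,
            tilt=0.002,
            mu_eff=0.28,
            scatter_growth=0.01 + 0.0005 * size,
        )
        truth["collimators"][name] = {
            "shape": shape,
            "nominal_size_mm": size,
            "edge_sigma_mm": sigma,
            "dose_cax_gy": bt.dose_cax,
            "rof": rof,
            "flatness_dome": bt.flatness_dome,
            "tilt_per_mm": bt.tilt,
            "mu_eff_per_cm": bt.mu_eff,
            "scatter_growth_per_cm": bt.scatter_growth,
        }
        (col_dir / name).mkdir(exist_ok=True)
        maps = generate_depth_series(bt, _DEPTHS_CM)
        for d, dmap in zip(_DEPTHS_CM, maps):
            scan = generate_film_scan(dmap, model, seed=sub_seed[1] + 1000 * j + int(10 * d))
            fname = f"depth_{d:.1f}cm.tif"
            io_mod.write_film_tiff(col_dir / name / fname, scan)
            manifest.append(
                {
                    "collimator": name,
                    "depth_cm": d,
                    "filename": f"{name}/{fname}",
                    "is_reference": name == SCENARIOS[scenario][-1][0],
                }
            )
    pd.DataFrame(manifest).to_csv(col_dir / "manifest.csv", index=False)

    # --- chamber series -----------------------------------------------------
    ch_dir = root / "chamber"
    ch_dir.mkdir(exist_ok=True)
    for current in (13.0, 6.0, 1.0, 0.1):
        series = generate_chamber_series(
            "linearity",
            {
                "times": [1.0, 2.0, 5.0, 10.0, 30.0, 60.0],
                "current_mA": current,
                "charge_rate": 1.2,
                "end_effect": end_effect,
                "noise_sd": 0.02 * current,
            },
            seed=sub_seed[2] + int(current * 10),
        )
        io_mod.write_chamber_csv(ch_dir / f"linearity_{current:g}mA.csv", series)
    io_mod.write_chamber_csv(
        ch_dir / "inverse_square.csv",
        generate_chamber_series(
            "inverse_square",
            {"offsets": [-50.0, -30.0, 0.0, 30.0, 50.0], "d0": 3.61, "ssd_eff": reference_ssd,
             "noise_sd": 0.003},
            seed=sub_seed[3],
        ),
    )
    io_mod.write_chamber_csv(
        ch_dir / "constancy.csv",
        generate_chamber_series(
            "constancy",
            {"start_date": "2024-01-15", "n_sessions": 10, "interval_days": 56,
             "baseline": baseline_rate, "drift_per_year": -0.01, "noise_sd": 0.008},
            seed=sub_seed[4],
        ),
    )
    io_mod.write_chamber_csv(
        ch_dir / "transmission.csv",
        generate_chamber_series(
            "transmission",
            {"thicknesses": list(np.arange(0.0, 3.6, 0.25)), "mu0": 0.70, "hardening": 0.12},
            seed=sub_seed[5],
        ),
    )
    truth["chamber"] = {
        "end_effect_s": end_effect,
        "ssd_eff_mm": reference_ssd,
        "baseline_gy_min": baseline_rate,
    }

    # --- geometry -----------------------------------------------------------
    geom = GeometryGroundTruth(
        flex_u_amp=flex_u_amp,
        flex_v_amp=flex_v_amp,
        flex_u_phase=0.4,
        flex_v_phase=1.1,
        iso_wobble_amp=0.0,
    )
    geo_dir = root / "geometry"
    angles = np.arange(n_flex_angles) * (360.0 / n_flex_angles)
    flex_set = generate_bb_projections(
        geom, angles, [(0.0, 0.0, 0.0)], seed=sub_seed[6], noise_sd=8.0
    )
    _write_projection_set(geo_dir / "flex", flex_set, "large")

    wl_geom = GeometryGroundTruth(
        flex_u_amp=flex_u_amp,
        flex_v_amp=flex_v_amp,
        flex_u_phase=0.4,
        flex_v_phase=1.1,
        iso_wobble_amp=iso_wobble_amp,
    )
    wl_set = generate_bb_projections(
        wl_geom, angles, [(0.0, 0.0, 0.0)], seed=sub_seed[7],
        aperture_radius_mm=6.0, noise_sd=8.0,
    )
    _write_projection_set(geo_dir / "wl", wl_set, "large")

    mag_dir = geo_dir / "mag"
    mag_dir.mkdir(parents=True, exist_ok=True)
    mag_geom = GeometryGroundTruth()
    shifts = (-5.0, -3.0, 3.0, 5.0)
    axial = 50.0
    mag_rows = []
    shots = []
    for kind, z in (("iso", 0.0), ("axial", axial)):
        for s in shifts:
            shots.append((0.0, (s, 0.0, z)))
            mag_rows.append({"kind": kind, "shift_mm": s, "z_mm": z,
                             "filename": f"shot_{kind}_{s:+g}.tif"})
    mag_set = generate_bb_projections(
        mag_geom, [a for a, _ in shots], [o for _, o in shots],
        seed=sub_seed[6] + 1, noise_sd=8.0,
    )
    for row, img in zip(mag_rows, mag_set.images):
        io_mod.write_gray_tiff(mag_dir / row["filename"], img)
    pd.DataFrame(mag_rows).to_csv(mag_dir / "manifest.csv", index=False)

    truth["geometry"] = {
        "sad_mm": geom.sad,
        "sdd_mm": geom.sdd,
        "magnification": geom.magnification,
        "flex_u_amp_mm": flex_u_amp,
        "flex_v_amp_mm": flex_v_amp,
        "iso_wobble_amp_mm": iso_wobble_amp,
        "panel_pixel_pitch_mm": geom.panel_pixel_pitch,
        "axial_shift_mm": axial,
    }
    (root / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return root


def _write_projection_set(directory: Path, proj_set, focal_spot: str) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, angle, off) in enumerate(
        zip(proj_set.images, proj_set.angles, proj_set.stage_offsets)
    ):
        fname = f"proj_{i:03d}.tif"
        io_mod.write_gray_tiff(directory / fname, img)
        rows.append(
            {
                "filename": fname,
                "angle_deg": angle,
                "offset_x_mm": off[0],
                "offset_y_mm": off[1],
                "offset_z_mm": off[2],
                "focal_spot": focal_spot,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def load_projection_set(directory: PathLike, panel_pixel_pitch: float = 0.2):
    """Read a projection directory (manifest.csv + TIFFs) back into memory."""
    from .core import BBProjectionSet

    directory = Path(directory)
    df = pd.read_csv(directory / "manifest.csv")
    images = [io_mod.read_gray_tiff(directory / f) for f in df["filename"]]
    offsets = df[["offset_x_mm", "offset_y_mm", "offset_z_mm"]].to_numpy(float)
    return BBProjectionSet(images, df["angle_deg"].to_numpy(float), offsets, panel_pixel_pitch)


# ---------------------------------------------------------------------------
# batch analyses
# ---------------------------------------------------------------------------

def _fit_bundle_calibration(config: CommissioningConfig):
    cal_dir = config.bundle / "calibration"
    doses_csv = cal_dir / "doses.csv"
    if not doses_csv.exists():
        raise FileNotFoundError(f"missing calibration set: {doses_csv}")
    df = pd.read_csv(doses_csv)
    doses, scan_groups = [], []
    for dose, group in df.groupby("dose_gy"):
        doses.append(float(dose))
        scan_groups.append([io_mod.read_film_tiff(cal_dir / f) for f in group["filename"]])
    return film_mod.fit_calibration(doses, scan_groups, roi_mm=config.roi_mm)


def _film_to_map(scan: FilmScan, curve, config: CommissioningConfig) -> DoseMap:
    with warnings.catch_warnings():
        # low-dose films legitimately have noise pixels above the
        # zero-dose intensity; clamping them to zero dose is expected
        warnings.simplefilter("ignore", film_mod.OutOfRangeWarning)
        dose = film_mod.apply_calibration(scan, curve)
    return film_mod.adaptive_filter(dose, window=config.filter_window)


def run_relative_dosimetry(config: CommissioningConfig) -> dict[str, pd.DataFrame]:
    """Full film-based relative dosimetry on a bundle.

    Fits the calibration curve, converts every collimator's depth stack
    to dose, and produces three tables (also written as CSV under
    ``config.output``): per-collimator profile metrics at 5 mm depth,
    relative output factors against the reference collimator, and PDD
    per collimator.  If ``config.reference_table`` points to a CSV with
    columns ``collimator, fwhm_mm`` a percent-difference column is
    added under the configured denominator convention.
    """
    curve = _fit_bundle_calibration(config)
    manifest_csv = config.bundle / "collimators" / "manifest.csv"
    if not manifest_csv.exists():
        raise FileNotFoundError(f"missing collimator manifest: {manifest_csv}")
    manifest = pd.read_csv(manifest_csv)
    config.output.mkdir(parents=True, exist_ok=True)

    metric_rows, rof_rows, pdd_rows = [], [], []
    ref_roi = None
    per_col_roi: dict[str, float] = {}
    for name, group in manifest.groupby("collimator", sort=False):
        depth_maps = []
        for _, row in group.sort_values("depth_cm").iterrows():
            scan = io_mod.read_film_tiff(config.bundle / "collimators" / row["filename"])
            depth_maps.append((float(row["depth_cm"]), _film_to_map(scan, curve, config)))

        by_depth = dict(depth_maps)
        map_5mm = by_depth.get(0.5, depth_maps[0][1])
        row_out: dict = {"collimator": name}
        fwhms = []
        for ax in ("crossplane", "inplane"):
            try:
                prof = metrics_mod.extract_profile(map_5mm, ax, config.n_average)
                m = metrics_mod.profile_metrics(prof, monotone_tol=config.monotone_tol)
                for key, val in m.as_dict().items():
                    row_out[f"{ax}_{key}"] = val
                fwhms.append(m.fwhm)
            except ValueError as exc:
                warnings.warn(f"{name}/{ax}: {exc}")
        metric_rows.append(row_out)

        # keep the ROI inside small fields: at most 40 % of the FWHM
        roi_mm = config.roi_mm
        if fwhms:
            roi_mm = min(roi_mm, 0.4 * float(np.mean(fwhms)))

        pdd = metrics_mod.compute_pdd(depth_maps, roi_mm=roi_mm)
        for d, dose, p in zip(pdd.depths, pdd.roi_doses, pdd.pdd):
            pdd_rows.append({"collimator": name, "depth_cm": d, "roi_dose_gy": dose, "pdd_pct": p})

        roi = map_5mm.central_roi_mean(roi_mm)
        per_col_roi[str(name)] = roi
        if bool(group["is_reference"].iloc[0]):
            ref_roi = roi
    if ref_roi is None:
        raise ValueError("no reference collimator flagged in the manifest")
    for name, roi in per_col_roi.items():
        rof_rows.append({"collimator": name, "rof": metrics_mod.compute_rof(roi, ref_roi)})

    tables = {
        "metrics": pd.DataFrame(metric_rows),
        "rof": pd.DataFrame(rof_rows),
        "pdd": pd.DataFrame(pdd_rows),
    }

    if config.reference_table is not None:
        ref = pd.read_csv(config.reference_table)
        merged = tables["metrics"].merge(ref, on="collimator", how="left", suffixes=("", "_ref"))
        diffs = []
        for _, row in merged.iterrows():
            local = 0.5 * (row.get("crossplane_fwhm_mm", np.nan) + row.get("inplane_fwhm_mm", np.nan))
            if np.isfinite(local) and np.isfinite(row.get("fwhm_mm", np.nan)):
                d = metrics_mod.percent_difference(local, row["fwhm_mm"], config.denominator)
                diffs.append(metrics_mod.round_half_up(d, config.rounding))
            else:
                diffs.append(np.nan)
        tables["metrics"]["fwhm_diff_pct"] = diffs

    for key, df in tables.items():
        df.to_csv(config.output / f"{key}.csv", index=False)
    return tables


def run_magnification(config: CommissioningConfig) -> tuple[float, float, float]:
    """SAD/SDD/magnification from the bundle's magnification shots."""
    mag_dir = config.bundle / "geometry" / "mag"
    df = pd.read_csv(mag_dir / "manifest.csv")
    truth = json.loads((config.bundle / "truth.json").read_text())
    pitch = truth["geometry"]["panel_pixel_pitch_mm"]
    shots: dict[str, list[tuple[float, float]]] = {"iso": [], "axial": []}
    for _, row in df.iterrows():
        img = io_mod.read_gray_tiff(mag_dir / row["filename"])
        u, _ = geometry_mod.detect_bb_centroid(img)
        shots[row["kind"]].append((float(row["shift_mm"]), u))
    axial_z = float(df.loc[df["kind"] == "axial", "z_mm"].iloc[0])
    return geometry_mod.compute_magnification(shots["iso"], shots["axial"], axial_z, pitch)


def run_flexmap(config: CommissioningConfig, magnification: Optional[float] = None):
    """Build and save the panel flexmap from the bundle's rotation set."""
    truth = json.loads((config.bundle / "truth.json").read_text())
    pitch = truth["geometry"]["panel_pixel_pitch_mm"]
    mag = magnification or truth["geometry"]["magnification"]
    proj = load_projection_set(config.bundle / "geometry" / "flex", pitch)
    flexmap = geometry_mod.build_flexmap(proj, magnification=mag)
    config.output.mkdir(parents=True, exist_ok=True)
    io_mod.write_flexmap_csv(config.output / "flexmap.csv", flexmap)
    return flexmap


def run_winston_lutz(config: CommissioningConfig, flexmap=None):
    """Winston–Lutz displacements (and self-correction residual) for a bundle."""
    truth = json.loads((config.bundle / "truth.json").read_text())
    pitch = truth["geometry"]["panel_pixel_pitch_mm"]
    mag = truth["geometry"]["magnification"]
    proj = load_projection_set(config.bundle / "geometry" / "wl", pitch)
    result = geometry_mod.winston_lutz(proj, mag, flexmap=flexmap)
    corrected = geometry_mod.winston_lutz(
        proj, mag, flexmap=flexmap, correction=list(zip(result.u, result.v))
    )
    config.output.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"angle_deg": result.angles, "u_mm": result.u, "v_mm": result.v}
    ).to_csv(config.output / "winston_lutz.csv", index=False)
    result.residual_u = corrected.residual_u
    result.residual_v = corrected.residual_v
    result.residual_max = corrected.residual_max
    return result


def run_constancy_report(config: CommissioningConfig) -> tuple[pd.DataFrame, str]:
    """Output-constancy deviations, tolerance flags and a ±1 % error band.

    Baseline defaults to the first reading when not set in the config.
    Returns the per-date table (also written to CSV) and the overall
    status string.
    """
    path = config.bundle / "chamber" / "constancy.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing constancy series: {path}")
    series = io_mod.read_chamber_csv(path, "constancy")
    baseline = config.constancy_baseline or float(series.y[0])
    status = chamber_mod.check_constancy(series, baseline)
    df = pd.DataFrame(
        {
            "date": np.datetime_as_string(series.x, unit="D"),
            "dose_rate_gy_min": series.y,
            "deviation_pct": status.deviations_pct,
            "flag": status.flags,
            "band_low_gy_min": series.y * 0.99,
            "band_high_gy_min": series.y * 1.01,
        }
    )
    config.output.mkdir(parents=True, exist_ok=True)
    df.to_csv(config.output / "constancy.csv", index=False)
    return df, status.overall
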