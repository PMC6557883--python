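"""Relative-dosimetry metrics from 2-D dose maps.

Profiles are taken through the map centre as the average of an odd
number of adjacent lines and normalised to the central-axis (CAX) dose,
estimated as the mean over a central square ROI whose side is 20 % of
the FWHM (minimum 3x3 pixels).  From the normalised profile:

* field size = full width at half maximum (50 % crossings, linearly
  interpolated);
* penumbra = 80 %-to-20 % distance at each edge;
* symmetry = max |D(+x) - D(-x)| x 100 % over mirrored pairs within the
  central 80 % of the field width;
* flatness = 100 (Dmax - Dmin) / (Dmax + Dmin) over the same region.

The "central 80 % of the field" is the interval spanning 80 % of the
FWHM centred midway between the 50 % crossings.  All shape metrics are
invariant under multiplication of the dose map by a positive constant.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator

from .core import DepthDoseSeries, DoseMap, DoseProfile, ProfileMetrics

__all__ = [
    "extract_profile",
    "compute_fwhm",
    "compute_penumbra",
    "compute_symmetry",
    "compute_flatness",
    "profile_metrics",
    "compute_pdd",
    "compute_rof",
    "effective_offset",
    "percent_difference",
    "round_half_up",
    "compare_dose_grids",
    "GridComparison",
]


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------

def extract_profile(
    dose_map: DoseMap,
    axis: str = "crossplane",
    n_average: int = 5,
    depth: float = 0.0,
) -> DoseProfile:
    """Average ``n_average`` central lines and normalise to the CAX dose.

    ``crossplane`` runs along x (averaging adjacent rows); ``inplane``
    along y (averaging adjacent columns).  ``n_average`` must be odd so
    the centre line is unambiguous.
    """
    if n_average % 2 == 0:
        raise ValueError("n_average must be odd (centre line would be ambiguous)")
    vals = dose_map.values
    k = n_average // 2
    if axis == "crossplane":
        r0 = (vals.shape[0] - 1) // 2
        if r0 - k < 0 or r0 + k >= vals.shape[0]:
            raise ValueError("map too narrow for the requested line average")
        raw = vals[r0 - k : r0 + k + 1, :].mean(axis=0)
        positions = dose_map.positions(1)
    elif axis == "inplane":
        c0 = (vals.shape[1] - 1) // 2
        if c0 - k < 0 or c0 + k >= vals.shape[1]:
            raise ValueError("map too narrow for the requested line average")
        raw = vals[:, c0 - k : c0 + k + 1].mean(axis=1)
        positions = dose_map.positions(0)
    else:
        raise ValueError("axis must be 'crossplane' or 'inplane'")

    centre_val = raw[(len(raw) - 1) // 2]
    if centre_val <= 0:
        raise ValueError("non-positive dose at the profile centre")
    cax = centre_val
    try:
        fwhm0 = compute_fwhm(DoseProfile(positions, raw / centre_val, axis, depth))
        roi_mm = max(0.2 * fwhm0, 3.0 * dose_map.pixel_pitch)
        cax = dose_map.central_roi_mean(roi_mm)
    except ValueError:
        pass  # fall back to the centre-sample estimate
    return DoseProfile(positions, raw / cax, axis, depth)


# ---------------------------------------------------------------------------
# crossings
# ---------------------------------------------------------------------------

def _level_crossings(positions: np.ndarray, values: np.ndarray, level: float) -> np.ndarray:
    """Positions where the profile crosses ``level``, linearly interpolated.

    Samples exactly at the level (plateaus) resolve to the outermost
    bracketing sample of the plateau: the low-position end for a rising
    edge, the high-position end for a falling edge.
    """
    d = np.asarray(values, dtype=float) - level
    xs: list[float] = []
    for i in range(len(d) - 1):
        a, b = d[i], d[i + 1]
        if a != 0.0 and b != 0.0 and a * b < 0:
            t = a / (a - b)
            xs.append(float(positions[i] + t * (positions[i + 1] - positions[i])))
    zero_idx = np.flatnonzero(d == 0.0)
    if zero_idx.size:
        runs = np.split(zero_idx, np.where(np.diff(zero_idx) > 1)[0] + 1)
        for run in runs:
            lo, hi = int(run[0]), int(run[-1])
            left = d[lo - 1] if lo > 0 else 0.0
            right = d[hi + 1] if hi < len(d) - 1 else 0.0
            if left < 0 < right:  # rising edge
                xs.append(float(positions[lo]))
            elif left > 0 > right:  # falling edge
                xs.append(float(positions[hi]))
            # tangent plateaus (same sign both sides) are not crossings
    return np.sort(np.asarray(xs))


def compute_fwhm(profile: DoseProfile) -> float:
    """Field size: distance between the two 50 % crossings (mm)."""
    xs = _level_crossings(profile.positions, profile.values, 0.5)
    if len(xs) != 2:
        raise ValueError(
            f"expected exactly two 50% crossings, found {len(xs)}; "
            "profile is not a single well-formed field"
        )
    return float(xs[1] - xs[0])


def _edge_crossing(
    profile: DoseProfile,
    level: float,
    edge: str,
    centre: float,
) -> tuple[float, int]:
    """The ``level`` crossing on one edge, nearest the field centre side."""
    pos, val = profile.positions, profile.values
    if edge == "left":
        mask = pos <= centre
    else:
        mask = pos >= centre
    xs = _level_crossings(pos[mask], val[mask], level)
    if len(xs) == 0:
        raise ValueError(f"no {100 * level:g}% crossing on the {edge} edge")
    x = xs[-1] if edge == "left" else xs[0]
    idx = int(np.searchsorted(pos, x))
    return float(x), idx


def compute_penumbra(
    profile: DoseProfile,
    monotone_tol: float = 0.0,
) -> tuple[float, float]:
    """80-20 % penumbral widths (left, right) in mm.

    The profile must cross 0.2 and 0.8 exactly once per edge and be
    monotone across the 20-80 % window; decrements larger than
    ``monotone_tol`` (in CAX-normalised units) reject the edge.
    """
    xs50 = _level_crossings(profile.positions, profile.values, 0.5)
    if len(xs50) != 2:
        raise ValueError("penumbra needs a profile with exactly two 50% crossings")
    centre = 0.5 * (xs50[0] + xs50[1])
    widths = []
    for edge in ("left", "right"):
        x80, i80 = _edge_crossing(profile, 0.8, edge, centre)
        x20, i20 = _edge_crossing(profile, 0.2, edge, centre)
        lo_i, hi_i = sorted((i20, i80))
        seg = profile.values[max(lo_i - 1, 0) : hi_i + 1]
        step = np.diff(seg) if edge == "left" else -np.diff(seg)
        if np.any(step < -monotone_tol):
            raise ValueError(f"non-monotone {edge} edge within the 20-80% window")
        widths.append(abs(x80 - x20))
    return (widths[0], widths[1])


# ---------------------------------------------------------------------------
# uniformity metrics over the central 80 % of the field
# ---------------------------------------------------------------------------

def _central_region(profile: DoseProfile) -> tuple[float, float]:
    """(centre, half-width) of the central-80 %-of-FWHM interval."""
    xs = _level_crossings(profile.positions, profile.values, 0.5)
    if len(xs) != 2:
        raise ValueError("central region needs exactly two 50% crossings")
    centre = 0.5 * (xs[0] + xs[1])
    half = 0.4 * (xs[1] - xs[0])
    return centre, half


def compute_symmetry(profile: DoseProfile) -> float:
    """Max |D(+x) - D(-x)| x 100 over mirrored pairs in the central 80 %.

    Off-grid mirror points are evaluated with a shape-preserving
    (monotone cubic) interpolant, which stays faithful on the steep
    penumbral samples near the region boundary.
    """
    centre, half = _central_region(profile)
    pos = profile.positions
    in_region = pos[(pos > centre) & (pos <= centre + half)]
    offsets = set(np.round(in_region - centre, 9))
    left_region = pos[(pos >= centre - half) & (pos < centre)]
    offsets.update(np.round(centre - left_region, 9))
    offsets.add(round(half, 9))
    offsets.discard(0.0)
    if not offsets:
        return 0.0
    off = np.asarray(sorted(offsets))
    interp = PchipInterpolator(pos, profile.values)
    d_plus = interp(centre + off)
    d_minus = interp(centre - off)
    return float(np.max(np.abs(d_plus - d_minus)) * 100.0)


def compute_flatness(profile: DoseProfile) -> float:
    """100 (Dmax - Dmin) / (Dmax + Dmin) over the central 80 % region.

    Grid samples inside the region are used directly; the exact region
    endpoints are evaluated with a shape-preserving interpolant.
    """
    centre, half = _central_region(profile)
    pos = profile.positions
    mask = (pos >= centre - half) & (pos <= centre + half)
    samples = list(profile.values[mask])
    interp = PchipInterpolator(pos, profile.values)
    samples.append(float(interp(centre - half)))
    samples.append(float(interp(centre + half)))
    d_max, d_min = max(samples), min(samples)
    if d_max + d_min == 0:
        raise ValueError("degenerate profile: Dmax + Dmin = 0")
    return float(100.0 * (d_max - d_min) / (d_max + d_min))


def profile_metrics(profile: DoseProfile, monotone_tol: float = 0.0) -> ProfileMetrics:
    """All shape metrics of one profile in a single pass."""
    pen_l, pen_r = compute_penumbra(profile, monotone_tol=monotone_tol)
    return ProfileMetrics(
        fwhm=compute_fwhm(profile),
        penumbra_left=pen_l,
        penumbra_right=pen_r,
        symmetry=compute_symmetry(profile),
        flatness=compute_flatness(profile),
    )


# ---------------------------------------------------------------------------
# depth dose, output factors, comparisons
# ---------------------------------------------------------------------------

def compute_pdd(
    depth_maps: Sequence[tuple[float, DoseMap]],
    roi_mm: float = 5.0,
) -> DepthDoseSeries:
    """Percentage depth dose from central-ROI means, referenced to depth 0."""
    depths = np.asarray([d for d, _ in depth_maps], dtype=float)
    rois = np.asarray([m.central_roi_mean(roi_mm) for _, m in depth_maps])
    ref_idx = np.flatnonzero(depths == 0.0)
    if ref_idx.size == 0:
        raise ValueError("PDD requires a measurement at the reference depth 0")
    ref = rois[ref_idx[0]]
    return DepthDoseSeries(depths, rois, 100.0 * rois / ref)


def compute_rof(d_col: float, d_ref: float) -> float:
    """Relative output factor: dose for a collimator over the reference dose."""
    if d_ref <= 0:
        raise ValueError("reference dose must be positive")
    return float(d_col) / float(d_ref)


def effective_offset(
    metric_pairs: Sequence[Optional[tuple[Optional[ProfileMetrics], Optional[ProfileMetrics]]]],
) -> list[Optional[tuple[float, float]]]:
    """Per-collimator effective source offset indicator.

    Each entry is an (inplane, crossplane) metrics pair; the offset is
    (right - left) penumbra in the crossplane as dx and in the inplane
    as dy.  A systematic grouping of the points in one quadrant flags a
    source offset.  Entries with a missing axis are skipped (``None``)
    with a warning.
    """
    out: list[Optional[tuple[float, float]]] = []
    for i, pair in enumerate(metric_pairs):
        if pair is None or pair[0] is None or pair[1] is None:
            warnings.warn(f"collimator {i}: missing axis, entry skipped")
            out.append(None)
            continue
        inplane, crossplane = pair
        out.append(
            (
                crossplane.penumbra_right - crossplane.penumbra_left,
                inplane.penumbra_right - inplane.penumbra_left,
            )
        )
    return out


def percent_difference(
    local: float,
    reference: float,
    denominator: str = "reference",
) -> float:
    """100 |local - reference| / denominator-value.

    ``denominator='reference'`` follows the multi-institution-mean
    convention; ``'local'`` the film-denominator convention.  Rounding
    to printed precision is the caller's concern (:func:`round_half_up`).
    """
    denom = {"reference": reference, "local": local}.get(denominator)
    if denom is None:
        raise ValueError("denominator must be 'reference' or 'local'")
    if denom == 0:
        raise ValueError("zero denominator in percent difference")
    return abs(local - reference) / abs(denom) * 100.0


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding to the printed precision of report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# film vs external (planning-system) dose grid
# ---------------------------------------------------------------------------

@dataclass
class GridComparison:
    """Side-by-side film vs external-grid metrics at one depth."""

    film: dict[str, ProfileMetrics]  # per axis
    external: dict[str, ProfileMetrics]
    diff_pct: dict[str, dict[str, float]]  # per axis, per metric (film denominator)
    roi_film: float
    roi_external: float
    roi_ratio: float


def _plane_at_depth(grid: np.ndarray, dz_mm: float, depth_cm: float) -> np.ndarray:
    z = np.arange(grid.shape[0]) * dz_mm
    depth_mm = 10.0 * depth_cm
    if depth_mm < z[0] - 1e-9 or depth_mm > z[-1] + 1e-9:
        raise ValueError(f"depth {depth_cm:g} cm outside the external grid")
    k = int(np.clip(np.searchsorted(z, depth_mm) - 1, 0, grid.shape[0] - 2))
    t = (depth_mm - z[k]) / (z[k + 1] - z[k]) if grid.shape[0] > 1 else 0.0
    t = float(np.clip(t, 0.0, 1.0))
    return (1.0 - t) * grid[k] + t * grid[k + 1]


def compare_dose_grids(
    film: DoseMap,
    external: np.ndarray,
    voxel_spacing: tuple[float, float, float],
    depth: float,
    roi_mm: float = 5.0,
    n_average: int = 5,
    monotone_tol: float = 0.0,
) -> GridComparison:
    """Compare a film dose map with an externally computed 3-D dose grid.

    ``external`` is (nz, ny, nx) with ``voxel_spacing`` (dz, dy, dx) in
    mm, the first plane at depth 0 and the beam axis at the grid centre.
    The plane at ``depth`` (cm) is extracted by linear interpolation
    along z, resampled to the film pixel pitch, and both maps are run
    through the same metric operations.  Percent differences use the
    film value as denominator.
    """
    dz, dy, dx = voxel_spacing
    plane = _plane_at_depth(np.asarray(external, dtype=float), dz, depth)
    ny, nx = plane.shape
    ys = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xs = (np.arange(nx) - (nx - 1) / 2.0) * dx
    interp = RegularGridInterpolator((ys, xs), plane, bounds_error=False, fill_value=0.0)

    pitch = film.pixel_pitch
    half_y, half_x = ys[-1], xs[-1]
    my = int(np.floor(half_y / pitch))
    mx = int(np.floor(half_x / pitch))
    gy = np.arange(-my, my + 1) * pitch
    gx = np.arange(-mx, mx + 1) * pitch
    yy, xx = np.meshgrid(gy, gx, indexing="ij")
    ext_map = DoseMap(interp(np.stack([yy, xx], axis=-1)), pitch)

    film_metrics, ext_metrics, diffs = {}, {}, {}
    for ax in ("crossplane", "inplane"):
        fm = profile_metrics(extract_profile(film, ax, n_average), monotone_tol)
        em = profile_metrics(extract_profile(ext_map, ax, n_average), monotone_tol)
        film_metrics[ax], ext_metrics[ax] = fm, em
        diffs[ax] = {
            key: percent_difference(f_val, e_val, denominator="local")
            for (key, f_val), e_val in zip(fm.as_dict().items(), em.as_dict().values())
            if f_val != 0
        }
    roi_f = film.central_roi_mean(roi_mm)
    roi_e = ext_map.central_roi_mean(roi_mm)
    return GridComparison(
        film=film_metrics,
        external=ext_metrics,
        diff_pct=diffs,
        roi_film=roi_f,
        roi_external=roi_e,
        roi_ratio=roi_f / roi_e if roi_e else float("nan"),
    )
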