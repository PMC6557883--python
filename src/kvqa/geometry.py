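"""Image-based geometric QA: BB detection, magnification, flexmaps, Winston–Lutz.

Coordinate convention: image origin top-left; u increases rightward
(gantry-lateral, i.e. orthogonal to the rotation axis), v downward
(along the rotation axis).  Gantry 0 degrees puts the source at the top
of rotation, angles increasing clockwise.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import BBProjectionSet, FlexMap, WLResult

__all__ = [
    "detect_bb_centroid",
    "compute_magnification",
    "build_flexmap",
    "winston_lutz",
    "fit_sinusoid",
]

_MIN_BLOB_PX = 5  # single-pixel noise specks are not candidate BBs


def _robust_threshold(image: np.ndarray) -> float:
    # The dark disc can occupy well under 1 % of the panel, so the low
    # percentile must be tight enough to land inside it.
    lo, hi = np.percentile(image, [0.05, 99.5])
    return float(0.5 * (lo + hi))


def detect_bb_centroid(
    image: np.ndarray,
    expected_radius: Optional[float] = None,
) -> tuple[float, float]:
    """Sub-pixel centroid (u, v) of a single dark disc on a bright background.

    The below-threshold region (threshold = midpoint of the robust 1st
    and 99th intensity percentiles) is segmented; exactly one blob of at
    least a few pixels must remain, otherwise the image is rejected with
    the blob count.  The centroid is weighted by darkness (threshold
    minus intensity) for sub-pixel precision.
    """
    img = np.asarray(image, dtype=float)
    thresh = _robust_threshold(img)
    mask = img < thresh
    labels, n = ndimage.label(mask)
    if n > 0:
        sizes = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= _MIN_BLOB_PX) + 1
    else:
        keep = np.array([], dtype=int)
    if len(keep) != 1:
        raise ValueError(f"expected exactly one BB candidate blob, found {len(keep)}")
    blob = labels == keep[0]
    weights = np.where(blob, thresh - img, 0.0)
    weights = np.clip(weights, 0.0, None)
    total = weights.sum()
    rows, cols = np.indices(img.shape)
    v = float((weights * rows).sum() / total)
    u = float((weights * cols).sum() / total)
    if expected_radius is not None:
        area = blob.sum()
        r_est = np.sqrt(area / np.pi)
        if not (0.5 * expected_radius <= r_est <= 2.0 * expected_radius):
            raise ValueError(
                f"BB radius estimate {r_est:.1f} px far from expected {expected_radius:.1f} px"
            )
    return u, v


def _slope(shifts: np.ndarray, displacements: np.ndarray) -> float:
    """Least-squares slope of panel displacement vs stage shift."""
    if len(np.unique(shifts)) < 2:
        raise ValueError("degenerate shifts: at least two distinct values required")
    x = shifts - shifts.mean()
    y = displacements - displacements.mean()
    return float(np.sum(x * y) / np.sum(x * x))


def compute_magnification(
    shots_iso: Sequence[tuple[float, float]],
    shots_axial: Sequence[tuple[float, float]],
    axial_shift: float,
    panel_pixel_pitch: float,
) -> tuple[float, float, float]:
    """SAD, SDD and magnification from BB shots at known stage shifts.

    Parameters
    ----------
    shots_iso : sequence of (lateral shift mm, centroid u px)
        Lateral stage shifts with the BB at the isocentre plane.
    shots_axial : sequence of (lateral shift mm, centroid u px)
        The same lateral shifts with the BB moved ``axial_shift`` mm
        toward the source.
    axial_shift : float
        Stage displacement toward the source (mm, non-zero).
    panel_pixel_pitch : float
        mm per panel pixel.

    With a point source, lateral displacements magnify by
    ``m(z) = SDD / (SAD - z)``; the two slopes m(0) and m(z) separate
    SAD from SDD:  SAD = m(z) z / (m(z) - m(0)),  SDD = m(0) SAD.

    Returns (sad_mm, sdd_mm, magnification) with magnification = SDD/SAD.
    """
    if axial_shift == 0:
        raise ValueError("axial_shift must be non-zero to separate SAD from SDD")
    iso = np.asarray(shots_iso, dtype=float)
    axial = np.asarray(shots_axial, dtype=float)
    m0 = _slope(iso[:, 0], iso[:, 1] * panel_pixel_pitch)
    mz = _slope(axial[:, 0], axial[:, 1] * panel_pixel_pitch)
    if mz <= m0:
        raise ValueError(
            "magnification did not increase toward the source; "
            "check the sign of axial_shift"
        )
    sad = mz * axial_shift / (mz - m0)
    sdd = m0 * sad
    return float(sad), float(sdd), float(m0)


def build_flexmap(
    projections: BBProjectionSet,
    focal_spot: str = "large",
    magnification: Optional[float] = None,
    max_gap_deg: float = 30.0,
) -> FlexMap:
    """Panel flexmap from a full rotation with the BB held fixed.

    Per-angle (u, v) displacement of the BB centroid from the reference
    centroid (the arithmetic mean over all angles), converted to mm at
    panel scale.  Gaps larger than ``max_gap_deg`` in the angular
    sampling trigger a warning; readers interpolate linearly in angle.
    """
    if not np.allclose(projections.stage_offsets, projections.stage_offsets[0]):
        raise ValueError("flexmap acquisition requires a stationary BB")
    angles = projections.angles
    order = np.argsort(angles)
    sorted_angles = angles[order]
    gaps = np.diff(np.concatenate([sorted_angles, [sorted_angles[0] + 360.0]]))
    if np.any(gaps > max_gap_deg):
        import warnings

        warnings.warn(
            f"angular gaps up to {gaps.max():.0f} deg; flexmap will be interpolated"
        )
    centroids = np.array([detect_bb_centroid(img) for img in projections.images])
    ref = centroids.mean(axis=0)
    pitch = projections.panel_pixel_pitch
    u = (centroids[:, 0] - ref[0]) * pitch
    v = (centroids[:, 1] - ref[1]) * pitch
    return FlexMap(angles, u, v, focal_spot=focal_spot, magnification=magnification)


def _wl_centroids(image: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    """(BB centroid, field centroid) in px for a Winston–Lutz image.

    The collimated field is the above-half-maximum region (holes filled
    so the BB shadow does not bias its centroid); the BB is the dark
    region inside it.
    """
    img = np.asarray(image, dtype=float)
    half = _robust_threshold(img)
    field = img > half
    filled = ndimage.binary_fill_holes(field)
    if not filled.any():
        raise ValueError("field aperture not detectable (no above-half-maximum region)")
    labels, n = ndimage.label(filled)
    sizes = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
    filled = labels == (int(np.argmax(sizes)) + 1)
    rows, cols = np.indices(img.shape)
    field_v = float(rows[filled].mean())
    field_u = float(cols[filled].mean())

    bb_mask = filled & (img < half)
    if bb_mask.sum() < _MIN_BLOB_PX:
        raise ValueError("BB shadow not detectable inside the field aperture")
    weights = np.where(bb_mask, half - img, 0.0).clip(0.0, None)
    total = weights.sum()
    bb_v = float((weights * rows).sum() / total)
    bb_u = float((weights * cols).sum() / total)
    return (bb_u, bb_v), (field_u, field_v)


def winston_lutz(
    projections: BBProjectionSet,
    magnification: float,
    flexmap: Optional[FlexMap] = None,
    correction: Optional[Sequence[tuple[float, float]]] = None,
) -> WLResult:
    """Winston–Lutz analysis of BB-in-collimated-field projections.

    Per angle, the displacement of the BB centroid from the field
    centroid is converted to mm at isocentre scale (pitch divided by
    magnification).  When a ``flexmap`` is supplied its panel-scale
    (u, v) at each angle is subtracted before scaling.  When a
    ``correction`` pattern (per-angle (u, v) in isocentre mm, e.g. a
    previous result's displacements used as stage tracking) is supplied,
    the residual after subtracting it is reported as well.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    pitch = projections.panel_pixel_pitch
    us, vs = [], []
    for img in projections.images:
        (bb_u, bb_v), (f_u, f_v) = _wl_centroids(img)
        us.append((bb_u - f_u) * pitch)
        vs.append((bb_v - f_v) * pitch)
    u_panel = np.asarray(us)
    v_panel = np.asarray(vs)
    if flexmap is not None:
        flex = np.array([flexmap.at(a) for a in projections.angles])
        u_panel = u_panel - flex[:, 0]
        v_panel = v_panel - flex[:, 1]
    u_iso = u_panel / magnification
    v_iso = v_panel / magnification
    max_mag = float(np.max(np.hypot(u_iso, v_iso)))

    res_u = res_v = None
    res_max = None
    if correction is not None:
        corr = np.asarray(correction, dtype=float)
        if corr.shape != (len(u_iso), 2):
            raise ValueError("correction must provide one (u, v) pair per angle")
        res_u = u_iso - corr[:, 0]
        res_v = v_iso - corr[:, 1]
        res_max = (float(np.max(np.abs(res_u))), float(np.max(np.abs(res_v))))
    return WLResult(
        angles=projections.angles,
        u=u_iso,
        v=v_iso,
        max_magnitude=max_mag,
        residual_u=res_u,
        residual_v=res_v,
        residual_max=res_max,
    )


def fit_sinusoid(angles_deg: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of ``offset + amp * sin(theta + phase)``.

    Returns (amplitude, phase_rad, offset); used to summarise flexmaps
    and wobble patterns.
    """
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    design = np.column_stack([np.sin(th), np.cos(th), np.ones_like(th)])
    coef, *_ = np.linalg.lstsq(design, np.asarray(values, dtype=float), rcond=None)
    b, c, offset = coef
    amp = float(np.hypot(b, c))
    phase = float(np.arctan2(c, b))
    return amp, phase, float(offset)
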