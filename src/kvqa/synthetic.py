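"""Synthetic measurement generators with known ground truth.

Every downstream analysis stage in this package has a generator here that
emulates the corresponding physical measurement — film irradiations,
ion-chamber reading series, ball-bearing (BB) projection images — from
explicit ground-truth parameters.  Composing a noiseless generator with
the matching analysis operation must recover the ground truth; that
parameter-recovery contract is what the test suite exercises throughout.

Models
------
* Dose fields have Gaussian-integral (error-function) edges: for circular
  collimators the edge applies to the radial distance, for square
  collimators separably per axis.  A quadratic "dome" term and a linear
  tilt modulate the flat top.
* Film response is the saturating rational form
  ``intensity = a + b / (dose - c)`` with ``c < 0``, strictly decreasing
  in dose — standard radiochromic behaviour.
* Depth series follow ``exp(-mu_eff d) (1 + scatter_growth d)`` times an
  optional inverse-square factor.
* Chamber series: linear charge accumulation with an end-effect,
  inverse-square falloff about an effective source position, slow linear
  output drift, and exponential transmission with optional beam
  hardening.
* BB projections: a dark disc on a bright panel whose centre carries the
  magnified stage offset, sinusoidal panel flex, and isocentre wobble.

All randomness is driven by explicit integer seeds; no global state.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr  # standard normal CDF

from .core import (
    BBProjectionSet,
    ChamberReadingSeries,
    DoseMap,
    FilmScan,
)

__all__ = [
    "BeamGroundTruth",
    "FilmResponseModel",
    "GeometryGroundTruth",
    "generate_dose_map",
    "generate_film_scan",
    "generate_depth_series",
    "generate_chamber_series",
    "generate_bb_projections",
]


# ---------------------------------------------------------------------------
# ground-truth parameter bundles
# ---------------------------------------------------------------------------

@dataclass
class BeamGroundTruth:
    """Parameters of one collimated beam at the isocentre plane.

    ``nominal_size`` is the FWHM (diameter for circular fields, side for
    square ones), ``edge_sigma`` the Gaussian-integral edge parameter,
    ``flatness_dome`` a quadratic droop (>0) / horn (<0) coefficient over
    the central region, and ``tilt`` a fractional dose gradient per mm.
    ``mu_eff`` (1/cm) and ``scatter_growth`` (1/cm) shape depth series.
    """

    shape: str = "circular"  # or "square"
    nominal_size: float = 10.0  # mm (FWHM at the isocentre plane)
    edge_sigma: float = 0.4  # mm
    dose_cax: float = 2.0  # Gy
    flatness_dome: float = 0.0
    tilt: float = 0.0  # fraction / mm
    mu_eff: float = 0.3  # 1/cm
    scatter_growth: float = 0.0  # 1/cm

    def __post_init__(self) -> None:
        if self.shape not in ("circular", "square"):
            raise ValueError("shape must be 'circular' or 'square'")
        if self.nominal_size <= 0:
            raise ValueError("nominal_size must be positive")
        if self.edge_sigma <= 0:
            raise ValueError("edge_sigma must be positive")
        if self.dose_cax <= 0:
            raise ValueError("dose_cax must be positive")


@dataclass
class FilmResponseModel:
    """Saturating film response ``intensity = a + b/(dose - c)``, c < 0.

    Defaults put zero dose near 54 000 counts and 10 Gy near 15 500 on
    the 16-bit scale, strictly decreasing in between.  Green and blue
    channels use weaker variants of the same form so multi-channel scans
    look plausible; only the red channel is used for calibration.
    """

    a: float = 4000.0
    b: float = 150000.0
    c: float = -3.0
    noise_sd: float = 0.0  # intensity counts
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.c >= 0:
            raise ValueError("c must be negative for a pole-free response")
        if self.b <= 0:
            raise ValueError("b must be positive (decreasing response)")
        if self.bit_depth != 16:
            raise ValueError("only 16 bits per channel is supported")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def response(self, dose: np.ndarray | float) -> np.ndarray | float:
        return self.a + self.b / (np.asarray(dose, dtype=float) - self.c)

    def inverse(self, intensity: np.ndarray | float) -> np.ndarray | float:
        return self.c + self.b / (np.asarray(intensity, dtype=float) - self.a)

    def channel_response(self, dose: np.ndarray, channel: str) -> np.ndarray:
        """Per-channel response; green/blue are weaker, distinct variants."""
        if channel == "red":
            return self.response(dose)
        if channel == "green":
            return self.a + 0.55 * self.b * 2.0 / (np.asarray(dose) - 2.0 * self.c)
        if channel == "blue":
            return self.a + 0.30 * self.b * 3.0 / (np.asarray(dose) - 3.0 * self.c)
        raise ValueError(f"unknown channel {channel!r}")


@dataclass
class GeometryGroundTruth:
    """Imaging-chain geometry plus panel flex and isocentre wobble.

    Distances in mm; flex phases in radians.  Defaults reflect a
    source-to-axis distance of 306.4 mm, source-to-detector distance of
    625 mm (magnification ≈ 2.04) and a 0.2 mm panel pixel, i.e. about
    0.1 mm resolution at isocentre.
    """

    sad: float = 306.4
    sdd: float = 625.0
    flex_u_amp: float = 0.0
    flex_u_phase: float = 0.0
    flex_u_offset: float = 0.0
    flex_v_amp: float = 0.0
    flex_v_phase: float = 0.0
    flex_v_offset: float = 0.0
    iso_wobble_amp: float = 0.0  # mm at isocentre scale, lateral (u)
    panel_pixel_pitch: float = 0.2  # mm

    def __post_init__(self) -> None:
        if not (self.sdd > self.sad > 0):
            raise ValueError("require sdd > sad > 0")
        if self.panel_pixel_pitch <= 0:
            raise ValueError("panel_pixel_pitch must be positive")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    def flex_u(self, angle_deg: np.ndarray | float) -> np.ndarray | float:
        th = np.deg2rad(angle_deg)
        return self.flex_u_offset + self.flex_u_amp * np.sin(th + self.flex_u_phase)

    def flex_v(self, angle_deg: np.ndarray | float) -> np.ndarray | float:
        th = np.deg2rad(angle_deg)
        return self.flex_v_offset + self.flex_v_amp * np.sin(th + self.flex_v_phase)

    def wobble_u(self, angle_deg: np.ndarray | float) -> np.ndarray | float:
        return self.iso_wobble_amp * np.sin(np.deg2rad(angle_deg))


# ---------------------------------------------------------------------------
# dose maps & film scans
# ---------------------------------------------------------------------------

def _edge_profile_circular(r: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    return ndtr((radius - r) / sigma)


def _edge_profile_slab(t: np.ndarray, half: float, sigma: float) -> np.ndarray:
    # rect of half-width `half` convolved with a Gaussian of width sigma
    return ndtr((half - t) / sigma) + ndtr((half + t) / sigma) - 1.0


def generate_dose_map(
    truth: BeamGroundTruth,
    grid_extent: float,
    pixel_pitch: float,
    seed: Optional[int] = None,
    noise_sd: float = 0.0,
) -> DoseMap:
    """Render the ground-truth beam onto a square grid.

    Parameters
    ----------
    grid_extent : float
        Physical side of the (square) grid in mm.  Must cover the field
        plus its penumbra, ``nominal_size + 6 * edge_sigma``.
    pixel_pitch : float
        mm per pixel; 25.4/75 emulates a 75 dpi film scan.
    noise_sd : float
        Optional additive Gaussian dose noise (Gy), seeded by ``seed``.
    """
    required = truth.nominal_size + 6.0 * truth.edge_sigma
    if grid_extent < required:
        raise ValueError(
            f"grid_extent {grid_extent:g} mm too small to contain the field; "
            f"need at least nominal_size + 6*edge_sigma = {required:g} mm"
        )
    n = int(round(grid_extent / pixel_pitch))
    if n % 2 == 0:
        n += 1  # odd grid keeps a pixel centre on the beam axis
    coords = (np.arange(n) - (n - 1) / 2.0) * pixel_pitch
    x, y = np.meshgrid(coords, coords)

    half = truth.nominal_size / 2.0
    if truth.shape == "circular":
        r = np.hypot(x, y)
        base = _edge_profile_circular(r, half, truth.edge_sigma)
        centre_val = float(ndtr(half / truth.edge_sigma))
    else:
        base = _edge_profile_slab(x, half, truth.edge_sigma) * _edge_profile_slab(
            y, half, truth.edge_sigma
        )
        centre_val = float(_edge_profile_slab(np.zeros(1), half, truth.edge_sigma)[0]) ** 2
    base = base / centre_val  # exact dose_cax at the field centre

    rho2 = (x**2 + y**2) / half**2
    modulation = (1.0 - truth.flatness_dome * rho2) * (1.0 + truth.tilt * x)
    dose = truth.dose_cax * base * modulation
    if dose.min() < 0:
        raise ValueError("tilt/dome too strong: dose would go negative in the grid")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dose = dose + rng.normal(0.0, noise_sd, size=dose.shape)
        dose = np.clip(dose, 0.0, None)
    return DoseMap(dose, pixel_pitch)


def generate_film_scan(
    dose: DoseMap,
    model: FilmResponseModel,
    seed: int = 0,
    dpi: float = 75.0,
) -> FilmScan:
    """Expose a virtual film to ``dose`` and scan it as 48-bit RGB.

    The red channel carries the primary response plus Gaussian noise of
    ``model.noise_sd`` counts; green and blue carry distinct weaker
    responses.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    channels = []
    for name in ("red", "green", "blue"):
        intensity = model.channel_response(dose.values, name)
        if model.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, model.noise_sd, dose.values.shape)
        channels.append(intensity)
    pixels = np.clip(np.rint(np.stack(channels, axis=-1)), 0, model.max_value)
    return FilmScan(pixels.astype(np.uint16), dpi=dpi)


def generate_depth_series(
    truth: BeamGroundTruth,
    depths: Sequence[float],
    ssd: Optional[float] = None,
) -> list[DoseMap]:
    """Dose maps at increasing solid-water depths.

    Central dose at depth ``d`` (cm) is
    ``dose_cax * exp(-mu_eff d) * (1 + scatter_growth d)`` times the
    inverse-square factor ``(ssd / (ssd + 10 d))**2`` when an ``ssd``
    (mm) is given.
    """
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be sorted increasing")
    extent = truth.nominal_size + 8.0 * truth.edge_sigma + 4.0
    pitch = 25.4 / 75.0
    base = generate_dose_map(truth, extent, pitch)
    maps = []
    for d in depths:
        factor = np.exp(-truth.mu_eff * d) * (1.0 + truth.scatter_growth * d)
        if ssd is not None:
            factor *= (ssd / (ssd + 10.0 * d)) ** 2
        maps.append(base.scaled(float(factor)))
    return maps


# ---------------------------------------------------------------------------
# chamber reading series
# ---------------------------------------------------------------------------

def _require(params: dict, keys: Sequence[str], kind: str) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise ValueError(f"{kind} series is missing parameter(s): {', '.join(missing)}")


def generate_chamber_series(
    kind: str,
    params: dict,
    seed: int = 0,
) -> ChamberReadingSeries:
    """Generate an ion-chamber reading series of the requested kind.

    Required ``params`` per kind:

    ``linearity``
        ``times`` (s), ``current_mA``, ``charge_rate`` (nC/s/mA),
        ``end_effect`` (s); optional ``noise_sd`` (nC).
    ``inverse_square``
        ``offsets`` (mm, sorted), ``d0`` (Gy), ``ssd_eff`` (mm);
        optional ``noise_sd`` (Gy).
    ``constancy``
        ``start_date`` (ISO), ``n_sessions``, ``interval_days``,
        ``baseline`` (Gy/min), ``drift_per_year`` (fractional);
        optional ``noise_sd`` (Gy/min).
    ``transmission``
        ``thicknesses`` (mm Cu, sorted), ``mu0`` (1/mm); optional
        ``hardening`` (1/mm, >= 0) and ``noise_sd``.

    Transmission follows ``T(x) = exp(-mu0 x / (1 + hardening x))`` so a
    positive hardening coefficient makes the effective attenuation
    decrease with thickness (second half-value layer thicker than the
    first).
    """
    rng = np.random.default_rng(seed)
    noise_sd = float(params.get("noise_sd", 0.0))

    if kind == "linearity":
        _require(params, ("times", "current_mA", "charge_rate", "end_effect"), kind)
        t = np.asarray(params["times"], dtype=float)
        charge = params["charge_rate"] * params["current_mA"] * (t + params["end_effect"])
        y = charge + (rng.normal(0.0, noise_sd, t.shape) if noise_sd else 0.0)
        meta = {"current_mA": params["current_mA"]}
        return ChamberReadingSeries("linearity", t, y, meta)

    if kind == "inverse_square":
        _require(params, ("offsets", "d0", "ssd_eff"), kind)
        delta = np.asarray(params["offsets"], dtype=float)
        dose = params["d0"] * (params["ssd_eff"] / (params["ssd_eff"] + delta)) ** 2
        y = dose + (rng.normal(0.0, noise_sd, delta.shape) if noise_sd else 0.0)
        return ChamberReadingSeries("inverse_square", delta, y, {})

    if kind == "constancy":
        _require(
            params,
            ("start_date", "n_sessions", "interval_days", "baseline", "drift_per_year"),
            kind,
        )
        n = int(params["n_sessions"])
        dates = np.datetime64(params["start_date"]) + np.arange(n) * np.timedelta64(
            int(params["interval_days"]), "D"
        )
        elapsed_years = np.arange(n) * params["interval_days"] / 365.25
        rate = params["baseline"] * (1.0 + params["drift_per_year"] * elapsed_years)
        y = rate + (rng.normal(0.0, noise_sd, rate.shape) if noise_sd else 0.0)
        return ChamberReadingSeries("constancy", dates, y, {"baseline": params["baseline"]})

    if kind == "transmission":
        _require(params, ("thicknesses", "mu0"), kind)
        xt = np.asarray(params["thicknesses"], dtype=float)
        h = float(params.get("hardening", 0.0))
        trans = np.exp(-params["mu0"] * xt / (1.0 + h * xt))
        y = trans + (rng.normal(0.0, noise_sd, xt.shape) if noise_sd else 0.0)
        return ChamberReadingSeries("transmission", xt, y, {"mu0": params["mu0"], "hardening": h})

    raise ValueError(f"unknown series kind {kind!r}")


# ---------------------------------------------------------------------------
# BB projection images
# ---------------------------------------------------------------------------

def _soft_disc(
    shape: tuple[int, int],
    centre: tuple[float, float],  # (col, row), px
    radius_px: float,
    edge_px: float = 1.0,
) -> np.ndarray:
    """Occupancy map of a disc with a smooth (error-function) edge."""
    rows, cols = np.indices(shape)
    d = np.hypot(cols - centre[0], rows - centre[1])
    return ndtr((radius_px - d) / edge_px)


def project_bb_centre(
    geom: GeometryGroundTruth,
    angle_deg: float,
    offset: Sequence[float],
) -> tuple[float, float]:
    """Panel-plane (u, v) displacement in mm of the BB projection.

    Room coordinates: the rotation axis is y (the v direction); at
    gantry 0° the source sits at +z (top) and the lateral u axis is x.
    The source rotates clockwise in the x–z plane.  The BB picks up a
    depth-dependent magnification when offset toward/away from the
    source, plus panel flex and isocentre wobble.
    """
    ox, oy, oz = (float(c) for c in offset)
    th = np.deg2rad(angle_deg)
    u_iso = ox * np.cos(th) - oz * np.sin(th)
    w = ox * np.sin(th) + oz * np.cos(th)  # toward the source
    if w >= geom.sad:
        raise ValueError("stage offset places the BB at or behind the source")
    m = geom.sdd / (geom.sad - w)
    u_mm = m * u_iso + float(geom.flex_u(angle_deg))
    v_mm = m * oy + float(geom.flex_v(angle_deg))
    return (u_mm, v_mm)


def generate_bb_projections(
    geom: GeometryGroundTruth,
    angles: Sequence[float],
    stage_offsets: Sequence[Sequence[float]],
    seed: int = 0,
    panel_shape: tuple[int, int] = (150, 200),
    bb_radius_px: float = 6.0,
    aperture_radius_mm: Optional[float] = None,
    noise_sd: float = 10.0,
) -> BBProjectionSet:
    """Project a BB at each (angle, stage offset) pair onto the panel.

    Each image is one dark disc on a bright background.  When
    ``aperture_radius_mm`` is given a bright collimated-field disc (the
    Winston–Lutz aperture) is rendered, the outside left dark, and the
    BB shadow cast inside it.  Model split: the BB projection carries
    the panel-flex term (an image-registration drift the flexmap
    calibration corrects); the aperture projection carries the
    magnified isocentre-wobble term (motion of the collimation axis
    relative to the fixed BB with gantry angle).
    """
    angles = np.asarray(angles, dtype=float)
    offsets = np.atleast_2d(np.asarray(stage_offsets, dtype=float))
    if offsets.shape[0] == 1 and len(angles) > 1:
        offsets = np.repeat(offsets, len(angles), axis=0)
    if np.any((angles < 0) | (angles >= 360)):
        raise ValueError("angles must lie in [0, 360)")
    rng = np.random.default_rng(seed)
    rows, cols = panel_shape
    centre_col = (cols - 1) / 2.0
    centre_row = (rows - 1) / 2.0
    pitch = geom.panel_pixel_pitch

    bright, dark_bb, dark_bg = 3000.0, 300.0, 200.0
    images = []
    for angle, off in zip(angles, offsets):
        u_mm, v_mm = project_bb_centre(geom, angle, off)
        bb_centre = (centre_col + u_mm / pitch, centre_row + v_mm / pitch)
        if aperture_radius_mm is None:
            img = np.full(panel_shape, bright)
        else:
            m_iso = geom.magnification
            ap_u = m_iso * float(geom.wobble_u(angle))
            ap_centre = (centre_col + ap_u / pitch, centre_row)
            ap = _soft_disc(panel_shape, ap_centre, aperture_radius_mm / pitch)
            img = dark_bg + (bright - dark_bg) * ap
        img = img - (bright - dark_bb) * _soft_disc(panel_shape, bb_centre, bb_radius_px)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        images.append(np.clip(img, 0.0, 65535.0))
    return BBProjectionSet(images, angles, offsets, pitch)
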