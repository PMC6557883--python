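"""Shared data containers for commissioning analyses.

The common currency of the film / treatment-planning comparison is the
:class:`DoseMap` — a 2-D grid of dose values with a physical pixel pitch,
centred on the beam-axis estimate.  Chamber measurements travel as
:class:`ChamberReadingSeries`, geometric QA results as :class:`FlexMap`
and :class:`WLResult`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DoseMap",
    "DoseProfile",
    "ProfileMetrics",
    "DepthDoseSeries",
    "FilmScan",
    "CalibrationCurve",
    "ChamberReadingSeries",
    "ConstancyStatus",
    "FlexMap",
    "BBProjectionSet",
    "WLResult",
    "MM_PER_INCH",
]

MM_PER_INCH = 25.4

CHAMBER_KINDS = ("linearity", "inverse_square", "constancy", "transmission")

#: CSV column headers per chamber-series kind (x column, y column).
CHAMBER_CSV_COLUMNS = {
    "linearity": ("time_s", "charge_nC"),
    "inverse_square": ("offset_mm", "dose_gy"),
    "constancy": ("date", "dose_rate_gy_min"),
    "transmission": ("thickness_mm_cu", "transmission"),
}


@dataclass
class DoseMap:
    """2-D dose distribution with physical pixel pitch.

    The grid origin convention is that the centre of the grid is the
    beam-axis estimate; :meth:`positions` returns millimetre coordinates
    relative to that centre.
    """

    values: np.ndarray  # 2-D, Gy or relative units
    pixel_pitch: float  # mm / pixel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DoseMap values must be a 2-D array")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def positions(self, axis: int) -> np.ndarray:
        """Millimetre coordinates of pixel centres along ``axis``, centred."""
        n = self.values.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    def central_roi_mean(self, roi_mm: float = 5.0) -> float:
        """Mean dose over a centred square ROI of side ``roi_mm``."""
        half_px = max(1, int(round(roi_mm / (2.0 * self.pixel_pitch))))
        r0, c0 = (s // 2 for s in self.values.shape)
        sl = self.values[
            max(r0 - half_px, 0) : r0 + half_px + 1,
            max(c0 - half_px, 0) : c0 + half_px + 1,
        ]
        return float(sl.mean())

    def scaled(self, factor: float) -> "DoseMap":
        return DoseMap(self.values * factor, self.pixel_pitch)


@dataclass
class DoseProfile:
    """1-D dose profile, normalised to the central-axis estimate."""

    positions: np.ndarray  # mm, uniform and strictly increasing
    values: np.ndarray  # dose / CAX dose
    axis: str = "crossplane"  # or "inplane"
    depth: float = 0.0  # cm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def interp(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.interp(x, self.positions, self.values)


@dataclass
class ProfileMetrics:
    """Shape metrics of one profile (the per-collimator report row)."""

    fwhm: float  # mm
    penumbra_left: float  # mm
    penumbra_right: float  # mm
    symmetry: float  # %
    flatness: float  # %

    def as_dict(self) -> dict[str, float]:
        return {
            "fwhm_mm": self.fwhm,
            "penumbra_left_mm": self.penumbra_left,
            "penumbra_right_mm": self.penumbra_right,
            "symmetry_pct": self.symmetry,
            "flatness_pct": self.flatness,
        }


@dataclass
class DepthDoseSeries:
    """Central-ROI doses against depth with the derived PDD curve."""

    depths: np.ndarray  # cm
    roi_doses: np.ndarray  # Gy (or relative)
    pdd: np.ndarray  # %, 100 at the reference (zero) depth

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.roi_doses = np.asarray(self.roi_doses, dtype=float)
        self.pdd = np.asarray(self.pdd, dtype=float)


@dataclass
class FilmScan:
    """An RGB film scan: 16-bit-per-channel pixels plus scan resolution."""

    pixels: np.ndarray  # (rows, cols, 3) uint16
    dpi: float = 75.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("FilmScan pixels must be (rows, cols, 3)")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.pixels.dtype != np.uint16:
            if self.pixels.min() < 0 or self.pixels.max() > 0xFFFF:
                raise ValueError("pixel values must lie in [0, 65535]")
            self.pixels = self.pixels.astype(np.uint16)

    @property
    def pixel_pitch(self) -> float:
        """mm per pixel implied by the scan dpi."""
        return MM_PER_INCH / self.dpi


@dataclass
class CalibrationCurve:
    """Fitted film response: intensity = a + b / (dose - c), c < 0.

    ``dose_range`` is the span of the calibration doses; inversion outside
    the corresponding intensity range is clamped by the caller.
    """

    form: str
    a: float
    b: float
    c: float
    dose_range: tuple[float, float]
    rms_residual: float  # Gy, residual of inverted intensities vs doses
    n_points: int
    monotone_ok: bool = True
    metadata: dict = field(default_factory=dict)

    def intensity(self, dose: np.ndarray | float) -> np.ndarray | float:
        return self.a + self.b / (np.asarray(dose, dtype=float) - self.c)

    def dose(self, intensity: np.ndarray | float) -> np.ndarray | float:
        return self.c + self.b / (np.asarray(intensity, dtype=float) - self.a)

    @property
    def intensity_range(self) -> tuple[float, float]:
        """(low, high) intensity corresponding to the fitted dose range.

        The response decreases with dose, so the low intensity belongs to
        the high dose end.
        """
        i_hi = float(self.intensity(self.dose_range[0]))
        i_lo = float(self.intensity(self.dose_range[1]))
        return (min(i_lo, i_hi), max(i_lo, i_hi))


@dataclass
class ChamberReadingSeries:
    """Tabulated electrometer readings against one independent variable.

    ``x`` is seconds, millimetres, mm Cu, or ``numpy.datetime64`` dates
    depending on ``kind``; ``y`` the reading (nC, Gy/min, or transmission
    fraction).
    """

    kind: str
    x: np.ndarray
    y: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CHAMBER_KINDS:
            raise ValueError(
                f"unknown series kind {self.kind!r}; expected one of {CHAMBER_KINDS}"
            )
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if len(self.x) and np.any(np.diff(self._x_numeric()) <= 0):
            raise ValueError("x must be strictly increasing within a series")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("readings must be finite")

    def _x_numeric(self) -> np.ndarray:
        if np.issubdtype(self.x.dtype, np.datetime64):
            return (self.x - self.x[0]) / np.timedelta64(1, "D")
        return self.x.astype(float)

    @property
    def x_days(self) -> np.ndarray:
        """Elapsed days for date-indexed series."""
        return self._x_numeric()


@dataclass
class ConstancyStatus:
    """Per-date output deviations and tolerance flags.

    Tolerance rule: a single reading deviating by >= 3 % from baseline
    fails outright; two consecutive readings each deviating by >= 2 %
    fail together; a lone reading in [2, 3) % is a warning.
    """

    deviations_pct: np.ndarray
    flags: list[str]  # per reading: ok | single_warn | consecutive_fail | single_fail
    overall: str

    @property
    def ok(self) -> bool:
        return self.overall == "ok"


@dataclass
class FlexMap:
    """Per-gantry-angle lateral (u) and longitudinal (v) panel displacement.

    Values are at panel scale (mm of physical panel displacement); divide
    by the magnification for the isocentre-scale companion.
    """

    angles: np.ndarray  # degrees
    u: np.ndarray  # mm, lateral (orthogonal to rotation axis)
    v: np.ndarray  # mm, parallel to rotation axis
    focal_spot: str = "large"
    magnification: Optional[float] = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.angles) == len(self.u) == len(self.v)):
            raise ValueError("angles, u and v must have equal length")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flex values must be finite")

    def at(self, angle: float) -> tuple[float, float]:
        """Linear interpolation in angle, periodic over 360 degrees."""
        order = np.argsort(self.angles)
        ang = self.angles[order]
        u = self.u[order]
        v = self.v[order]
        ang_ext = np.concatenate([ang, ang[:1] + 360.0])
        u_ext = np.concatenate([u, u[:1]])
        v_ext = np.concatenate([v, v[:1]])
        a = float(angle) % 360.0
        return (
            float(np.interp(a, ang_ext, u_ext)),
            float(np.interp(a, ang_ext, v_ext)),
        )

    def iso_scale(self) -> "FlexMap":
        if self.magnification is None:
            raise ValueError("magnification required for isocentre-scale flexmap")
        m = self.magnification
        return FlexMap(self.angles, self.u / m, self.v / m, self.focal_spot, 1.0)


@dataclass
class BBProjectionSet:
    """Grayscale BB projections tagged with gantry angle and stage offset."""

    images: list[np.ndarray]
    angles: np.ndarray  # degrees, one per image
    stage_offsets: np.ndarray  # (n, 3) mm, room coordinates (x, y, z)
    panel_pixel_pitch: float  # mm

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.stage_offsets = np.atleast_2d(np.asarray(self.stage_offsets, dtype=float))
        if len(self.images) != len(self.angles):
            raise ValueError("one image per angle required")
        if self.stage_offsets.shape != (len(self.images), 3):
            raise ValueError("one (x, y, z) stage offset per image required")
        if np.any((self.angles < 0) | (self.angles >= 360)):
            raise ValueError("angles must lie in [0, 360)")
        if self.panel_pixel_pitch <= 0:
            raise ValueError("panel_pixel_pitch must be positive")


@dataclass
class WLResult:
    """Winston–Lutz displacements of the BB relative to the collimation centre."""

    angles: np.ndarray  # degrees
    u: np.ndarray  # mm at isocentre scale
    v: np.ndarray  # mm at isocentre scale
    max_magnitude: float  # mm
    residual_u: Optional[np.ndarray] = None  # after tracking correction
    residual_v: Optional[np.ndarray] = None
    residual_max: Optional[tuple[float, float]] = None  # (max |u|, max |v|) mm


def as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr
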