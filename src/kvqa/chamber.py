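"""Ion-chamber series analyses: timer error, constancy, effective SSD, HVL.

These operate on :class:`~kvqa.core.ChamberReadingSeries` objects read
from the documented CSV schemas or produced by the synthetic generators.
"""
from __future__ import annotations

import numpy as np

from .core import ChamberReadingSeries, ConstancyStatus

__all__ = [
    "fit_timer_error",
    "check_constancy",
    "fit_effective_ssd",
    "compute_hvl",
]


def _r_squared(y: np.ndarray, y_fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_timer_error(series: ChamberReadingSeries) -> tuple[float, float]:
    """Timer error (end-effect) from a charge-vs-beam-on-time series.

    An ordinary least-squares line ``charge = m t + q`` is fitted and
    extrapolated; the timer error is the intercept expressed in time
    units, ``q / m`` — positive when the effective exposure is longer
    than the set time (the line crosses the time axis at ``-q/m``).

    Returns (timer_error_s, r_squared).  A non-positive slope is
    rejected as non-physical.
    """
    if series.kind != "linearity":
        raise ValueError("timer error requires a 'linearity' series")
    t = series.x.astype(float)
    q = series.y
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    m, q0 = np.polyfit(t, q, 1)
    if m <= 0:
        raise ValueError("non-physical fit: charge must increase with beam-on time")
    return float(q0 / m), _r_squared(q, m * t + q0)


def check_constancy(series: ChamberReadingSeries, baseline: float) -> ConstancyStatus:
    """Apply the output-constancy tolerance rule to dated dose rates.

    Deviation_i = 100 |rate_i - baseline| / baseline.  Any single
    deviation >= 3 % fails; two adjacent deviations each >= 2 % fail
    together; a lone deviation in [2, 3) % is a warning.
    """
    if series.kind != "constancy":
        raise ValueError("constancy check requires a 'constancy' series")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if len(series.y) == 0:
        raise ValueError("empty constancy series")
    dev = 100.0 * np.abs(series.y - baseline) / baseline

    flags = []
    n = len(dev)
    for i in range(n):
        if dev[i] >= 3.0:
            flags.append("single_fail")
        elif dev[i] >= 2.0:
            neighbour = (i > 0 and dev[i - 1] >= 2.0) or (i < n - 1 and dev[i + 1] >= 2.0)
            flags.append("consecutive_fail" if neighbour else "single_warn")
        else:
            flags.append("ok")

    if "single_fail" in flags:
        overall = "single_fail"
    elif "consecutive_fail" in flags:
        overall = "consecutive_fail"
    elif "single_warn" in flags:
        overall = "single_warn"
    else:
        overall = "ok"
    return ConstancyStatus(dev, flags, overall)


def fit_effective_ssd(
    series: ChamberReadingSeries,
    linearization: str = "sqrt_ratio",
) -> tuple[float, float]:
    """Effective source-to-surface distance from dose vs stage offset.

    For a point source at effective distance SSDeff the inverse-square
    law gives ``sqrt(D0 / D_delta) = 1 + delta / SSDeff``.  A least-
    squares line constrained through intercept 1 is fitted to the left
    side against the offset delta; the slope s yields SSDeff = 1/s.

    ``linearization='squared_ratio'`` instead fits the published form
    ``(D0/D_delta)^2 = 1 + delta/SSDeff``, which is not consistent with
    the inverse-square law and is provided for comparison only.

    Returns (ssd_eff_mm, r_squared of the linearised fit).
    """
    if series.kind != "inverse_square":
        raise ValueError("effective SSD requires an 'inverse_square' series")
    delta = series.x.astype(float)
    dose = series.y
    if len(delta) < 3:
        raise ValueError("need at least 3 offsets including 0")
    zero = np.flatnonzero(np.isclose(delta, 0.0))
    if zero.size == 0:
        raise ValueError("series must include the zero-offset reading")
    if np.any(dose <= 0):
        raise ValueError("all doses must be positive")
    d0 = dose[zero[0]]

    if linearization == "sqrt_ratio":
        y = np.sqrt(d0 / dose) - 1.0
    elif linearization == "squared_ratio":
        y = (d0 / dose) ** 2 - 1.0
    else:
        raise ValueError("linearization must be 'sqrt_ratio' or 'squared_ratio'")

    mask = ~np.isclose(delta, 0.0)
    x = delta[mask]
    yy = y[mask]
    slope = float(np.sum(x * yy) / np.sum(x * x))  # through-origin LS
    if slope <= 0:
        raise ValueError("non-physical fit: dose must fall with distance")
    r2 = _r_squared(y, slope * delta)
    return 1.0 / slope, r2


def _thickness_at_transmission(
    thickness: np.ndarray, transmission: np.ndarray, level: float
) -> float:
    """Thickness where transmission crosses ``level``, log-linear interp."""
    ln_t = np.log(transmission)
    target = np.log(level)
    below = np.flatnonzero(ln_t <= target)
    if below.size == 0:
        raise ValueError(f"transmission data do not span down to {level:g}")
    j = below[0]
    if j == 0:
        return float(thickness[0])
    t0, t1 = ln_t[j - 1], ln_t[j]
    frac = (target - t0) / (t1 - t0)
    return float(thickness[j - 1] + frac * (thickness[j] - thickness[j - 1]))


def compute_hvl(series: ChamberReadingSeries) -> tuple[float | None, float | None]:
    """First and second half-value layers from a transmission series.

    ln(T) is interpolated piecewise-linearly against added attenuator
    thickness.  HVL1 is the thickness at T = 0.5; HVL2 is the
    *additional* thickness from T = 0.5 down to T = 0.25.  Either value
    is returned as ``None`` when the data do not span the corresponding
    transmission level.
    """
    if series.kind != "transmission":
        raise ValueError("HVL requires a 'transmission' series")
    x = series.x.astype(float)
    t = series.y
    if np.any(np.diff(t) >= 0):
        raise ValueError("transmission must be strictly decreasing with thickness")
    if np.any(t <= 0):
        raise ValueError("transmission values must be positive")
    try:
        hvl1: float | None = _thickness_at_transmission(x, t, 0.5)
    except ValueError:
        return None, None
    try:
        x25 = _thickness_at_transmission(x, t, 0.25)
        hvl2: float | None = x25 - hvl1
    except ValueError:
        hvl2 = None
    return hvl1, hvl2
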