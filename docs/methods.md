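# Methods

This note records the models, conventions and numerical choices behind
`kvqa`, and what the synthetic generators do and do not emulate.

## Beam model

A collimated field at the isocentre plane is modelled with
Gaussian-integral (error-function) edges. For a circular collimator of
nominal size S (the FWHM) the edge applies to the radial distance,
`D(r) ∝ Φ((S/2 − r)/σ)`; for square collimators the edge applies
separably per axis as a rect–Gaussian convolution. The edge parameter
σ (mm) sets the penumbra: the 80–20 % width of an error-function edge
is `(z₀.₈ − z₀.₂)σ = 1.6832 σ`, which gives closed-form oracles for the
penumbra metric. Two modulations perturb the flat top: a quadratic
"dome" term `1 − k·(r/(S/2))²` (k > 0 is droop, k < 0 horns) and a
linear tilt `1 + t·x` (t in fraction/mm) producing asymmetry. The map
is normalised so the dose at the field centre equals the nominal
central-axis dose exactly.

Depth series scale the surface map by
`exp(−μ_eff d)·(1 + s·d)` with depth d in cm, an effective attenuation
μ_eff (1/cm) and a scatter-growth term s (1/cm) that increases with
field size, optionally times an inverse-square factor for the
source-to-plane distance. This is phenomenological: it reproduces the
shape of measured kV depth-dose curves without modelling the phantom
material.

## Film response and calibration

Film response uses the saturating rational form
`I(D) = a + b/(D − c)` with c < 0, strictly decreasing in dose and
analytically invertible (`D = c + b/(I − a)`). Defaults (a = 4000,
b = 150000, c = −3 Gy on the 16-bit scale) put zero dose near 54 000
counts and 10 Gy near 15 500, similar to radiochromic film scanned in
transmission. Scanner noise is additive Gaussian on intensity counts.
Green and blue channels carry weaker variants of the same form so scans
look plausible; only red is used quantitatively.

Calibration fits the ROI-mean red intensity against dose by
least squares (`scipy.optimize.curve_fit`, c bounded negative), with at
least four distinct dose levels including zero and replicate films
averaged. The rms residual is reported in dose space (invert the fitted
curve at the measured intensities). An alternative net-optical-density
fit (`log10(I₀/I)` vs dose, same rational form) is available behind the
`use_net_od` switch. Inversion clamps intensities outside the fitted
range to the corresponding dose-range end and warns when more than 5 %
of pixels are clamped; a relative tolerance of 10⁻³ of the intensity
span keeps boundary pixels (e.g. the zero-dose background under noise)
from being counted as out of range.

The adaptive filter is the classic local-statistics Wiener filter:
with local mean m and variance s² over an odd window (default 5×5,
chosen to match the usual neighbourhood of pixel-wise adaptive
filtering of film scans) and noise estimate v = mean of all local
variances, `out = m + max(s² − v, 0)/max(s², v)·(in − m)`. Borders are
edge-replicated. On fields only a few pixels wide (the 2.5 mm
collimator at 75 dpi is ~7 px) the filter measurably lowers the peak;
recovered output factors for the smallest field are biased low by a few
percent for this reason, mirroring the difficulty of small-field film
dosimetry at coarse scan resolution.

## Profile metrics

Profiles are the mean of five adjacent lines (odd by contract) through
the map centre, normalised to the central-axis estimate: the mean over
a central square ROI of side 20 % of the FWHM, floored at 3×3 pixels.
Level crossings (50 % for field size, 80/20 % for penumbra) use linear
interpolation between bracketing samples; a plateau exactly at a level
resolves to its outermost sample. Symmetry and flatness are evaluated
over the central 80 % of the FWHM centred midway between the 50 %
crossings. Mirror-point and region-endpoint values are evaluated with a
shape-preserving monotone cubic (PCHIP) interpolant rather than linear
interpolation: on the steep penumbral samples near the region boundary
linear chords are biased low by several percent of dose, and the
monotone cubic removes most of that bias without inventing overshoot.

Known limitation: for a 2.5 mm field at the 75 dpi pitch (0.339 mm) the
central-80 % boundary falls on the penumbral cliff, where the profile
drops by ~0.4 per pixel. There, flatness retains a discretisation error
of one to a few percentage points relative to a continuum evaluation —
irreducible at that sampling — while field size, penumbra and symmetry
remain within a pixel-scale tolerance. Higher-resolution scanning is
the practical remedy for small-field flatness.

Percent differences are `100·|local − reference|/denominator` with the
denominator selectable (published-mean convention vs film-denominator
convention); report rounding is decimal half-up, applied only at
presentation.

## Chamber analyses

- **Timer error**: OLS line through charge vs beam-on time;
  `t_err = intercept/slope`, positive when the effective exposure
  exceeds the set time. Exact on noiseless data for any slope and
  intercept.
- **Output constancy**: deviation of each dated rate from the baseline;
  ≥3 % on a single reading fails, ≥2 % on two adjacent readings fails,
  a lone ≥2 % is a warning. The end-effect is deliberately not
  corrected for in constancy arithmetic.
- **Effective SSD**: the inverse-square law gives
  `√(D₀/D_Δ) = 1 + Δ/SSD_eff`; a through-intercept-1 least-squares line
  yields SSD_eff = 1/slope, exact on ideal data. The squared-ratio form
  sometimes printed in commissioning write-ups, `(D₀/D_Δ)² = 1 +
  Δ/SSD_eff`, is dimensionally inconsistent with an inverse-square
  source and does not recover the generating distance on exact data; it
  is available as `linearization="squared_ratio"` for comparison only.
- **HVL**: log-linear interpolation of ln T against added attenuator
  thickness; HVL₁ at T = 0.5, HVL₂ as the *additional* thickness to
  T = 0.25 (the alternative total-to-quarter convention is HVL₁ +
  HVL₂). The synthetic attenuation model
  `T(x) = exp(−μ₀x/(1 + hx))` gives beam hardening (effective μ falling
  with thickness) for h > 0 and has closed-form roots for oracles.

## Imaging geometry

Image convention: origin top-left, u rightward (gantry-lateral), v
downward (rotation axis); gantry 0° has the source at the top,
clockwise positive. Defaults reflect a source-axis distance of
306.4 mm, source-detector distance of 625 mm (magnification ≈ 2.04) and
a 0.2 mm panel pixel, i.e. ~0.1 mm per pixel at isocentre.

A BB offset from isocentre projects with depth-dependent magnification
`m(w) = SDD/(SAD − w)` (w toward the source); lateral shots at two
heights separate SAD from SDD: `SAD = m(z)·z/(m(z) − m(0))`,
`SDD = m(0)·SAD`. BB centroids are darkness-weighted centroids of the
below-threshold blob, threshold at the midpoint of tight robust
percentiles (0.05/99.5) so discs occupying well under 1 % of the panel
are still segmented; blobs under 5 px are treated as noise.

Model split for rotation tests: the BB projection carries the panel
flex term (sinusoid per axis, amplitude/phase/offset), representing the
image-registration drift that a stored flexmap corrects; the collimated
aperture carries the magnified isocentre-wobble term, representing
motion of the collimation axis relative to a BB fixed at the nominal
isocentre. Physically both projections share the panel-sag component —
the split reproduces the vendor workflow in which flexmaps are measured
in a dedicated rotation (no aperture) and then applied to Winston–Lutz
data, making the two effects separable by construction. The flexmap
reference centroid is the arithmetic mean over the sampled angles,
which removes the constant term of a uniformly sampled sinusoid.

Winston–Lutz displacement is (BB centroid − field centroid) × pitch /
magnification, flex-corrected when a flexmap is supplied; the field
centroid is the centroid of the above-half-maximum aperture region with
holes filled, so the BB shadow does not bias it. Supplying a previous
result's displacements as a tracking correction reports the residual;
on self-correction it is noise-limited, below one panel pixel at
isocentre scale.

## Synthetic bundles and problem sizes

`make_fixtures` writes a self-describing bundle (films as 16-bit RGB
TIFF at 75 dpi, chamber CSVs, BB projections as grayscale TIFF with a
manifest, `truth.json` sidecar). The paper-like scenario uses the
collimator set {2.5, 5, 10, 25 mm circles; 10×10, 40×40 mm² squares},
depths 0–5.5 cm, calibration doses 0–8 Gy with three replicates, film
noise of 120 counts (~0.2 % of the zero-dose intensity), bi-monthly
constancy sessions with −1 %/year drift, and 36-angle rotations on a
150×200 px panel. These sizes keep a full end-to-end run in seconds
while leaving every recovery within its test tolerance; tests use a
two-collimator variant of the same bundle. The generators emulate edge
shapes, saturating film response, attenuation, inverse-square falloff,
drift, flex and wobble — they do not emulate film lateral-response
artifacts, scanner polarisation, spectral effects, or Monte Carlo
transport, so passing recovery tests demonstrates correctness of the
analysis chain, not fidelity to any particular physical device.
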