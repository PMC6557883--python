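"""Profile metrics (field size, penumbra, symmetry, flatness) per collimator.

Generates noiseless dose maps for the clinical collimator set and prints
the Table-style metric row for each: FWHM field size, 80-20 % penumbrae,
symmetry and flatness over the central 80 % of the field.
"""
from kvqa import BeamGroundTruth, extract_profile, generate_dose_map, profile_metrics

PITCH = 25.4 / 75.0

collimators = [
    ("2.5 mm circle", "circular", 2.5, 0.25),
    ("5 mm circle", "circular", 5.0, 0.30),
    ("10 mm circle", "circular", 10.0, 0.35),
    ("25 mm circle", "circular", 25.0, 0.40),
    ("10x10 mm square", "square", 10.0, 0.35),
    ("40x40 mm square", "square", 40.0, 0.45),
]

print(f"{'collimator':<18}{'FWHM':>7}{'pen L':>7}{'pen R':>7}{'sym %':>7}{'flat %':>7}")
for name, shape, size, sigma in collimators:
    truth = BeamGroundTruth(shape=shape, nominal_size=size, edge_sigma=sigma,
                            flatness_dome=0.02, tilt=0.002)
    m = generate_dose_map(truth, size + 8 * sigma + 4.0, PITCH)
    met = profile_metrics(extract_profile(m, "crossplane"))
    print(f"{name:<18}{met.fwhm:>7.2f}{met.penumbra_left:>7.2f}{met.penumbra_right:>7.2f}"
          f"{met.symmetry:>7.2f}{met.flatness:>7.2f}")
# FWHM tracks the nominal collimator size to within one pixel; the small
# tilt shows up as non-zero symmetry, the dome as non-zero flatness, and
# both grow for small fields whose central 80 % reaches into the penumbra.
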