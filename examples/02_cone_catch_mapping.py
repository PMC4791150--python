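"""Map camera colours to the cone catches of a UV-sensitive tetrachromat.

Builds a training table of paired camera / receptor quanta over a library of
smooth synthetic reflectance spectra under a daylight-like illuminant, fits
the no-intercept polynomial mapping (single channels plus pairwise products)
and reports the per-receptor training R².  Values near 1 mean the camera's
five channels carry nearly all the information the four cones would see.
"""

from multispec.conemap import PolynomialTermSet, build_training_table, fit_cone_map
from multispec.synth import (
    avian_receptors,
    daylight_illuminant,
    default_camera,
    generate_spectra_library,
)

camera = default_camera()
receptors = avian_receptors()
library = generate_spectra_library(1000, seed=7)

table = build_training_table(camera.bank, receptors, daylight_illuminant(), library)
print(f"training table: {table.shape[0]} spectra x {table.shape[1]} channels")

terms = PolynomialTermSet(tuple(camera.bank.channel_names), interaction_level=2)
model = fit_cone_map(table, terms=terms)
for rec in receptors.channel_names:
    print(f"  {rec}: R² = {model.r_squared[rec]:.5f}  ({len(model.terms[rec])} terms)")

simplified = fit_cone_map(table, terms=terms, simplification="BIC")
kept = {r: len(simplified.terms[r]) for r in receptors.channel_names}
print(f"after BIC stepwise simplification, terms kept per receptor: {kept}")
print(
    "\nR² ~ 0.999 means mapped cone catches are nearly indistinguishable from "
    "direct spectral computation; BIC drops products that do not pay for "
    "their degrees of freedom."
)
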