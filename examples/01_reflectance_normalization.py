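"""Normalize a photograph against its grey standards and measure reflectance.

Renders a synthetic scene containing coloured patches plus 20% and 80% grey
standards, rebuilds the normalized 32-bit stack from the saved project file,
and measures each region.  Printed means are on the 0-1 reflectance scale
(1.0 = the 100% level), so a value of 0.43 in channel vR means the patch
reflects 43% as much long-wave light as an ideal white surface.
"""

import tempfile

from multispec import build_stack, measure_regions
from multispec.synth import (
    default_camera,
    flat_reflectance,
    generate_spectra_library,
    patch_grid,
    render_scene,
    write_scene_project,
)

library = generate_spectra_library(4, seed=21)
reflectances = list(library.spectra) + [flat_reflectance(20), flat_reflectance(80)]
scene = patch_grid(reflectances, standard_percents=[None] * 4 + [20, 80])
camera = default_camera()
images, truth = render_scene(scene, camera, seed=21)

with tempfile.TemporaryDirectory() as d:
    project = write_scene_project(scene, images, d, name="demo")
    stack = build_stack(project, base_dir=d)

print(f"stack channels: {stack.channel_names}, normalized={stack.normalized}")
table = measure_regions(stack, project.regions)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nEach row is one region x channel: 'mean' is estimated reflectance "
    "(0-1), 'sd' the within-region spread, 'n' the pixel count."
)
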