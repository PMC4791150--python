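# multispec

Calibrated multispectral image analysis for visual ecology: turn linear
camera images into objective measurements of **reflectance**, **colour as an
animal sees it**, and **pattern**.

Consumer cameras are built to make pictures for human eyes, not measurements:
their processed output is nonlinear in radiance, white-balanced, and clipped.
Given *linear* 16-bit images (from a RAW decoder configured for linear
output, or linear TIFF/PNG), `multispec` provides the full measurement
pipeline used in studies of animal coloration, signalling and camouflage:

- **Reflectance normalization** against grey standards. With one standard of
  stated reflectance *S* (%) and mean pixel value *G*, a pixel *V* maps to
  `V · (S/100) · (65535/G)` on the 16-bit scale; with several standards an
  ordinary least-squares line (the same relation plus an intercept) also
  recovers the photograph's black point, correcting veiling glare. A
  histogram heuristic (lowest 0.5% of pixels ≡ 0.5% reflectance) covers the
  single-standard case, and a *sequential* mode uses a standard photographed
  separately under identical conditions. All processing is 32-bit floating
  point: values above 100% (shiny, fluorescent surfaces) are never clipped.
- **Channel alignment**: an exhaustive coarse-to-fine search over translation
  (3×3 candidate grid with offset halving, e.g. 128 → 64 → … → 1 px) and
  scale (hill climbing from 1% steps), minimizing the mean absolute pixel
  difference — robust where feature matching fails, e.g. UV-blue vs
  visible-blue pairs.
- **Cone-catch mapping** (camera → animal vision). Receptor quantum catch is
  `L = Σ_λ l(λ) Q(λ) I(λ)` over a 1 nm grid, von-Kries-normalized against a
  white reference (`L_n = L/L_wr`). Because natural spectra are smooth, a
  no-intercept polynomial in the camera channels (e.g.
  `a₁R + a₂G + a₃B + a₄RG + a₅RB + a₆GB`, optionally three-way products and
  squares) maps normalized camera responses to cone catches with R² ≈ 0.999;
  backward stepwise AIC/BIC simplification prunes unneeded terms.
- **Region measurement** of polygonal ROIs (pooled groups unified before
  measurement), batch processing of whole project directories.
- **Pattern granularity**: FFT bandpass filtering into octave-spaced bands;
  a band's *energy* is the SD of the filtered image, describing marking
  size, contrast and diversity, plus pairwise pattern differences.
- **Receptor-noise-limited discrimination**: chromatic and achromatic
  distances in JND units between measured samples, for di- to tetrachromatic
  visual systems.

A small JSON *project file* records sources, standard selections, alignment
offsets, scale bar and ROIs, so the exact 32-bit stack is rebuilt on demand
instead of being stored. A synthetic-scene renderer (`multispec.synth`)
generates physically consistent camera images with known ground truth, so
the whole pipeline is testable without cameras.

## Worked example

`examples/02_cone_catch_mapping.py` fits a mapping from a five-channel
visible+UV camera to a UV-sensitive tetrachromat over 1000 smooth synthetic
spectra:

```
training table: 1000 spectra x 9 channels
  uv: R² = 0.99996  (15 terms)
  sw: R² = 0.99992  (15 terms)
  mw: R² = 0.99984  (15 terms)
  lw: R² = 0.99985  (15 terms)
after BIC stepwise simplification, terms kept per receptor: {'uv': 9, 'sw': 13, 'mw': 12, 'lw': 12}
```

Each R² is the training fit of one receptor's catch predicted from the
camera's channels: ≈0.9999 means camera colours carry essentially all the
information those cones would receive. The other scripts in `examples/`
walk through normalization, alignment, granularity and JND computation the
same way; each prints its numbers with a line explaining them. The `multispec`
command exposes the same workflow for shell use (`multispec --help`), e.g.
`multispec batch <dir> --out results.csv` to measure every project in a
directory with identical settings.

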