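# Methods

This note documents the models implemented in `multispec`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not demonstrate.

## Spectral model

All spectral quantities — camera/receptor sensitivities `l(λ)`, reflectances
`Q(λ)`, illuminant radiance `I(λ)` — live on an integer 1 nm wavelength grid
with closed, inclusive ranges (typically 300–700 nm). Quantum catch is the
plain inclusive sum `L = Σ_λ l·Q·I`; no trapezoid weighting is applied
because the grid step is fixed at 1 nm (curves sampled more coarsely are
linearly interpolated on load). Resampling a curve to a wider grid
zero-fills outside its measured range rather than extrapolating:
sensitivities are physically zero outside their band, and any nonzero
extrapolation would be invented data.

von Kries adaptation divides each channel's catch by its catch for an ideal
flat white under the same illuminant, so a grey surface scores equally in
every channel and the white reference itself scores exactly 1. Both camera
and receptor quanta are adapted this way before mapping, which makes the
mapping illumination-referenced rather than absolute.

## Normalization

Reflectance is carried internally on a 0–1 scale (1.0 = the 100% standard
level); 65535 is applied only when exporting 16-bit levels. This keeps the
32-bit arithmetic scale-free while honouring the 16-bit convention exactly.

- One standard: a line through the origin, slope `(S/100)/G` per channel.
- ≥2 standards: per-channel ordinary least squares of stated reflectance on
  mean pixel value. Regressing in this direction makes prediction direct
  (reflectance = slope·pixel + intercept). With ≥3 standards the fit R² is
  recorded and any channel under 0.98 triggers a warning (machine-readable
  code `LOW_LINEARISATION_FIT`); the model is still returned, since the
  user may knowingly be working with a marginal standard set.
- Histogram dark point (one standard only): the dark anchor is the **mean of
  the pixels at or below the 0.5th percentile** of the channel histogram,
  assigned 0.5% reflectance; the single lowest pixel is never used alone
  because it is dominated by noise. Whether the original procedure averages
  the tail or takes the percentile value itself is ambiguous; averaging is
  the more noise-robust reading and is fixed here. The heuristic assumes the
  scene's darkest content genuinely reflects about 0.5% — scenes without
  near-black content will overcorrect.
- Sequential method: standards measured in a separate frame, asserted by the
  caller to share lighting and settings. If the standard frame was k× as
  bright, recovered reflectances are biased by 1/k; this failure mode is
  exercised in the tests rather than guarded against, as it is undetectable
  from the images alone.

Negative normalized values (possible with an intercept) are preserved in the
stack; they are floored at zero only where non-negativity is required (cone
mapping), and each flooring event is logged.

## Alignment

Cost is the **mean** absolute difference over the overlapping, in-bounds
pixels (optionally inside an ROI). A raw sum would favour large offsets with
small overlaps; the mean removes that bias, which is the one deliberate
deviation from the classic "sum of absolute differences" phrasing.

Translation search: evaluate the 3×3 grid of offsets spaced by the current
step (default start 128 px, reduced with a warning for small images) around
the incumbent, re-centre on the best, halve the step, finishing at 1 px.
Ties prefer the smaller displacement, deterministically. Scale search wraps
this: hill climbing from unit scale in 1% steps (each candidate scale fully
re-aligned in translation), halving the step when neither direction
improves, terminating below 0.001 — the termination tolerance is our choice,
as no printed value exists. Scaling is bilinear about the image centre.

The hierarchical search can stall in a coarse local minimum on textures
whose variance sits mainly at fine scales (e.g. single-scale noise); real
scenes, with red (coarse-dominated) spatial spectra, give it a wide basin.
The full search trace is exposed on the result for convergence inspection,
and `brute_force_translation` provides an exhaustive fallback for small
images. Rotation and shear are out of scope, as is feature-based
registration.

## Cone mapping

The polynomial has **no intercept**: a camera in the dark must predict zero
catch. Terms are single channels, plus all distinct pairwise products
(level 2), plus all distinct triples (level 3), plus per-channel squares on
request. Fitting is per-receptor ordinary least squares on the expanded term
matrix; aliased (rank-deficient) terms are dropped once, with a warning.
R² is computed against the **uncentered** total sum of squares, the form
consistent with a through-the-origin model; centred R² would overstate fit
quality for data far from the origin.

Stepwise simplification is backward-only and greedy: repeatedly refit with
each single term removed, drop the removal that most improves the criterion
(AIC `n·ln(RSS/n) + 2k`, BIC `n·ln(RSS/n) + k·ln n`), stop when no removal
improves it; ties break by term order. BIC's larger penalty makes it remove
more terms than AIC on average — asserted statistically in the tests, since
greedy paths can occasionally differ on a single data set. Single-term
greedy steps are our reading of "stepwise"; drop-all-nonsignificant variants
would be faster but path-dependent in less transparent ways.

The number of camera channels must be at least the number of receptors, and
both sensitivity sets must overlap the spectra library's range. Training
rows must at least equal the term count (identifiability); fewer than two
rows per term warns.

## Granularity

Bands are octave-spaced pass sizes (2, 4, …, ≤512 px, configurable). Each
band's filter is a hard isotropic annulus in frequency space whose
wavelength bounds are the geometric midpoints to the neighbouring band
sizes (end bands extend by the same octave ratio), so the annuli tile
frequency space without overlap. Energy is the standard deviation of the
filtered image over in-region pixels; pixels outside the region are replaced
by the region mean before the transform to suppress boundary ringing.
Bands larger than the region's smaller bounding-box side are computed but
flagged unreliable rather than dropped. Analysis operates on one
caller-chosen channel (typically a luminance or double-cone channel).

Pattern difference is the summed absolute band-energy difference, requiring
identical band sets and pixel scale; comparing photographs therefore first
requires `rescale_to_uniform` (bilinear) to a common px/mm. The "diversity"
statistic — the count of bands holding more than half the dominant band's
energy — is an interpretation; no canonical formula exists for it.

## Discrimination

The receptor-noise-limited model is implemented in its log-linear,
neural-noise-only form: receptor signals `Δf_i = ln(q_i^a/q_i^b)`, noise
`e_i` per receptor, and the standard closed-form ΔS for 2–4 receptors
(equivalently, the noise-weighted distance of Δf after projecting out the
achromatic direction — the tests verify this equivalence). Quantum
(intensity-dependent) noise variants are out of scope. Noise can be derived
from relative cone abundances as `e_i = ω_ref·√(η_ref/η_i)`; shipped example
abundances are user-editable parameters, not measurements. Log-ratio signals
make ΔS invariant to a common intensity factor, consistent with the von
Kries step upstream.

## Synthetic scenes and what they show

The renderer computes each patch's quantum catch exactly as the spectral
model does, scales by exposure and per-channel gain (set so a 100% white
sits at ~60000 DN at unit exposure), adds an optional veiling-glare offset,
Gaussian noise with SD `a + b·signal` (defaults a = 20 DN, b = 1%, standing
in for read and shot noise), and quantizes to 16 bits with saturation.
A `gamma ≠ 1` option deliberately breaks linearity as a negative control.
Reflectance spectra are logistic squashes of low-order Gaussian bases —
smooth, bounded curves sharing the key property of natural spectra that
makes polynomial mapping work. Alignment fixtures use multi-octave
(red-spectrum) textures, matching the coarse-dominated spatial statistics of
real scenes; zoomed fixtures are sampled from a 2× supersampled parent so
the zoom happens before pixel sampling, as real optics do.

The validation experiments are therefore *consistency* checks at desk
scale: the eight-standard (2, 5, 10, 20, 40, 60, 80, 99%) linearity series
across three exposures (expected values normalized by each photograph's
pooled standard response, corrected for any saturation-excluded standards),
and the cone-mapping experiment (3000 spectra, five camera channels,
avian-like tetrachromat, pairwise interactions, no simplification). Default
fixtures are ≤256×256 px and libraries ≤3000 spectra, so the full suite runs
in seconds on one CPU. Passing them shows the pipeline's mathematics and
bookkeeping are right; it does not certify any physical camera's linearity,
spectral sensitivity estimates, demosaicing artefacts, lens flare, or the
metamerism risk of real spectra — those remain properties of real equipment
that users must validate with real standards.

## Known limitations

- RAW ingestion delegates to an external decoder (rawpy/libraw) and trusts
  its linear configuration; no linearity check is performed on load.
- No flat-field/vignetting correction; no rotation or shear in alignment.
- The project format is a documented JSON schema; files from the original
  ImageJ-based tooling are not importable.
- The RNL model's general n-receptor form is not exposed (2–4 receptors
  only), and colour-space visualisations are out of scope.
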