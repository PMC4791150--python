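"""Synthetic cameras, scenes and spectra for end-to-end validation.

Real validation of a calibration pipeline needs photographs of reflectance
standards and a library of measured natural spectra.  This module renders
physically consistent stand-ins: a parameterized multispectral camera with
smooth unimodal sensitivities (five channels vR, vG, vB, uB, uR spanning
300-700 nm by default), a daylight-like broadband illuminant, flat grey
standards, and libraries of smooth random reflectance spectra emulating the
key property of natural spectra — smoothness — that makes low-order
polynomial cone mapping work.  Rendered pixel values are exactly linear in
scene radiance before noise and 16-bit quantization, so every downstream
claim (normalization exactness, cone-map fit quality, alignment recovery)
can be checked against known ground truth.

Two desk-scale validation experiments are provided: a linearity experiment
photographing an 8-standard set (2-99% reflectance) across exposures, and —
via the library generator plus the cone-mapping module — a mapping-accuracy
experiment against a synthetic spectra library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .images import LinearImage, MspecProject, StandardSelection
from .spectral import (
    ReflectanceLibrary,
    SensitivityBank,
    SpectralCurve,
    cone_catch,
    white_reference,
)

__all__ = [
    "SyntheticCamera",
    "SyntheticScene",
    "Patch",
    "gaussian_sensitivity",
    "daylight_illuminant",
    "default_camera",
    "avian_receptors",
    "flat_reflectance",
    "generate_spectra_library",
    "generate_jagged_library",
    "render_scene",
    "scaled_shifted_pair",
    "patch_grid",
    "write_scene_project",
    "standard_scene",
    "linearity_experiment",
    "STANDARD_SET_PERCENT",
]

#: the stated reflectances of the standard validation set, in percent
STANDARD_SET_PERCENT = (2, 5, 10, 20, 40, 60, 80, 99)

GRID_START, GRID_END = 300, 700


def _grid():
    return np.arange(GRID_START, GRID_END + 1)


def gaussian_sensitivity(center_nm: float, width_nm: float, name: str = "") -> SpectralCurve:
    """A smooth unimodal (Gaussian) sensitivity on the 300-700 nm grid."""
    wl = _grid()
    vals = np.exp(-0.5 * ((wl - center_nm) / width_nm) ** 2)
    return SpectralCurve(GRID_START, vals, name=name)


def daylight_illuminant(temperature_k: float = 6500.0, name: str = "daylight-6500K") -> SpectralCurve:
    """A smooth broadband daylight-like illuminant (Planck spectrum, peak 1).

    A 6500 K black-body radiance curve stands in for standard daylight: it is
    broadband, smooth and UV-containing, which is what the pipeline needs
    from its model illuminant.
    """
    wl_m = _grid() * 1e-9
    h, c, k = 6.626e-34, 2.998e8, 1.381e-23
    rad = (2 * h * c**2 / wl_m**5) / (np.exp(h * c / (wl_m * k * temperature_k)) - 1.0)
    return SpectralCurve(GRID_START, rad / rad.max(), name=name)


def flat_reflectance(percent: float, name: str | None = None) -> SpectralCurve:
    """A spectrally flat (grey) Lambertian reflectance at the stated level."""
    vals = np.full(GRID_END - GRID_START + 1, percent / 100.0)
    return SpectralCurve(GRID_START, vals, name=name or f"grey{percent:g}")


@dataclass(frozen=True)
class SyntheticCamera:
    """A linear multispectral camera model.

    Rendered signal per channel: quantum catch x exposure x gain, plus a
    veiling-glare offset, Gaussian noise with SD = noise_a + noise_b * signal
    (additive floor plus signal-proportional shot-noise stand-in), then
    quantization to 16 bits with saturation at 65535.  ``gamma`` defaults to
    1 (linear); values != 1 deliberately break linearity for negative
    controls.
    """

    bank: SensitivityBank
    gains: np.ndarray
    noise_a: float = 20.0  # DN, additive floor
    noise_b: float = 0.01  # signal-proportional fraction
    glare_dn: float = 0.0
    bit_depth: int = 16
    gamma: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if g.size != len(self.bank):
            raise ValueError("one gain per channel required")
        if np.any(g <= 0):
            raise ValueError("gains must be positive")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit rendering is supported")
        object.__setattr__(self, "gains", g)

    @property
    def channel_names(self):
        return self.bank.channel_names


def default_camera(
    illuminant: SpectralCurve | None = None,
    noise_a: float = 20.0,
    noise_b: float = 0.01,
    glare_dn: float = 0.0,
    gamma: float = 1.0,
    white_level_dn: float = 60000.0,
) -> SyntheticCamera:
    """The standard five-channel visible+UV camera (vR, vG, vB, uB, uR).

    Visible channels are broad Gaussians at 600/535/460 nm; the UV-filter
    channels peak at 360/385 nm, mimicking the residual UV response of the
    blue and red sensor channels behind a UV-pass filter.  Gains are set so
    a 100% flat white under the given illuminant renders at *white_level_dn*
    (just below saturation) at unit exposure.
    """
    illum = illuminant or daylight_illuminant()
    curves = (
        gaussian_sensitivity(600, 45, "vR"),
        gaussian_sensitivity(535, 40, "vG"),
        gaussian_sensitivity(460, 35, "vB"),
        gaussian_sensitivity(360, 22, "uB"),
        gaussian_sensitivity(385, 28, "uR"),
    )
    bank = SensitivityBank(curves, tuple(c.name for c in curves))
    white = white_reference(bank, illum)
    gains = white_level_dn / white.quanta
    return SyntheticCamera(bank, gains, noise_a, noise_b, glare_dn, 16, gamma)


def avian_receptors() -> SensitivityBank:
    """A UV-sensitive tetrachromat visual system (uv, sw, mw, lw cones).

    Smooth unimodal sensitivities with peaks typical of a UVS-type bird
    (roughly 370, 445, 508, 565 nm).
    """
    curves = (
        gaussian_sensitivity(370, 18, "uv"),
        gaussian_sensitivity(445, 22, "sw"),
        gaussian_sensitivity(508, 26, "mw"),
        gaussian_sensitivity(565, 32, "lw"),
    )
    return SensitivityBank(curves, tuple(c.name for c in curves))


# ---------------------------------------------------------------------------
# Spectra libraries


def generate_spectra_library(n: int, seed: int, smoothness: float = 60.0) -> ReflectanceLibrary:
    """A seeded library of smooth random reflectance spectra in [0, 1].

    Each spectrum is a logistic squash of a low-order basis: a random
    baseline plus 1-4 broad Gaussians with widths drawn around *smoothness*
    nm (and never narrower than half of it), giving the gentle curvature of
    natural reflectance spectra.  Identical seeds give identical libraries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    wl = _grid().astype(float)
    spectra = []
    for i in range(n):
        x = np.full(wl.size, rng.normal(-0.4, 1.0))
        for _ in range(rng.integers(1, 5)):
            center = rng.uniform(250, 750)
            width = max(smoothness / 2, rng.normal(smoothness * 1.5, smoothness / 2))
            amp = rng.normal(0.0, 1.6)
            x += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        refl = 1.0 / (1.0 + np.exp(-x))
        spectra.append(SpectralCurve(GRID_START, refl, name=f"synthetic-{i:05d}"))
    return ReflectanceLibrary(tuple(spectra), tuple("synthetic" for _ in spectra))


def generate_jagged_library(n: int, seed: int) -> ReflectanceLibrary:
    """A deliberately rough control library (unsmoothed noise in [0, 1])."""
    rng = np.random.default_rng(seed)
    wl = _grid()
    spectra = tuple(
        SpectralCurve(GRID_START, rng.uniform(0, 1, wl.size), name=f"jagged-{i:05d}")
        for i in range(n)
    )
    return ReflectanceLibrary(spectra, tuple("jagged-control" for _ in spectra))


def textured_field(
    shape, seed: int, octaves: int = 6, power: float = 1.5, amplitude: float = 1.0
) -> np.ndarray:
    """Natural-looking multi-octave (red-spectrum) random texture.

    Sums Gaussian-smoothed noise at dyadic scales, weighting scale sigma by
    sigma**power, so the image has structure at every spatial frequency with
    most of its variance at coarse scales — like a real scene.  The
    coarse-scale dominance is what gives the coarse-to-fine alignment search
    a wide attraction basin: single-scale noise has none, and the search can
    stall on it.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    out = np.zeros(shape)
    for o in range(octaves):
        sigma = 2.0**o
        layer = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
        out += layer * sigma**power
    out /= np.abs(out).max() or 1.0
    return amplitude * out


def scaled_shifted_pair(shape, seed: int, dx: float, dy: float, scale: float = 1.0, supersample: int = 2):
    """A (fixed, moving) channel pair whose moving image was captured shifted
    by (dx, dy) px and zoomed by *scale* about the centre.

    Both images are sampled from one supersampled parent texture (the zoom is
    applied before pixel sampling, as a real refocus happens before the
    sensor), so the pair carries no asymmetric interpolation blur and the
    best compensating alignment is genuinely (-dx, -dy) at 1/scale.
    """
    from .alignment import warp_channel

    s = supersample
    parent = textured_field((shape[0] * s, shape[1] * s), seed)
    warped = np.nan_to_num(warp_channel(parent, dx * s, dy * s, scale), nan=0.0)

    def block_mean(a):
        return a.reshape(shape[0], s, shape[1], s).mean(axis=(1, 3))

    return block_mean(parent), block_mean(warped)


# ---------------------------------------------------------------------------
# Scenes and rendering


@dataclass(frozen=True)
class Patch:
    """An axis-aligned rectangular patch of uniform reflectance."""

    x0: int
    y0: int
    width: int
    height: int
    reflectance: SpectralCurve
    label: str = ""
    standard_percent: float | None = None  # set for flat grey standards

    def vertices(self):
        x0, y0 = self.x0 - 0.5, self.y0 - 0.5
        x1, y1 = x0 + self.width, y0 + self.height
        return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))


@dataclass(frozen=True)
class SyntheticScene:
    """A grid of disjoint reflectance patches under one illuminant.

    Pixels not covered by a patch take the *background* reflectance (black
    when None).
    """

    shape: tuple  # (H, W)
    patches: tuple
    illuminant: SpectralCurve
    background: SpectralCurve | None = None

    def __post_init__(self) -> None:
        occupied = np.zeros(self.shape, dtype=bool)
        for p in self.patches:
            if p.x0 < 0 or p.y0 < 0 or p.x0 + p.width > self.shape[1] or p.y0 + p.height > self.shape[0]:
                raise ValueError(f"patch {p.label!r} exceeds the scene bounds")
            block = occupied[p.y0 : p.y0 + p.height, p.x0 : p.x0 + p.width]
            if block.any():
                raise ValueError(f"patch {p.label!r} overlaps another patch")
            block[:] = True
            if p.standard_percent is not None and np.ptp(p.reflectance.values) > 1e-12:
                raise ValueError(f"standard patch {p.label!r} must be spectrally flat")
        object.__setattr__(self, "patches", tuple(self.patches))

    @property
    def standards(self):
        return tuple(p for p in self.patches if p.standard_percent is not None)


def patch_grid(
    reflectances,
    patch_px: int = 24,
    margin_px: int = 4,
    columns: int | None = None,
    background: SpectralCurve | None = None,
    standard_percents=None,
) -> SyntheticScene:
    """Lay out reflectance spectra as a grid scene (standards flagged)."""
    reflectances = list(reflectances)
    standard_percents = list(standard_percents or [None] * len(reflectances))
    cols = columns or int(np.ceil(np.sqrt(len(reflectances))))
    rows = int(np.ceil(len(reflectances) / cols))
    cell = patch_px + margin_px
    shape = (rows * cell + margin_px, cols * cell + margin_px)
    patches = []
    for i, (refl, sp) in enumerate(zip(reflectances, standard_percents)):
        r, c = divmod(i, cols)
        patches.append(
            Patch(
                x0=margin_px + c * cell,
                y0=margin_px + r * cell,
                width=patch_px,
                height=patch_px,
                reflectance=refl,
                label=refl.name or f"patch-{i}",
                standard_percent=sp,
            )
        )
    illum = daylight_illuminant()
    return SyntheticScene(shape, tuple(patches), illum, background=background)


def standard_scene(percents=STANDARD_SET_PERCENT, patch_px: int = 24) -> SyntheticScene:
    """The 8-standard validation target: flat greys from 2% to 99%."""
    refl = [flat_reflectance(p) for p in percents]
    return patch_grid(refl, patch_px=patch_px, standard_percents=list(percents))


def render_scene(
    scene: SyntheticScene,
    camera: SyntheticCamera,
    exposure: float = 1.0,
    seed: int = 0,
    receptors: SensitivityBank | None = None,
    misalignment: dict | None = None,
):
    """Render a scene to per-channel 16-bit linear images plus ground truth.

    Per channel: each patch's quantum catch under the scene illuminant is
    scaled by exposure and gain, a veiling-glare offset added, Gaussian noise
    (SD = a + b*signal) applied, and the result quantized to uint16 with
    saturation.  Background (non-patch) pixels are dark (glare + noise only).
    *misalignment* maps channel name -> (dx, dy, scale) applied to the ideal
    image before noise, emulating camera movement between filter changes.

    Returns ``(images, truth)``: channel name -> LinearImage, and a dict with
    the ground-truth reflectance images per channel (von-Kries normalized
    camera quanta) plus, when *receptors* is given, normalized receptor
    catch images under the same illuminant.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    from .alignment import warp_channel

    rng = np.random.default_rng(seed)
    h, w = scene.shape
    cam_white = white_reference(camera.bank, scene.illuminant)
    images: dict[str, LinearImage] = {}
    truth: dict[str, np.ndarray] = {"camera": {}, "receptors": {}}

    rec_white = None
    if receptors is not None:
        rec_white = white_reference(receptors, scene.illuminant)
        for name in receptors.channel_names:
            truth["receptors"][name] = np.zeros((h, w))

    for ci, ch in enumerate(camera.channel_names):
        sens = camera.bank.curves[ci]
        if scene.background is not None:
            bg = cone_catch(sens, scene.background, scene.illuminant)
            ideal = np.full((h, w), bg * exposure * camera.gains[ci])
            refl_truth = np.full((h, w), bg / cam_white.quanta[ci])
        else:
            ideal = np.zeros((h, w))
            refl_truth = np.zeros((h, w))
        for p in scene.patches:
            catch = cone_catch(sens, p.reflectance, scene.illuminant)
            sl = np.s_[p.y0 : p.y0 + p.height, p.x0 : p.x0 + p.width]
            ideal[sl] = catch * exposure * camera.gains[ci]
            refl_truth[sl] = catch / cam_white.quanta[ci]
        if camera.gamma != 1.0:
            # nonlinearity control: distort the normalized response curve
            full = 65535.0
            ideal = full * (np.clip(ideal / full, 0, None) ** camera.gamma)
        if misalignment and ch in misalignment:
            dx, dy, scale = misalignment[ch]
            ideal = np.nan_to_num(warp_channel(ideal, dx, dy, scale), nan=0.0)
        signal = ideal + camera.glare_dn
        noisy = signal + rng.normal(0.0, camera.noise_a + camera.noise_b * signal)
        images[ch] = LinearImage(
            np.clip(np.round(noisy), 0, 65535).astype(np.uint16),
            channel_name=ch,
            exposure={"exposure": exposure},
        )
        truth["camera"][ch] = refl_truth

    if receptors is not None:
        for ri, rname in enumerate(receptors.channel_names):
            if scene.background is not None:
                bg = cone_catch(receptors.curves[ri], scene.background, scene.illuminant)
                plane = np.full((h, w), bg / rec_white.quanta[ri])
            else:
                plane = np.zeros((h, w))
            for p in scene.patches:
                catch = cone_catch(receptors.curves[ri], p.reflectance, scene.illuminant)
                sl = np.s_[p.y0 : p.y0 + p.height, p.x0 : p.x0 + p.width]
                plane[sl] = catch / rec_white.quanta[ri]
            truth["receptors"][rname] = plane
    return images, truth


def write_scene_project(
    scene: SyntheticScene,
    images: dict,
    directory,
    name: str = "synthetic",
    region_patches: bool = True,
) -> MspecProject:
    """Write rendered channels as 16-bit TIFFs plus a matching project file."""
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sources = {}
    for ch, img in images.items():
        fname = f"{name}_{ch}.tif"
        tifffile.imwrite(directory / fname, img.pixels)
        sources[ch] = fname
    standards = [
        StandardSelection(p.standard_percent, p.vertices()) for p in scene.standards
    ]
    from .images import Region

    regions = []
    if region_patches:
        regions = [
            Region(p.label, p.vertices())
            for p in scene.patches
            if p.standard_percent is None
        ]
    project = MspecProject(name=name, sources=sources, standards=standards, regions=regions)
    project.save(directory / f"{name}.mspec.json")
    return project


# ---------------------------------------------------------------------------
# Validation experiment: linearity


def linearity_experiment(
    camera: SyntheticCamera | None = None,
    exposures=(0.25, 0.5, 1.0),
    seed: int = 0,
    percents=STANDARD_SET_PERCENT,
    patch_px: int = 24,
) -> pd.DataFrame:
    """Photograph the standard set across exposures and test channel linearity.

    For each exposure the 8-standard scene is rendered and each standard's
    mean pixel value measured per channel.  To pool across exposures, each
    stated reflectance is multiplied by that photograph's pooled average
    standard pixel response (per channel), giving an expected value on the
    pixel scale; a single regression of observed means on expected values per
    channel then tests linearity within and between exposures.  Saturated
    standards (mean within 1% of full scale) are excluded with a warning.

    Returns a DataFrame with one row per channel: R², slope, n points.
    """
    if len(exposures) < 3:
        raise ValueError("need at least three exposures to span a dynamic range")
    camera = camera or default_camera()
    scene = standard_scene(percents, patch_px=patch_px)
    records = {ch: {"x": [], "y": []} for ch in camera.channel_names}
    rng = np.random.default_rng(seed)
    for exposure in exposures:
        images, _ = render_scene(scene, camera, exposure=exposure, seed=int(rng.integers(2**31)))
        for ch in camera.channel_names:
            px = images[ch].pixels
            means, used = [], []
            for p in scene.standards:
                m = float(px[p.y0 : p.y0 + p.height, p.x0 : p.x0 + p.width].mean())
                if m >= 0.99 * 65535:
                    warnings.warn(
                        f"standard {p.standard_percent}% saturated at exposure "
                        f"{exposure} in channel {ch}; excluded",
                        stacklevel=2,
                    )
                    continue
                means.append(m)
                used.append(p.standard_percent / 100.0)
            # pooled average standard response, normalized by the mean stated
            # reflectance of the standards pooled: the photograph's estimated
            # 100%-reflectance response, so exclusions do not bias the scale
            pooled = float(np.mean(means)) / float(np.mean(used))
            records[ch]["x"].extend(np.asarray(used) * pooled)
            records[ch]["y"].extend(means)
    rows = []
    for ch, d in records.items():
        x, y = np.asarray(d["x"]), np.asarray(d["y"])
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        r2 = 1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        rows.append({"channel": ch, "r_squared": float(r2), "slope": float(slope), "n": x.size})
    return pd.DataFrame(rows).set_index("channel")
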