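"""FFT bandpass granularity analysis of animal markings.

A pattern is decomposed into a geometric series of spatial-frequency bands
(pass sizes of 2, 4, ..., 512 px by default).  For each band the image is
bandpass filtered — an isotropic annulus in frequency space whose wavelength
bounds are the geometric midpoints to the adjacent band sizes — and the
band's "energy" is the standard deviation of the filtered image inside the
measured region.  The resulting energy spectrum describes marking size (the
dominant band), contrast (total energy) and diversity (how spread the energy
is across bands).  Comparing patterns between photographs requires images
rescaled to a common number of pixels per unit length first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import MultispectralStack, Region

__all__ = [
    "BandEnergySpectrum",
    "PatternStats",
    "default_band_sizes",
    "band_wavelength_bounds",
    "granularity_spectrum",
    "pattern_stats",
    "pattern_difference",
    "rescale_to_uniform",
]


@dataclass(frozen=True)
class BandEnergySpectrum:
    """Energies per spatial-frequency band for one region of one channel."""

    band_sizes_px: tuple
    energies: np.ndarray
    pixels_per_mm: float | None = None
    unreliable: tuple = ()  # band sizes larger than the region supports

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.band_sizes_px)
        e = np.asarray(self.energies, dtype=float)
        if len(sizes) < 2:
            raise ValueError("need at least two bands")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("band sizes must be strictly increasing")
        if e.size != len(sizes):
            raise ValueError("one energy per band required")
        if np.any(e < 0):
            raise ValueError("energies must be non-negative")
        object.__setattr__(self, "band_sizes_px", sizes)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "unreliable", tuple(self.unreliable))

    def compatible(self, other: "BandEnergySpectrum") -> bool:
        same_scale = (
            self.pixels_per_mm is None
            and other.pixels_per_mm is None
            or self.pixels_per_mm is not None
            and other.pixels_per_mm is not None
            and np.isclose(self.pixels_per_mm, other.pixels_per_mm)
        )
        return self.band_sizes_px == other.band_sizes_px and same_scale


@dataclass(frozen=True)
class PatternStats:
    """Descriptive statistics of a band-energy spectrum.

    ``diversity`` counts the bands holding more than half the dominant band's
    energy — a simple spread descriptor (1 = a single dominant marking size,
    larger = energy spread over many scales).
    """

    total_energy: float
    dominant_band_px: float
    dominant_proportion: float
    diversity: int
    defined: bool = True


def default_band_sizes(shape) -> tuple:
    """Octave-spaced pass sizes 2, 4, ... up to min(512, smallest image side)."""
    top = min(512, min(shape))
    sizes = []
    s = 2
    while s <= top:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        raise ValueError(f"image of shape {shape} too small for a band series")
    return tuple(sizes)


def band_wavelength_bounds(band_sizes) -> list:
    """(lo, hi] wavelength bounds per band: geometric midpoints to neighbours.

    The first band extends down by the same octave ratio below its size, the
    last up by the ratio above, so adjacent annuli tile frequency space
    without gap or overlap.
    """
    sizes = [float(s) for s in band_sizes]
    bounds = []
    for i, s in enumerate(sizes):
        lo = np.sqrt(sizes[i - 1] * s) if i > 0 else s / np.sqrt(sizes[1] / s)
        hi = np.sqrt(s * sizes[i + 1]) if i < len(sizes) - 1 else s * np.sqrt(s / sizes[i - 1])
        bounds.append((lo, hi))
    return bounds


def _annulus_mask(shape, lo_wavelength, hi_wavelength) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    r = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        wavelength = np.where(r > 0, 1.0 / np.maximum(r, 1e-300), np.inf)
    return (wavelength > lo_wavelength) & (wavelength <= hi_wavelength)


def granularity_spectrum(
    channel: np.ndarray,
    region: Region | np.ndarray | None = None,
    band_sizes=None,
    pixels_per_mm: float | None = None,
) -> BandEnergySpectrum:
    """Band energies of one channel inside a region.

    Pixels outside the region are replaced by the region mean before the
    transform (suppressing edge ringing from the region boundary); the energy
    of each band is the standard deviation of the bandpass-filtered image
    over in-region pixels only.  Bands whose pass size exceeds the region's
    smaller bounding-box side are still computed but flagged unreliable.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("granularity operates on a single 2-D channel")
    if band_sizes is None:
        band_sizes = default_band_sizes(img.shape)
    if region is None:
        mask = np.ones(img.shape, dtype=bool)
    elif isinstance(region, Region):
        mask = region.mask(img.shape)
    else:
        mask = np.asarray(region, dtype=bool)
    npix = int(mask.sum())
    if npix < 64:
        raise ValueError(f"region rasterizes to {npix} px; need >= 64")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    extent = min(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    unreliable = tuple(s for s in band_sizes if s > extent)

    filled = np.where(mask, img, img[mask].mean())
    spectrum = np.fft.fft2(filled)
    energies = []
    for lo, hi in band_wavelength_bounds(band_sizes):
        band = np.fft.ifft2(spectrum * _annulus_mask(img.shape, lo, hi)).real
        energies.append(float(band[mask].std()))
    return BandEnergySpectrum(tuple(band_sizes), np.array(energies), pixels_per_mm, unreliable)


def pattern_stats(spectrum: BandEnergySpectrum) -> PatternStats:
    """Summarize a band-energy spectrum (marking size, contrast, diversity).

    The dominant band is the energy argmax, ties broken toward the smaller
    band size.  An all-zero spectrum has no meaningful statistics and is
    returned flagged undefined.
    """
    e = spectrum.energies
    total = float(e.sum())
    if total == 0:
        return PatternStats(0.0, float("nan"), float("nan"), 0, defined=False)
    i = int(np.argmax(e))  # argmax returns the first (smallest-size) maximum
    half = e[i] / 2.0
    return PatternStats(
        total_energy=total,
        dominant_band_px=spectrum.band_sizes_px[i],
        dominant_proportion=float(e[i] / total),
        diversity=int(np.sum(e > half)),
    )


def pattern_difference(a: BandEnergySpectrum, b: BandEnergySpectrum) -> float:
    """Pairwise pattern difference: sum over bands of |energy_a - energy_b|.

    Symmetric, zero iff the spectra are equal; requires identical band sets
    and identical pixel scale (compare rescaled images only).
    """
    if not a.compatible(b):
        raise ValueError(
            f"spectra not comparable: bands {a.band_sizes_px} @ {a.pixels_per_mm} px/mm "
            f"vs {b.band_sizes_px} @ {b.pixels_per_mm} px/mm"
        )
    return float(np.abs(a.energies - b.energies).sum())


def rescale_to_uniform(stack: MultispectralStack, target_px_per_mm: float):
    """Bilinearly resample a stack to a target pixel scale.

    Pattern comparison across photographs requires a uniform number of pixels
    per unit length; the stack must carry a scale (from a scale bar).  Region
    polygons must be rescaled by the same factor (see ``Region.scaled``).
    Returns the rescaled stack and the scale factor applied.
    """
    from skimage.transform import rescale

    if stack.pixels_per_mm is None:
        raise ValueError("stack has no recorded scale; set a scale bar first")
    factor = target_px_per_mm / stack.pixels_per_mm
    if np.isclose(factor, 1.0):
        out = stack.with_channels(stack.channel_names, stack.data.copy())
        out.pixels_per_mm = target_px_per_mm
        return out, 1.0
    planes = [
        rescale(p.astype(float), factor, order=1, anti_aliasing=factor < 1, preserve_range=True)
        for p in stack.data
    ]
    out = stack.with_channels(stack.channel_names, np.stack(planes).astype(np.float32))
    out.pixels_per_mm = target_px_per_mm
    return out, factor
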