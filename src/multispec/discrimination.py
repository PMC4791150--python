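"""Receptor-noise-limited colour and luminance discrimination (JND).

In the receptor-noise-limited (RNL) model of colour discrimination, two
stimuli are compared through the log contrast of each receptor's quantum
catch, Δf_i = ln(q_i^a / q_i^b), and the perceptual distance ΔS weighs the
receptor-opponent differences against each receptor's noise e_i.  A distance
of 1 JND (just noticeable difference) is the nominal discrimination
threshold; values well above 1 indicate discriminable stimuli.

Noise can be given directly as a Weber fraction per receptor, or derived
from relative receptor abundances: e_i = ω_ref * sqrt(η_ref / η_i), so the
reference receptor (conventionally the most abundant, long-wave one) has the
stated Weber fraction.  The variant implemented is the log-linear receptor
signal with neural (intensity-independent) noise; the standard closed forms
for di-, tri- and tetrachromatic systems are used:

    dichromat:   ΔS² = (Δf1 − Δf2)² / (e1² + e2²)
    trichromat:  ΔS² = [e1²(Δf3−Δf2)² + e2²(Δf3−Δf1)² + e3²(Δf2−Δf1)²]
                       / [(e1 e2)² + (e1 e3)² + (e2 e3)²]
    tetrachromat: the analogous ratio with all six pairwise opponent terms
                  over all four triple noise products.

Achromatic (luminance) contrast uses a single channel: ΔS = |ln(a/b)| / ω.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import ConeCatchVector

__all__ = [
    "ReceptorNoiseSpec",
    "JNDResult",
    "receptor_contrasts",
    "chromatic_jnd",
    "achromatic_jnd",
    "jnd_matrix",
]


@dataclass(frozen=True)
class ReceptorNoiseSpec:
    """Per-receptor noise for the RNL model."""

    receptor_names: tuple
    noise: np.ndarray  # e_i per receptor

    def __post_init__(self) -> None:
        names = tuple(self.receptor_names)
        e = np.asarray(self.noise, dtype=float)
        if e.size != len(names):
            raise ValueError("one noise value per receptor required")
        if np.any(e <= 0) or not np.all(np.isfinite(e)):
            raise ValueError("receptor noise values must be positive and finite")
        object.__setattr__(self, "receptor_names", names)
        object.__setattr__(self, "noise", e)

    @classmethod
    def from_abundances(
        cls,
        receptor_names,
        abundances,
        weber_fraction: float,
        reference: str | None = None,
    ) -> "ReceptorNoiseSpec":
        """Derive noise from relative receptor abundances η_i.

        The *reference* receptor (default: the most abundant) is assigned the
        given Weber fraction; other receptors get e_i = ω * sqrt(η_ref / η_i).
        """
        names = tuple(receptor_names)
        eta = np.asarray(abundances, dtype=float)
        if np.any(eta <= 0):
            raise ValueError("abundances must be positive")
        if weber_fraction <= 0:
            raise ValueError("Weber fraction must be positive")
        ref_idx = int(np.argmax(eta)) if reference is None else names.index(reference)
        e = weber_fraction * np.sqrt(eta[ref_idx] / eta)
        return cls(names, e)


@dataclass(frozen=True)
class JNDResult:
    """A discrimination distance in JND units."""

    delta_s: float
    kind: str  # "chromatic" | "achromatic"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_s < 0:
            raise ValueError("ΔS must be non-negative")


def receptor_contrasts(a: ConeCatchVector, b: ConeCatchVector) -> np.ndarray:
    """Log receptor contrasts Δf_i = ln(q_i^a / q_i^b); antisymmetric in (a, b)."""
    if a.receptor_names != b.receptor_names:
        raise ValueError(f"receptor sets differ: {a.receptor_names} vs {b.receptor_names}")
    for vec, label in ((a, "first"), (b, "second")):
        bad = np.flatnonzero(vec.quanta <= 0)
        if bad.size:
            raise ValueError(
                f"{label} stimulus has non-positive catch in receptor "
                f"{vec.receptor_names[bad[0]]!r}; log contrast undefined"
            )
    return np.log(a.quanta / b.quanta)


def chromatic_jnd(delta_f, noise: ReceptorNoiseSpec) -> JNDResult:
    """Chromatic RNL distance for 2-4 receptors (closed forms above)."""
    f = np.asarray(delta_f, dtype=float)
    e = noise.noise
    if f.size != e.size:
        raise ValueError("Δf length must match the noise spec's receptor count")
    n = f.size
    if n < 2 or n > 4:
        raise ValueError(f"chromatic RNL model implemented for 2-4 receptors, got {n}")
    if n == 2:
        ds = abs(f[0] - f[1]) / np.sqrt(e[0] ** 2 + e[1] ** 2)
    elif n == 3:
        num = (
            e[0] ** 2 * (f[2] - f[1]) ** 2
            + e[1] ** 2 * (f[2] - f[0]) ** 2
            + e[2] ** 2 * (f[1] - f[0]) ** 2
        )
        den = (e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2
        ds = np.sqrt(num / den)
    else:
        num = (
            (e[0] * e[1]) ** 2 * (f[3] - f[2]) ** 2
            + (e[0] * e[2]) ** 2 * (f[3] - f[1]) ** 2
            + (e[0] * e[3]) ** 2 * (f[2] - f[1]) ** 2
            + (e[1] * e[2]) ** 2 * (f[3] - f[0]) ** 2
            + (e[1] * e[3]) ** 2 * (f[2] - f[0]) ** 2
            + (e[2] * e[3]) ** 2 * (f[1] - f[0]) ** 2
        )
        den = (
            (e[0] * e[1] * e[2]) ** 2
            + (e[0] * e[1] * e[3]) ** 2
            + (e[0] * e[2] * e[3]) ** 2
            + (e[1] * e[2] * e[3]) ** 2
        )
        ds = np.sqrt(num / den)
    return JNDResult(float(ds), "chromatic", {"receptors": list(noise.receptor_names)})


def achromatic_jnd(a_lum: float, b_lum: float, weber_fraction: float) -> JNDResult:
    """Achromatic (luminance) contrast: ΔS = |ln(a/b)| / ω; symmetric."""
    if a_lum <= 0 or b_lum <= 0:
        raise ValueError("luminances must be positive")
    if weber_fraction <= 0:
        raise ValueError("Weber fraction must be positive")
    ds = abs(np.log(a_lum / b_lum)) / weber_fraction
    return JNDResult(float(ds), "achromatic", {"weber_fraction": weber_fraction})


def jnd_matrix(samples: dict, noise: ReceptorNoiseSpec):
    """Pairwise chromatic JND matrix over named cone-catch samples.

    *samples* maps label -> ConeCatchVector; returns a symmetric DataFrame.
    """
    import pandas as pd

    labels = list(samples)
    m = np.zeros((len(labels), len(labels)))
    for i, la in enumerate(labels):
        for j in range(i + 1, len(labels)):
            df = receptor_contrasts(samples[la], samples[labels[j]])
            m[i, j] = m[j, i] = chromatic_jnd(df, noise).delta_s
    return pd.DataFrame(m, index=labels, columns=labels)
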