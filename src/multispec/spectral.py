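"""Spectral curves, illuminants, reflectance libraries and cone-catch quanta.

Everything downstream of the camera — normalization targets, visual-system
mapping, discrimination modelling — is driven by spectra sampled on a common
1 nm wavelength grid.  A photoreceptor's (or camera channel's) quantum catch
for a surface is the sensitivity-weighted sum of reflectance times illuminant
radiance over wavelength,

    L_c = sum_lambda  l(lambda) * Q(lambda) * I(lambda),

and catches are made illumination-independent by von Kries chromatic
adaptation: dividing each receptor's catch by its catch for a white
reference under the same illuminant, L_n = L_c / L_wr, so that any
spectrally flat (grey) surface yields equal values in every receptor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCurve",
    "SensitivityBank",
    "ReflectanceLibrary",
    "ConeCatchVector",
    "resample_to_grid",
    "cone_catch",
    "catch_vector",
    "white_reference",
    "von_kries_normalize",
    "read_spectra_csv",
    "write_spectra_csv",
]


@dataclass(frozen=True)
class SpectralCurve:
    """A spectral quantity sampled every 1 nm on a closed integer range.

    Parameters
    ----------
    start_nm : int
        Wavelength of the first sample, in nanometres.
    values : array-like
        One non-negative finite value per nanometre.
    name : str
        Label (e.g. ``"vR"``, ``"D65"``, ``"lw"``).
    emissive : bool
        Set for fluorescent/emissive reflectance spectra, whose values may
        exceed 1 on the 0-1 reflectance scale.
    """

    start_nm: int
    values: np.ndarray
    name: str = ""
    emissive: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"curve {self.name!r} contains non-finite values")
        if np.any(vals < 0):
            raise ValueError(f"curve {self.name!r} contains negative values")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "start_nm", int(self.start_nm))

    @property
    def end_nm(self) -> int:
        return self.start_nm + self.values.size - 1

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + 1)

    def __len__(self) -> int:
        return self.values.size

    def same_grid(self, other: "SpectralCurve") -> bool:
        return self.start_nm == other.start_nm and len(self) == len(other)

    @classmethod
    def from_samples(
        cls,
        wavelengths_nm,
        values,
        name: str = "",
        emissive: bool = False,
    ) -> "SpectralCurve":
        """Build a 1 nm curve from irregularly sampled (wavelength, value) pairs.

        Values between samples are linearly interpolated; the grid spans the
        integer range covered by the samples.  A sample pair (0, 1) at 400 and
        402 nm therefore yields 0.5 at 401 nm.
        """
        wl = np.asarray(wavelengths_nm, dtype=float)
        vals = np.asarray(values, dtype=float)
        if wl.size != vals.size or wl.size < 2:
            raise ValueError("need at least two (wavelength, value) samples")
        order = np.argsort(wl)
        wl, vals = wl[order], vals[order]
        start = int(np.ceil(wl[0]))
        end = int(np.floor(wl[-1]))
        grid = np.arange(start, end + 1)
        return cls(start, np.interp(grid, wl, vals), name=name, emissive=emissive)


def resample_to_grid(curve: SpectralCurve, start_nm: int, end_nm: int) -> SpectralCurve:
    """Re-express *curve* on the closed grid [start_nm, end_nm].

    Values inside the overlap are copied (the curve is already on a 1 nm
    grid, so no interpolation error is introduced); wavelengths outside the
    curve's measured range are zero-filled rather than extrapolated, since
    sensitivities and emission spectra are physically zero outside their band.
    """
    if end_nm < start_nm:
        raise ValueError("end_nm must be >= start_nm")
    lo = max(start_nm, curve.start_nm)
    hi = min(end_nm, curve.end_nm)
    if hi < lo:
        raise ValueError(
            f"requested grid [{start_nm}, {end_nm}] nm does not overlap "
            f"curve {curve.name!r} on [{curve.start_nm}, {curve.end_nm}] nm"
        )
    out = np.zeros(end_nm - start_nm + 1)
    out[lo - start_nm : hi - start_nm + 1] = curve.values[
        lo - curve.start_nm : hi - curve.start_nm + 1
    ]
    return SpectralCurve(start_nm, out, name=curve.name, emissive=curve.emissive)


@dataclass(frozen=True)
class SensitivityBank:
    """An ordered set of sensitivity curves sharing one wavelength grid.

    Channel names follow the filter-prefix/sensor-suffix convention used for
    multispectral photography: a lower-case prefix for the filter ('v'
    visible, 'u' UV) and an upper-case suffix for the sensor channel, e.g.
    ``vR, vG, vB, uB, uR``.
    """

    curves: tuple
    channel_names: tuple

    def __post_init__(self) -> None:
        curves = tuple(self.curves)
        names = tuple(self.channel_names)
        if len(curves) != len(names):
            raise ValueError("one name per curve required")
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique, got {names}")
        if not curves:
            raise ValueError("bank must contain at least one curve")
        first = curves[0]
        for c in curves[1:]:
            if not c.same_grid(first):
                raise ValueError(
                    f"curve {c.name!r} grid [{c.start_nm},{c.end_nm}] differs "
                    f"from [{first.start_nm},{first.end_nm}]"
                )
        object.__setattr__(self, "curves", curves)
        object.__setattr__(self, "channel_names", names)

    def __len__(self) -> int:
        return len(self.curves)

    @property
    def start_nm(self) -> int:
        return self.curves[0].start_nm

    @property
    def end_nm(self) -> int:
        return self.curves[0].end_nm

    def curve(self, name: str) -> SpectralCurve:
        try:
            return self.curves[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r} in bank {self.channel_names}") from None

    def resampled(self, start_nm: int, end_nm: int) -> "SensitivityBank":
        return SensitivityBank(
            tuple(resample_to_grid(c, start_nm, end_nm) for c in self.curves),
            self.channel_names,
        )


@dataclass(frozen=True)
class ReflectanceLibrary:
    """A collection of reflectance spectra (0-1 scale) on one shared grid."""

    spectra: tuple
    source_tags: tuple = ()

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        if not spectra:
            raise ValueError("library must contain at least one spectrum")
        tags = tuple(self.source_tags) or ("",) * len(spectra)
        if len(tags) != len(spectra):
            raise ValueError("one source tag per spectrum required")
        first = spectra[0]
        for s in spectra[1:]:
            if not s.same_grid(first):
                raise ValueError("all library spectra must share one grid")
        for s in spectra:
            if not s.emissive and np.any(s.values > 1.0 + 1e-9):
                raise ValueError(
                    f"spectrum {s.name!r} exceeds 1 but is not flagged emissive"
                )
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "source_tags", tags)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def start_nm(self) -> int:
        return self.spectra[0].start_nm

    @property
    def end_nm(self) -> int:
        return self.spectra[0].end_nm


@dataclass(frozen=True)
class ConeCatchVector:
    """Quantum catches for a set of receptors (raw L_c or von-Kries L_n)."""

    receptor_names: tuple
    quanta: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        q = np.asarray(self.quanta, dtype=float)
        names = tuple(self.receptor_names)
        if q.ndim != 1 or q.size != len(names):
            raise ValueError("one quantum per receptor required")
        if np.any(q < 0) or not np.all(np.isfinite(q)):
            raise ValueError("quanta must be finite and non-negative")
        object.__setattr__(self, "quanta", q)
        object.__setattr__(self, "receptor_names", names)


def cone_catch(
    sensitivity: SpectralCurve,
    reflectance: SpectralCurve,
    illuminant: SpectralCurve,
) -> float:
    """Quantum catch: sum over wavelength of sensitivity x reflectance x illuminant.

    All three curves must share an identical 1 nm grid (resample first); the
    sum runs inclusively over the shared range and is exactly linear in each
    argument.
    """
    for other, label in ((reflectance, "reflectance"), (illuminant, "illuminant")):
        if not sensitivity.same_grid(other):
            raise ValueError(
                f"{label} grid [{other.start_nm},{other.end_nm}] does not match "
                f"sensitivity grid [{sensitivity.start_nm},{sensitivity.end_nm}]"
            )
    return float(np.sum(sensitivity.values * reflectance.values * illuminant.values))


def catch_vector(
    bank: SensitivityBank,
    reflectance: SpectralCurve,
    illuminant: SpectralCurve,
) -> ConeCatchVector:
    """Raw catches of every channel in *bank* for one surface."""
    q = [cone_catch(c, reflectance, illuminant) for c in bank.curves]
    return ConeCatchVector(bank.channel_names, np.array(q), normalized=False)


def white_reference(bank: SensitivityBank, illuminant: SpectralCurve) -> ConeCatchVector:
    """Catches for an ideal 100%-reflectance (flat white) surface."""
    flat = SpectralCurve(bank.start_nm, np.ones(bank.end_nm - bank.start_nm + 1), "white")
    return catch_vector(bank, flat, illuminant)


def von_kries_normalize(
    raw: ConeCatchVector, white_ref: ConeCatchVector
) -> ConeCatchVector:
    """von Kries chromatic adaptation: L_n = L_c / L_wr per receptor.

    The white reference itself normalizes to exactly 1 in every receptor, and
    any grey surface yields equal values across receptors.
    """
    if raw.receptor_names != white_ref.receptor_names:
        raise ValueError(
            f"receptor sets differ: {raw.receptor_names} vs {white_ref.receptor_names}"
        )
    zero = np.flatnonzero(white_ref.quanta <= 0)
    if zero.size:
        bad = raw.receptor_names[zero[0]]
        raise ValueError(f"white reference catch is zero in receptor {bad!r}")
    return ConeCatchVector(
        raw.receptor_names, raw.quanta / white_ref.quanta, normalized=True
    )


# ---------------------------------------------------------------------------
# CSV interchange: first column wavelength (nm), one column per curve,
# header row of names, '#' comment lines tolerated.

def read_spectra_csv(path_or_buffer, emissive: bool = False) -> list:
    """Read spectral curves from CSV, interpolating each to the 1 nm grid."""
    df = pd.read_csv(path_or_buffer, comment="#")
    if df.shape[1] < 2:
        raise ValueError("spectra CSV needs a wavelength column plus >=1 curve column")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    curves = []
    for col in df.columns[1:]:
        curves.append(
            SpectralCurve.from_samples(
                wl, df[col].to_numpy(dtype=float), name=str(col), emissive=emissive
            )
        )
    return curves


def write_spectra_csv(path, curves) -> None:
    """Write curves sharing one grid as a wavelength-first CSV."""
    curves = list(curves)
    first = curves[0]
    for c in curves[1:]:
        if not c.same_grid(first):
            raise ValueError("all curves must share one grid to share a CSV")
    df = pd.DataFrame({"wavelength_nm": first.wavelengths})
    for c in curves:
        df[c.name or f"curve{len(df.columns)}"] = c.values
    df.to_csv(path, index=False)
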