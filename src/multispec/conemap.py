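"""Polynomial mapping from camera channel space to photoreceptor cone catches.

A camera's spectral sensitivities never coincide with an animal's receptor
sensitivities, so calibrated camera responses are device-dependent.  Because
natural reflectance spectra are smooth, a low-order polynomial regression can
map von-Kries-normalized camera catches to receptor catches with very little
error.  For three channels R, G, B the term sets are, without and with
third-order products and squares:

    L = a1*R + a2*G + a3*B + a4*RG + a5*RB + a6*GB
    L = a1*R + a2*G + a3*B + a4*RG + a5*RB + a6*GB + a7*RGB + a8*R^2 + a9*G^2 + a10*B^2

with no intercept (a zero camera response must map to a zero catch).  Models
are trained on a library of reflectance spectra under a chosen illuminant:
for every spectrum, camera and receptor quanta are computed and normalized
against a flat white reference, and each receptor is fitted by ordinary
least squares on the expanded term matrix.  Optional backward stepwise
simplification removes terms that do not pay for their degrees of freedom,
scored by AIC or BIC (BIC being the more conservative, removing more terms).
Training R-squared is reported per receptor to judge mapping quality; it is
computed against the uncentered total sum of squares, consistent with the
absent intercept.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import MultispectralStack
from .spectral import (
    ReflectanceLibrary,
    SensitivityBank,
    SpectralCurve,
    catch_vector,
    von_kries_normalize,
    white_reference,
)

__all__ = [
    "PolynomialTermSet",
    "ConeMapModel",
    "expand_terms",
    "build_training_table",
    "fit_cone_map",
    "apply_cone_map",
]


@dataclass(frozen=True)
class PolynomialTermSet:
    """The multiset-of-channels terms of a no-intercept polynomial map.

    ``interaction_level`` 1 keeps single channels only; 2 adds all distinct
    pairwise products; 3 adds all distinct triple products.  ``include_squares``
    adds each channel's square.  Terms are represented as sorted tuples of
    channel names, e.g. ``("R",)``, ``("G", "R")``, ``("R", "R")``.
    """

    channels: tuple
    interaction_level: int = 2
    include_squares: bool = False

    def __post_init__(self) -> None:
        chans = tuple(self.channels)
        if len(set(chans)) != len(chans) or not chans:
            raise ValueError("channels must be unique and non-empty")
        if self.interaction_level not in (1, 2, 3):
            raise ValueError("interaction level must be 1, 2 or 3")
        object.__setattr__(self, "channels", chans)

    @property
    def terms(self) -> tuple:
        terms = [(c,) for c in self.channels]
        if self.interaction_level >= 2:
            terms += [tuple(sorted(p)) for p in itertools.combinations(self.channels, 2)]
        if self.interaction_level >= 3:
            terms += [tuple(sorted(t)) for t in itertools.combinations(self.channels, 3)]
        if self.include_squares:
            terms += [(c, c) for c in self.channels]
        return tuple(terms)


def term_label(term) -> str:
    return "*".join(term)


def expand_terms(channel_values, terms) -> np.ndarray:
    """Evaluate each term (a product of channel values) for one sample.

    *channel_values* maps channel name to a scalar or array; *terms* is a
    ``PolynomialTermSet`` or an explicit term tuple.  Returns the stacked term
    values in term order (the design row/column for the regression).
    """
    term_list = terms.terms if isinstance(terms, PolynomialTermSet) else tuple(terms)
    cols = []
    for term in term_list:
        val = None
        for ch in term:
            if ch not in channel_values:
                raise KeyError(f"term {term_label(term)!r} needs missing channel {ch!r}")
            v = np.asarray(channel_values[ch], dtype=float)
            val = v if val is None else val * v
        cols.append(val)
    return np.stack(cols, axis=-1)


def build_training_table(
    camera: SensitivityBank,
    receptors: SensitivityBank,
    illuminant: SpectralCurve,
    library: ReflectanceLibrary,
) -> pd.DataFrame:
    """Paired camera/receptor quanta for every spectrum in the library.

    Camera and receptor sensitivities are resampled to the library grid (with
    zero fill outside their measured band), quanta computed per spectrum and
    von-Kries normalized against a flat white reference under the same
    illuminant.  Columns are the camera channels followed by the receptor
    channels; one row per spectrum.
    """
    if len(camera) < len(receptors):
        raise ValueError(
            f"{len(camera)} camera channels cannot map to {len(receptors)} receptors: "
            "the number of camera channels must be equal to or greater than the "
            "number of receptors"
        )
    start, end = library.start_nm, library.end_nm
    for bank, label in ((camera, "camera"), (receptors, "receptor")):
        if bank.end_nm < start or bank.start_nm > end:
            raise ValueError(
                f"{label} sensitivities [{bank.start_nm},{bank.end_nm}] nm do not "
                f"overlap the spectra library [{start},{end}] nm"
            )
    cam = camera.resampled(start, end)
    rec = receptors.resampled(start, end)
    illum = _match_grid(illuminant, start, end)
    cam_white = white_reference(cam, illum)
    rec_white = white_reference(rec, illum)

    rows = np.empty((len(library), len(cam) + len(rec)))
    for i, spectrum in enumerate(library.spectra):
        c = von_kries_normalize(catch_vector(cam, spectrum, illum), cam_white)
        r = von_kries_normalize(catch_vector(rec, spectrum, illum), rec_white)
        rows[i] = np.concatenate([c.quanta, r.quanta])
    cols = list(cam.channel_names) + list(rec.channel_names)
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["camera_channels"] = list(cam.channel_names)
    df.attrs["receptor_channels"] = list(rec.channel_names)
    return df


def _match_grid(curve: SpectralCurve, start: int, end: int) -> SpectralCurve:
    from .spectral import resample_to_grid

    if curve.start_nm == start and curve.end_nm == end:
        return curve
    return resample_to_grid(curve, start, end)


@dataclass
class ConeMapModel:
    """Per-receptor surviving terms, coefficients and training R-squared."""

    camera_channels: list
    receptor_channels: list
    terms: dict  # receptor -> tuple of term tuples
    coefficients: dict  # receptor -> ndarray aligned with terms
    r_squared: dict  # receptor -> float in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec, r2 in self.r_squared.items():
            if not (0.0 <= r2 <= 1.0 + 1e-12):
                raise ValueError(f"receptor {rec!r} R² {r2} outside [0, 1]")

    def predict(self, channel_values: dict) -> dict:
        """Receptor quanta for given camera channel values (scalars or arrays)."""
        out = {}
        for rec in self.receptor_channels:
            x = expand_terms(channel_values, self.terms[rec])
            out[rec] = x @ self.coefficients[rec]
        return out

    def to_dict(self) -> dict:
        return {
            "camera_channels": list(self.camera_channels),
            "receptor_channels": list(self.receptor_channels),
            "terms": {r: [list(t) for t in ts] for r, ts in self.terms.items()},
            "coefficients": {r: np.asarray(c).tolist() for r, c in self.coefficients.items()},
            "r_squared": {r: float(v) for r, v in self.r_squared.items()},
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ConeMapModel":
        return cls(
            list(d["camera_channels"]),
            list(d["receptor_channels"]),
            {r: tuple(tuple(t) for t in ts) for r, ts in d["terms"].items()},
            {r: np.asarray(c, dtype=float) for r, c in d["coefficients"].items()},
            dict(d["r_squared"]),
            dict(d.get("provenance", {})),
        )

    @classmethod
    def load(cls, path) -> "ConeMapModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _ols_no_intercept(X: np.ndarray, y: np.ndarray):
    """Least squares through the origin; returns (coefs, rss, uncentered R²)."""
    coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    rss = float(resid @ resid)
    tss = float(y @ y)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coefs, rss, min(max(r2, 0.0), 1.0)


def _criterion(rss: float, n: int, k: int, kind: str) -> float:
    # Gaussian log-likelihood up to constants; penalty 2k (AIC) or k ln n (BIC)
    rss = max(rss, 1e-300)
    penalty = 2.0 * k if kind == "AIC" else np.log(n) * k
    return n * np.log(rss / n) + penalty


def fit_cone_map(
    table: pd.DataFrame,
    camera_channels=None,
    receptor_channels=None,
    terms: PolynomialTermSet | None = None,
    simplification: str | None = None,
    provenance: dict | None = None,
) -> ConeMapModel:
    """Fit the per-receptor polynomial map on a training table.

    *simplification* is ``None``, ``"AIC"`` or ``"BIC"``: backward greedy
    stepwise removal, repeatedly dropping the term whose removal most improves
    the criterion until no removal improves it (ties broken by term order).
    Rank-deficient term matrices have their aliased terms dropped with a
    warning before fitting.
    """
    camera_channels = list(camera_channels or table.attrs.get("camera_channels") or [])
    receptor_channels = list(receptor_channels or table.attrs.get("receptor_channels") or [])
    if not camera_channels or not receptor_channels:
        raise ValueError("camera and receptor channel lists are required")
    if simplification not in (None, "AIC", "BIC"):
        raise ValueError("simplification must be None, 'AIC' or 'BIC'")
    if terms is None:
        terms = PolynomialTermSet(tuple(camera_channels), interaction_level=2)
    term_list = list(terms.terms)
    n = len(table)
    if n < len(term_list):
        raise ValueError(
            f"{n} training rows cannot identify {len(term_list)} terms"
        )
    if n < 2 * len(term_list):
        warnings.warn(
            f"only {n} training rows for {len(term_list)} terms; fits may be "
            "poorly constrained (prefer >=2 rows per term)",
            stacklevel=2,
        )

    values = {c: table[c].to_numpy() for c in camera_channels}
    X_full = expand_terms(values, term_list)
    # drop aliased (linearly dependent) columns once, for all receptors
    keep = _independent_columns(X_full)
    if len(keep) < len(term_list):
        dropped = [term_label(term_list[i]) for i in range(len(term_list)) if i not in keep]
        warnings.warn(f"dropping aliased terms {dropped} (rank-deficient design)", stacklevel=2)
        term_list = [term_list[i] for i in keep]
        X_full = X_full[:, keep]

    out_terms, out_coefs, out_r2 = {}, {}, {}
    for rec in receptor_channels:
        y = table[rec].to_numpy()
        active = list(range(len(term_list)))
        coefs, rss, r2 = _ols_no_intercept(X_full, y)
        if simplification:
            current = _criterion(rss, n, len(active), simplification)
            improved = True
            while improved and len(active) > 1:
                improved = False
                best = None
                for pos in range(len(active)):
                    trial = active[:pos] + active[pos + 1 :]
                    _, rss_t, _ = _ols_no_intercept(X_full[:, trial], y)
                    crit = _criterion(rss_t, n, len(trial), simplification)
                    if crit < current and (best is None or crit < best[0]):
                        best = (crit, pos)
                if best is not None:
                    current, pos = best
                    active = active[:pos] + active[pos + 1 :]
                    improved = True
            coefs, rss, r2 = _ols_no_intercept(X_full[:, active], y)
        out_terms[rec] = tuple(term_list[i] for i in active)
        out_coefs[rec] = coefs
        out_r2[rec] = r2
    prov = dict(provenance or {})
    prov.setdefault("simplification", simplification or "none")
    prov.setdefault("interaction_level", terms.interaction_level)
    prov.setdefault("include_squares", terms.include_squares)
    return ConeMapModel(camera_channels, receptor_channels, out_terms, out_coefs, out_r2, prov)


def _independent_columns(X: np.ndarray) -> list:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return sorted(piv[:rank].tolist())


def apply_cone_map(stack: MultispectralStack, model: ConeMapModel) -> MultispectralStack:
    """Convert a normalized reflectance stack to per-pixel cone-catch images.

    Negative reflectances (possible after an intercept-corrected
    normalization) are floored at zero before term expansion, since quantum
    catches are non-negative; each flooring event is logged.  Output values
    may exceed 1 for fluorescent or specular surfaces.
    """
    import logging

    if not stack.normalized:
        raise ValueError("stack must be normalized to reflectance before cone mapping")
    missing = set(model.camera_channels) - set(stack.channel_names)
    if missing:
        raise ValueError(f"stack lacks model channels {sorted(missing)}")
    values = {}
    for ch in model.camera_channels:
        plane = stack.channel(ch).astype(np.float64)
        neg = int(np.sum(plane < 0))
        if neg:
            logging.getLogger("multispec.conemap").info(
                "floored %d negative pixels in channel %s before cone mapping", neg, ch
            )
            plane = np.maximum(plane, 0.0)
        values[ch] = plane
    preds = model.predict(values)
    data = np.stack([preds[r] for r in model.receptor_channels]).astype(np.float32)
    out = stack.with_channels(model.receptor_channels, data, normalized=True)
    out.provenance["cone_map"] = {
        "receptors": list(model.receptor_channels),
        "r_squared": dict(model.r_squared),
    }
    return out
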