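"""Reflectance normalization against grey standards.

Two photographs taken under different illumination cannot be compared until
each channel is rescaled against a spectrally flat (grey) standard of known
reflectance.  With a single standard of stated reflectance S (percent) whose
mean linear pixel value is G, a pixel V_linear normalizes as

    V_norm = V_linear * (S / 100) * (65535 / G)

on the 16-bit output scale, i.e. a line through the origin.  With two or more
standards an ordinary least-squares line of reflectance on pixel value is
used instead (the same relation plus an intercept), which corrects the raised
black point caused by optical veiling glare.  With one standard only, the
dark point can alternatively be estimated from the channel histogram by
assuming the lowest 0.5% of pixels have a reflectance of 0.5%.

Internally reflectance is carried on a 0-1 scale (1.0 = 100%); 65535 is the
100% level only when exporting 16-bit previews, which keeps the 32-bit
arithmetic scale-free.  Normalized values above 1 (shiny or fluorescent
surfaces) and below 0 (possible with an intercept) are preserved, never
clipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import MspecProject, MultispectralStack, polygon_mask

logger = logging.getLogger("multispec.normalization")

__all__ = [
    "StandardMeasurement",
    "NormalizationModel",
    "fit_normalization",
    "fit_project_standards",
    "apply_normalization",
    "estimate_dark_point",
    "sequential_normalize",
    "LOW_FIT_R2",
]

#: below this R-squared a multi-standard linearisation triggers a warning
LOW_FIT_R2 = 0.98


@dataclass(frozen=True)
class StandardMeasurement:
    """One grey standard: stated reflectance and its mean pixel value per channel."""

    reflectance_percent: float
    mean_pixel: dict  # channel -> mean linear DN

    def __post_init__(self) -> None:
        if not (0 < self.reflectance_percent <= 100):
            raise ValueError("stated reflectance must be in (0, 100] percent")


@dataclass
class NormalizationModel:
    """Per-channel affine map from linear pixel value to 0-1 reflectance."""

    channel_names: list
    slopes: np.ndarray  # reflectance per DN
    intercepts: np.ndarray
    r_squared: np.ndarray | None = None  # recorded when >=3 standards
    method: str = "single"  # single | multi | histogram-dark-point | sequential

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if np.any(self.slopes <= 0):
            raise ValueError("normalization slopes must be positive")
        if self.method == "single" and np.any(self.intercepts != 0):
            raise ValueError("single-standard model must pass through the origin")

    def predict(self, values, channel: str) -> np.ndarray:
        i = self.channel_names.index(channel)
        return np.asarray(values, dtype=float) * self.slopes[i] + self.intercepts[i]

    def to_16bit_scale(self, reflectance) -> np.ndarray:
        """Express 0-1 reflectance on the 16-bit export scale (65535 = 100%)."""
        return np.asarray(reflectance, dtype=float) * 65535.0

    def to_dict(self) -> dict:
        return {
            "channel_names": list(self.channel_names),
            "slopes": self.slopes.tolist(),
            "intercepts": self.intercepts.tolist(),
            "r_squared": None if self.r_squared is None else np.asarray(self.r_squared).tolist(),
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationModel":
        r2 = d.get("r_squared")
        return cls(
            list(d["channel_names"]),
            np.asarray(d["slopes"]),
            np.asarray(d["intercepts"]),
            None if r2 is None else np.asarray(r2),
            d.get("method", "multi"),
        )


def fit_normalization(standards, channel_names=None, method: str = "auto") -> NormalizationModel:
    """Fit the pixel-to-reflectance line from one or more grey standards.

    One standard gives the through-the-origin relation; two or more give an
    ordinary least-squares regression of reflectance on pixel value per
    channel (prediction is then direct).  With three or more standards the
    fit R-squared is recorded and a warning is emitted when any channel's
    linearisation fit falls below 0.98 — the model is still returned.
    """
    standards = list(standards)
    if not standards:
        raise ValueError("at least one grey standard is required")
    if channel_names is None:
        channel_names = list(standards[0].mean_pixel)
    for s in standards:
        missing = set(channel_names) - set(s.mean_pixel)
        if missing:
            raise ValueError(f"standard at {s.reflectance_percent}% lacks channels {sorted(missing)}")

    refl = np.array([s.reflectance_percent / 100.0 for s in standards])
    pix = np.array([[s.mean_pixel[c] for c in channel_names] for s in standards])  # (n, C)
    n = len(standards)

    if n == 1 or method == "single":
        g = pix[0]
        if np.any(g <= 0):
            raise ValueError("standard mean pixel values must be positive")
        return NormalizationModel(list(channel_names), refl[0] / g, np.zeros_like(g), None, "single")

    slopes, intercepts, r2s = [], [], []
    for j, ch in enumerate(channel_names):
        x = pix[:, j]
        if np.unique(x).size < n:
            raise ValueError(
                f"channel {ch!r}: two standards share the same mean pixel value; "
                "cannot fit a line"
            )
        order = np.argsort(refl)
        if np.any(np.diff(x[order]) <= 0):
            warnings.warn(
                f"channel {ch!r}: pixel values do not increase with stated "
                "reflectance; check standard selections [code=NONMONOTONE_STANDARDS]",
                stacklevel=2,
            )
        slope, intercept = np.polyfit(x, refl, 1)
        if slope <= 0:
            raise ValueError(f"channel {ch!r}: fitted slope is not positive")
        slopes.append(slope)
        intercepts.append(intercept)
        if n >= 3:
            pred = slope * x + intercept
            ss_res = float(np.sum((refl - pred) ** 2))
            ss_tot = float(np.sum((refl - refl.mean()) ** 2))
            r2s.append(1.0 - ss_res / ss_tot)
    r2 = np.array(r2s) if r2s else None
    if r2 is not None and np.any(r2 < LOW_FIT_R2):
        bad = [c for c, v in zip(channel_names, r2) if v < LOW_FIT_R2]
        warnings.warn(
            f"linearisation fit below {LOW_FIT_R2} in channels {bad} "
            f"(min R²={r2.min():.4f}) [code=LOW_LINEARISATION_FIT]",
            stacklevel=2,
        )
        logger.warning("low linearisation fit: %s", dict(zip(channel_names, r2)))
    return NormalizationModel(list(channel_names), np.array(slopes), np.array(intercepts), r2, "multi")


def fit_project_standards(stack: MultispectralStack, project: MspecProject) -> NormalizationModel:
    """Measure a project's standard selections on the raw stack and fit."""
    if not project.standards:
        raise ValueError(f"project {project.name!r} has no grey-standard selections")
    h, w = stack.shape
    measurements = []
    for sel in project.standards:
        mask = polygon_mask(sel.vertices, (h, w))
        if not mask.any():
            raise ValueError(
                f"standard ({sel.reflectance_percent}%) selection lies outside the image"
            )
        means = {ch: float(stack.channel(ch)[mask].mean()) for ch in stack.channel_names}
        measurements.append(StandardMeasurement(sel.reflectance_percent, means))
    method = project.normalization_method
    if method == "histogram-dark-point":
        if len(measurements) != 1:
            raise ValueError("histogram dark-point estimation uses exactly one standard")
        channels = {ch: stack.channel(ch) for ch in stack.channel_names}
        return estimate_dark_point(channels, measurements[0])
    return fit_normalization(
        measurements, stack.channel_names, "single" if method == "single" else "auto"
    )


def apply_normalization(stack: MultispectralStack, model: NormalizationModel) -> MultispectralStack:
    """Apply the per-channel affine map; output is 32-bit float reflectance.

    Values above the 100% level and negative values are preserved untouched.
    """
    if list(model.channel_names) != list(stack.channel_names):
        raise ValueError(
            f"model channels {model.channel_names} do not match stack "
            f"channels {stack.channel_names}"
        )
    out = (
        stack.data.astype(np.float64) * model.slopes[:, None, None]
        + model.intercepts[:, None, None]
    ).astype(np.float32)
    new = stack.with_channels(stack.channel_names, out, normalized=True)
    new.provenance["normalization"] = model.to_dict()
    return new


def estimate_dark_point(channel_pixels: dict, standard: StandardMeasurement) -> NormalizationModel:
    """One-standard normalization with a histogram-estimated dark point.

    The dark anchor of each channel is the mean of the pixels at or below the
    0.5th percentile of that channel's histogram (the absolute lowest pixel is
    deliberately not used alone, being dominated by noise), and is assigned a
    reflectance of 0.5%.  The line is then drawn through (dark anchor, 0.5%)
    and (standard mean, stated reflectance), recovering an intercept that
    compensates additive veiling glare.
    """
    channels = list(channel_pixels)
    slopes, intercepts = [], []
    for ch in channels:
        pix = np.asarray(channel_pixels[ch], dtype=float).ravel()
        if pix.size < 200:
            raise ValueError(
                f"channel {ch!r}: need >=200 pixels to populate the 0.5% "
                f"histogram tail, got {pix.size}"
            )
        cut = np.percentile(pix, 0.5)
        dark = float(pix[pix <= cut].mean())
        g = float(standard.mean_pixel[ch])
        s = standard.reflectance_percent / 100.0
        if dark >= g:
            raise ValueError(
                f"channel {ch!r}: dark anchor ({dark:.1f}) is not below the "
                f"standard mean ({g:.1f}); cannot estimate a dark point"
            )
        slope = (s - 0.005) / (g - dark)
        slopes.append(slope)
        intercepts.append(0.005 - slope * dark)
    return NormalizationModel(channels, np.array(slopes), np.array(intercepts), None, "histogram-dark-point")


def sequential_normalize(
    target_project: MspecProject,
    standard_project: MspecProject,
    target_dir=None,
    standard_dir=None,
):
    """Normalize a target photograph against standards in a separate photograph.

    For subjects that cannot share the frame with a standard, the standard is
    photographed separately under identical lighting and camera settings; the
    caller asserts that identity.  The model fitted on the standard photograph
    is applied to the target stack.  If lighting differed (e.g. the standard
    frame was twice as bright) recovered reflectances are biased by the
    inverse factor — the method's documented failure mode.

    Returns ``(model, target_stack)`` where the model's method tag is
    ``"sequential"``.
    """
    from .images import build_stack

    t_chans = list(target_project.sources)
    s_chans = list(standard_project.sources)
    if set(t_chans) != set(s_chans):
        raise ValueError(
            f"channel sets differ between target {sorted(t_chans)} and "
            f"standard {sorted(s_chans)} projects"
        )
    raw_standard = build_stack(
        _without_standards(standard_project), base_dir=standard_dir
    )
    model = fit_project_standards(raw_standard, standard_project)
    model.method = "sequential"
    # reorder to the target's channel order
    idx = [model.channel_names.index(c) for c in t_chans]
    model = NormalizationModel(
        t_chans,
        model.slopes[idx],
        model.intercepts[idx],
        None if model.r_squared is None else model.r_squared[idx],
        "sequential",
    )
    target_stack = build_stack(target_project, base_dir=target_dir, model=model)
    return model, target_stack


def _without_standards(project: MspecProject) -> MspecProject:
    clone = MspecProject.from_dict(project.to_dict())
    clone.standards = []
    return clone
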