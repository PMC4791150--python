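"""Multispectral stacks, project files, regions of interest and linear ingestion.

A multispectral image is a stack of co-registered channels covering different
wavebands (e.g. visible RGB plus UV exposures).  Source images must be linear
with respect to radiance: either 16-bit linear TIFF/PNG, or camera RAW decoded
through an external decoder configured for linear, non-white-balanced 16-bit
output.  Linearity is a contract of the decoder, not re-derived here.

Rather than storing huge 32-bit stacks, a small plain-text project file (JSON)
records everything needed to rebuild the stack deterministically from its
source images: the channel map, grey-standard selections with their stated
reflectances, alignment offsets and scales, a scale-bar record and named
regions of interest.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "LinearImage",
    "MultispectralStack",
    "Region",
    "StandardSelection",
    "MspecProject",
    "load_linear_image",
    "build_stack",
    "set_scale_bar",
    "polygon_mask",
    "measure_region",
    "measure_regions",
]

_RAW_SUFFIXES = {".nef", ".cr2", ".dng", ".arw", ".raf", ".orf", ".rw2"}
_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass(frozen=True)
class LinearImage:
    """A single linear 16-bit channel as decoded from a source file."""

    pixels: np.ndarray  # uint16, 2-D
    channel_name: str = ""
    source: str = ""
    exposure: dict | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint16:
            raise ValueError(
                f"linear images must be 16-bit; got dtype {px.dtype} "
                f"({px.dtype.itemsize * 8}-bit)"
            )
        if px.ndim != 2:
            raise ValueError("a LinearImage holds a single 2-D channel")
        object.__setattr__(self, "pixels", px)


@dataclass
class MultispectralStack:
    """Named stack of 32-bit floating-point channels with shared geometry.

    Values are on a 0-1 reflectance scale once normalized (1.0 = the 100%
    reflectance level); they may exceed 1 for shiny, fluorescent or emissive
    surfaces and are never clipped by any processing step.
    """

    channel_names: list
    data: np.ndarray  # float32, (C, H, W)
    pixels_per_mm: float | None = None
    normalized: bool = False
    offsets: dict = field(default_factory=dict)  # channel -> (dx, dy, scale)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, H, W)")

    @property
    def shape(self):
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None

    def with_channels(self, names, data, normalized=None) -> "MultispectralStack":
        return MultispectralStack(
            list(names),
            data,
            pixels_per_mm=self.pixels_per_mm,
            normalized=self.normalized if normalized is None else normalized,
            offsets=dict(self.offsets),
            provenance=dict(self.provenance),
        )


@dataclass(frozen=True)
class Region:
    """A labelled polygonal region of interest, in pixel coordinates.

    Coordinates are 0-based, origin top-left, x along columns and y along
    rows; the pixel at (row r, column c) has its centre at (x=c, y=r).
    Regions sharing a ``pool`` group are unified (overlap counted once)
    before measurement.
    """

    label: str
    vertices: tuple  # ((x, y), ...)
    pool: str | None = None

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError(f"region {self.label!r} needs >=3 vertices")
        if not self.label:
            raise ValueError("region label must be non-empty")
        object.__setattr__(self, "vertices", verts)

    def mask(self, shape) -> np.ndarray:
        return polygon_mask(self.vertices, shape)

    def scaled(self, factor: float) -> "Region":
        return Region(
            self.label,
            tuple((x * factor, y * factor) for x, y in self.vertices),
            self.pool,
        )


def polygon_mask(vertices, shape) -> np.ndarray:
    """Rasterize a polygon: pixel centres inside under the even-odd rule.

    Vectorized crossing-number test: a pixel centre is inside if a ray cast
    in +x crosses the boundary an odd number of times.
    """
    h, w = shape
    verts = np.asarray(vertices, dtype=float)
    ys = np.arange(h, dtype=float)[:, None]
    xs = np.arange(w, dtype=float)[None, :]
    inside = np.zeros((h, w), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never cross a horizontal ray boundary
        # half-open in y so shared vertices are counted once
        spans = (ys >= min(y1, y2)) & (ys < max(y1, y2))
        x_at = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= spans & (xs < x_at)
    return inside


@dataclass(frozen=True)
class StandardSelection:
    """A grey-standard selection: stated reflectance plus its polygon."""

    reflectance_percent: float
    vertices: tuple

    def __post_init__(self) -> None:
        if not (0 < self.reflectance_percent <= 100):
            raise ValueError("stated reflectance must be in (0, 100] percent")
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError("standard selection needs >=3 vertices")
        object.__setattr__(self, "vertices", verts)


@dataclass
class MspecProject:
    """Everything needed to rebuild a normalized, aligned stack from sources.

    ``sources`` maps channel name -> relative path[:channel-selector], e.g.
    ``{"vR": "vis.tif:R", "uB": "uv.tif:B"}``.  Paths are resolved relative
    to the project file's directory so projects travel with their images.
    """

    name: str
    sources: dict
    standards: list = field(default_factory=list)  # [StandardSelection]
    offsets: dict = field(default_factory=dict)  # channel -> [dx, dy, scale]
    scale_bar: dict | None = None  # {"p1": [x,y], "p2": [x,y], "length_mm": L}
    regions: list = field(default_factory=list)  # [Region]
    normalization_method: str = "auto"  # auto | single | multi | histogram-dark-point

    @property
    def pixels_per_mm(self) -> float | None:
        if self.scale_bar is None:
            return None
        (x1, y1), (x2, y2) = self.scale_bar["p1"], self.scale_bar["p2"]
        return math.hypot(x2 - x1, y2 - y1) / self.scale_bar["length_mm"]

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sources": dict(self.sources),
            "standards": [
                {"reflectance_percent": s.reflectance_percent, "vertices": list(map(list, s.vertices))}
                for s in self.standards
            ],
            "offsets": {k: list(v) for k, v in self.offsets.items()},
            "scale_bar": self.scale_bar,
            "regions": [
                {"label": r.label, "vertices": list(map(list, r.vertices)), "pool": r.pool}
                for r in self.regions
            ],
            "normalization_method": self.normalization_method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MspecProject":
        return cls(
            name=d["name"],
            sources=dict(d["sources"]),
            standards=[
                StandardSelection(s["reflectance_percent"], tuple(map(tuple, s["vertices"])))
                for s in d.get("standards", [])
            ],
            offsets={k: tuple(v) for k, v in d.get("offsets", {}).items()},
            scale_bar=d.get("scale_bar"),
            regions=[
                Region(r["label"], tuple(map(tuple, r["vertices"])), r.get("pool"))
                for r in d.get("regions", [])
            ],
            normalization_method=d.get("normalization_method", "auto"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "MspecProject":
        return cls.from_dict(json.loads(Path(path).read_text()))


def set_scale_bar(project: MspecProject, p1, p2, physical_length_mm: float) -> MspecProject:
    """Record a scale-bar line of known physical length; stores px/mm."""
    if tuple(p1) == tuple(p2):
        raise ValueError("scale bar endpoints coincide (zero-length line)")
    if physical_length_mm <= 0:
        raise ValueError("physical length must be positive")
    project.scale_bar = {"p1": list(p1), "p2": list(p2), "length_mm": float(physical_length_mm)}
    return project


# ---------------------------------------------------------------------------
# Linear image ingestion


def load_linear_image(path, channel_selector=None, channel_name: str = "") -> LinearImage:
    """Load one linear 16-bit channel from a TIFF/PNG (or RAW via rawpy).

    No gamma, white balance, rescale or clipping is applied; an 8-bit (or any
    non-16-bit) file is rejected.  For multi-channel files *channel_selector*
    picks a plane: an integer index or one of ``"R"``, ``"G"``, ``"B"``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _RAW_SUFFIXES:
        arr = _decode_raw(path)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")

    arr = np.asarray(arr)
    if arr.dtype != np.uint16:
        raise ValueError(
            f"{path.name}: expected 16-bit linear pixels, got {arr.dtype.itemsize * 8}-bit "
            f"({arr.dtype})"
        )
    if arr.ndim == 3:
        if channel_selector is None:
            raise ValueError(f"{path.name} has {arr.shape[-1]} channels; a selector is required")
        idx = _CHANNEL_INDEX.get(channel_selector, channel_selector)
        if not isinstance(idx, int) or not (0 <= idx < arr.shape[-1]):
            raise ValueError(f"{path.name} has no channel {channel_selector!r}")
        arr = arr[..., idx]
    elif arr.ndim == 2:
        if channel_selector not in (None, 0):
            raise ValueError(f"{path.name} is single-channel; cannot select {channel_selector!r}")
    else:
        raise ValueError(f"{path.name}: unsupported image dimensionality {arr.ndim}")
    return LinearImage(arr, channel_name=channel_name, source=str(path))


def _decode_raw(path: Path) -> np.ndarray:
    """Delegate RAW decoding to rawpy/libraw, configured for linearity:
    no gamma, no auto-brightening, white balance disabled, 16-bit output."""
    try:
        import rawpy
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "RAW ingestion requires the optional 'rawpy' package "
            "(pip install multispec[raw]); alternatively decode to 16-bit "
            "linear TIFF externally"
        ) from exc
    with rawpy.imread(str(path)) as raw:  # pragma: no cover
        return raw.postprocess(
            gamma=(1, 1),
            no_auto_bright=True,
            use_camera_wb=False,
            use_auto_wb=False,
            output_bps=16,
        )


# ---------------------------------------------------------------------------
# Stack construction


def build_stack(project: MspecProject, base_dir=None, model=None) -> MultispectralStack:
    """Rebuild the normalized 32-bit stack a project describes.

    Channels are loaded, converted to 32-bit floating point, aligned with the
    project's stored (dx, dy, scale) per channel, and normalized to
    reflectance using the project's grey-standard selections (or an explicit
    *model*, e.g. from a sequential-method standard photograph).  The whole
    procedure is deterministic: the same project always yields the identical
    stack.
    """
    from . import normalization as _norm
    from .alignment import warp_channel

    base = Path(base_dir) if base_dir is not None else Path(".")
    names = list(project.sources)
    planes = []
    for ch in names:
        spec = project.sources[ch]
        rel, _, selector = spec.partition(":")
        src = base / rel
        if not src.exists():
            raise FileNotFoundError(f"channel {ch!r}: missing source image {src}")
        img = load_linear_image(src, selector or None, channel_name=ch)
        plane = img.pixels.astype(np.float32)
        dx, dy, scale = project.offsets.get(ch, (0.0, 0.0, 1.0))
        if (dx, dy, scale) != (0.0, 0.0, 1.0):
            plane = warp_channel(plane, dx, dy, scale, fill=np.nan)
            plane = np.nan_to_num(plane, nan=0.0).astype(np.float32)
        planes.append(plane)
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ValueError(f"channel dimensions differ after alignment: {sorted(shapes)}")
    data = np.stack(planes)
    stack = MultispectralStack(
        names,
        data,
        pixels_per_mm=project.pixels_per_mm,
        normalized=False,
        offsets=dict(project.offsets),
        provenance={"project": project.name},
    )
    if model is None:
        if not project.standards:
            return stack
        model = _norm.fit_project_standards(stack, project)
    return _norm.apply_normalization(stack, model)


# ---------------------------------------------------------------------------
# Region measurement


def measure_region(stack: MultispectralStack, region: Region) -> "pd.DataFrame":
    """Per-channel mean, sd and pixel count over one region."""
    return measure_regions(stack, [region], pool=False)


def measure_regions(stack: MultispectralStack, regions, pool: bool = True):
    """Measure regions; those sharing a pool group are unified first.

    Returns a tidy DataFrame with one row per region (or pooled group) per
    channel: label, channel, mean, sd (population), n pixels.
    """
    import pandas as pd

    h, w = stack.shape
    groups: dict[str, np.ndarray] = {}
    for r in regions:
        m = r.mask((h, w))
        key = r.pool if (pool and r.pool) else r.label
        groups[key] = groups.get(key, np.zeros((h, w), bool)) | m
    rows = []
    for label, mask in groups.items():
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"region {label!r} contains no pixel centres")
        for ch in stack.channel_names:
            vals = stack.channel(ch)[mask]
            rows.append(
                {
                    "region": label,
                    "channel": ch,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std()),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
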