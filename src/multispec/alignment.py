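"""Exhaustive coarse-to-fine channel alignment by sum-of-absolute-differences.

Visible and UV exposures of one scene are taken through different filters, so
the camera is often nudged between frames and non-achromatic lenses must be
refocused, slightly zooming the image.  Feature-based registration is
unreliable between UV-blue and visible-blue channels, so alignment here is
exhaustive: the moving channel is shifted over a 3x3 grid of candidate
offsets at a given spacing (e.g. 128 px), the search re-centres on the best
candidate, the spacing halves, and so on until it reaches one pixel.  A scale
search wraps this: the moving image is rescaled about its centre (initially
by 1%), each candidate scale is fully re-aligned, the search continues in an
improving direction and halves its step otherwise.

The matching cost is the mean absolute pixel difference over the overlapping
region (the mean, rather than a raw sum, so that large offsets with small
overlaps are not artificially favoured).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AlignmentResult",
    "warp_channel",
    "sad_cost",
    "align_translation",
    "align_with_scale",
    "brute_force_translation",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of an alignment search: offset, scale, final cost and trace."""

    dx: int
    dy: int
    scale: float
    cost: float
    trace: tuple = ()  # ((dx, dy, scale, cost), ...) in evaluation order

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def warp_channel(img: np.ndarray, dx: float, dy: float, scale: float = 1.0, fill=np.nan) -> np.ndarray:
    """Scale *img* about its centre then translate by (dx, dy).

    dx moves the content along +x (columns), dy along +y (rows).  Bilinear
    interpolation; pixels drawn from outside the source are set to *fill*
    (NaN by default, marking them invalid for cost computation).
    """
    img = np.asarray(img, dtype=float)
    if scale == 1.0 and float(dx).is_integer() and float(dy).is_integer():
        return _integer_shift(img, int(dx), int(dy), fill)
    cy = (img.shape[0] - 1) / 2.0
    cx = (img.shape[1] - 1) / 2.0
    # output coord -> input coord: in = (out - d - c)/s + c
    matrix = np.array([1.0 / scale, 1.0 / scale])
    offset = np.array([cy - (cy + dy) / scale, cx - (cx + dx) / scale])
    return ndimage.affine_transform(
        img, matrix, offset=offset, order=1, mode="constant", cval=fill
    )


def _integer_shift(img: np.ndarray, dx: int, dy: int, fill) -> np.ndarray:
    out = np.full_like(img, fill, dtype=float)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ysrc = slice(max(-dy, 0), min(h - dy, h))
    xsrc = slice(max(-dx, 0), min(w - dx, w))
    if ys.start < ys.stop and xs.start < xs.stop:
        out[ys, xs] = img[ysrc, xsrc]
    return out


def sad_cost(fixed, moving, dx, dy, scale: float = 1.0, roi=None) -> float:
    """Mean absolute difference between *fixed* and the warped *moving* channel.

    The moving channel is scaled about its centre by *scale* and shifted by
    (dx, dy); the cost averages |difference| over pixels where both images
    are defined (optionally restricted to a boolean *roi* mask on the fixed
    image), so overlap size does not bias the comparison.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(f"channel shapes differ: {fixed.shape} vs {moving.shape}")
    warped = warp_channel(moving, dx, dy, scale, fill=np.nan)
    valid = ~np.isnan(warped)
    if roi is not None:
        valid &= np.asarray(roi, dtype=bool)
    if not valid.any():
        raise ValueError(f"no overlap between channels at offset ({dx}, {dy}), scale {scale}")
    return float(np.mean(np.abs(fixed[valid] - warped[valid])))


def _cost_on_warped(fixed, warped_moving, dx, dy, roi) -> float:
    shifted = _integer_shift(warped_moving, dx, dy, np.nan)
    valid = ~np.isnan(shifted)
    if roi is not None:
        valid &= roi
    if not valid.any():
        raise ValueError(f"no overlap at offset ({dx}, {dy})")
    return float(np.mean(np.abs(fixed[valid] - shifted[valid])))


def align_translation(
    fixed,
    moving,
    start_offset: int = 128,
    roi=None,
    scale: float = 1.0,
    _trace=None,
) -> AlignmentResult:
    """Coarse-to-fine 3x3 translation search with offset halving.

    At each level the nine candidate offsets spaced by the current step
    around the incumbent are evaluated, the search re-centres on the best
    (ties broken deterministically toward the smaller displacement), and the
    step halves; the last level uses a spacing of one pixel.  *start_offset*
    must be a positive power of two; it is reduced with a warning when the
    images are smaller than twice its size.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(f"channel shapes differ: {fixed.shape} vs {moving.shape}")
    if start_offset < 1 or (start_offset & (start_offset - 1)):
        raise ValueError("start_offset must be a positive power of two")
    limit = min(fixed.shape)
    while start_offset > 1 and limit < 2 * start_offset:
        start_offset //= 2
        warnings.warn(
            f"images smaller than twice the start offset; reduced to {start_offset}",
            stacklevel=2,
        )
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)

    warped = warp_channel(moving, 0, 0, scale, fill=np.nan) if scale != 1.0 else moving
    trace = _trace if _trace is not None else []
    seen: dict[tuple, float] = {}

    def cost_at(dx, dy):
        key = (dx, dy)
        if key not in seen:
            seen[key] = _cost_on_warped(fixed, warped, dx, dy, roi)
            trace.append((dx, dy, scale, seen[key]))
        return seen[key]

    best = (0, 0)
    best_cost = cost_at(0, 0)
    step = start_offset
    while step >= 1:
        candidates = [
            (best[0] + sx * step, best[1] + sy * step)
            for sy in (-1, 0, 1)
            for sx in (-1, 0, 1)
        ]
        scored = []
        for dx, dy in candidates:
            try:
                scored.append((cost_at(dx, dy), abs(dx) + abs(dy), (dx, dy)))
            except ValueError:
                continue  # candidate with no overlap is not viable
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        best_cost, _, best = scored[0]
        if step == 1:
            break
        step //= 2
    return AlignmentResult(best[0], best[1], scale, best_cost, tuple(trace))


def align_with_scale(
    fixed,
    moving,
    initial_scale_step: float = 0.01,
    start_offset: int = 128,
    roi=None,
    min_step: float = 0.001,
) -> AlignmentResult:
    """Joint scale + translation search by hill climbing on the scale factor.

    Starting at unit scale, the search tries scale +/- step (each candidate
    scale is fully re-aligned in translation); when an improving direction is
    found it keeps stepping that way, otherwise the step halves, terminating
    once the step falls below *min_step* (0.001).  Ties prefer the scale
    closer to 1.
    """
    if not (0 < initial_scale_step <= 0.1):
        raise ValueError("initial scale step must be in (0, 0.1]")
    trace: list = []
    cache: dict[float, AlignmentResult] = {}

    def aligned(s: float) -> AlignmentResult:
        s = round(s, 10)
        if s not in cache:
            cache[s] = align_translation(
                fixed, moving, start_offset=start_offset, roi=roi, scale=s, _trace=trace
            )
        return cache[s]

    current = 1.0
    best = aligned(current)
    step = initial_scale_step
    while step >= min_step:
        options = []
        for s in (current + step, current - step):
            if s <= 0:
                continue
            r = aligned(s)
            options.append((r.cost, abs(s - 1.0), s, r))
        options.sort(key=lambda t: (t[0], t[1]))
        if options and options[0][0] < best.cost:
            _, _, current, best = options[0]
            # keep moving in the improving direction at the same step
        else:
            step /= 2
    return AlignmentResult(best.dx, best.dy, best.scale, best.cost, tuple(trace))


def brute_force_translation(fixed, moving, window: int, roi=None, scale: float = 1.0) -> AlignmentResult:
    """Exhaustive search over every integer offset in [-window, window]^2.

    Intended for small images: the optional fallback when the hierarchical
    search might stall on periodic texture, and the reference the fast search
    is validated against.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    warped = warp_channel(moving, 0, 0, scale, fill=np.nan) if scale != 1.0 else moving
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
    trace = []
    best = None
    for dy in range(-window, window + 1):
        for dx in range(-window, window + 1):
            try:
                c = _cost_on_warped(fixed, warped, dx, dy, roi)
            except ValueError:
                continue
            trace.append((dx, dy, scale, c))
            key = (c, abs(dx) + abs(dy), (dx, dy))
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("no offset in the window produced any overlap")
    c, _, (dx, dy) = best
    return AlignmentResult(dx, dy, scale, c, tuple(trace))
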