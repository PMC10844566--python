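"""Background correction, display LUT, and temporal projection.

Uneven illumination is removed with the rolling-ball filter: imagine a ball
rolled everywhere beneath the intensity surface; the envelope it traces is
the background. Mathematically this is the grayscale morphological opening
of the frame by a spherical-cap structuring function of radius ``r`` —
anti-extensive (background <= frame), increasing, and idempotent. The
sliding-paraboloid variant replaces the cap with a paraboloid of the same
apex curvature, ``h(d) = d^2 / (2 r)``, whose unbounded sides make it usable
when intensities are much larger than the object scale.

The radius should exceed the largest genuine structure (here, the largest
astrocyte soma) so that cells are not mistaken for background.

``slice_sum`` collapses the movie along time into a per-pixel sum, the
projection on which ROIs are placed: every active cell contributes to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .stack_io import ImageStack

__all__ = [
    "BackgroundParams",
    "Projection",
    "ball_profile",
    "paraboloid_profile",
    "estimate_background",
    "subtract_background",
    "apply_spectrum_lut",
    "slice_sum",
]

# Out-of-footprint marker for the structuring function: a depth so large the
# offset can never win the min/max. Kept finite to avoid inf-inf arithmetic.
_BIG = 1e30


@dataclass
class BackgroundParams:
    """Rolling-ball / sliding-paraboloid background settings.

    radius
        Ball (or paraboloid apex-curvature) radius in pixels; must exceed
        the largest foreground structure.
    method
        ``"rolling_ball"`` or ``"sliding_paraboloid"``.
    clamp_negative
        Clip corrected values below 0 (exact opening leaves only
        floating-point dust below 0).
    allow_downsample
        Enable the speed path (block-shrink, open, enlarge) for radii > 20.
        Off in any exactness-critical comparison.
    """

    radius: float
    method: Literal["rolling_ball", "sliding_paraboloid"] = "rolling_ball"
    clamp_negative: bool = True
    allow_downsample: bool = True

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.method not in ("rolling_ball", "sliding_paraboloid"):
            raise ValueError(f"unknown background method {self.method!r}")


@dataclass
class Projection:
    """Per-pixel temporal sum of a stack (the 'slice sum' z-projection)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("projection must be 2-D")


def ball_profile(radius: float) -> np.ndarray:
    """Spherical-cap depth below the apex, ``r - sqrt(r^2 - d^2)``.

    Returns a (2R+1, 2R+1) array of depths; offsets outside the ball
    footprint are marked with a huge depth so they never participate.
    """
    R = int(np.ceil(radius))
    yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
    d2 = (yy * yy + xx * xx).astype(np.float64)
    depth = np.full(d2.shape, _BIG)
    inside = d2 <= radius * radius
    depth[inside] = radius - np.sqrt(radius * radius - d2[inside])
    return depth


def paraboloid_profile(radius: float, max_depth: float) -> np.ndarray:
    """Paraboloid depth ``d^2 / (2 r)``, truncated where it exceeds ``max_depth``.

    The apex curvature matches the ball of the same radius. Depths beyond the
    frame's dynamic range cannot influence the opening, so the support is cut
    there (``max_depth`` should be at least frame max - frame min).
    """
    if max_depth <= 0:
        max_depth = 1.0
    R = int(np.ceil(np.sqrt(2.0 * radius * max_depth))) + 1
    yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
    d2 = (yy * yy + xx * xx).astype(np.float64)
    depth = d2 / (2.0 * radius)
    depth[depth > max_depth] = _BIG
    return depth


def _structure(frame: np.ndarray, params: BackgroundParams) -> np.ndarray:
    if params.method == "rolling_ball":
        return ball_profile(params.radius)
    span = float(frame.max() - frame.min())
    return paraboloid_profile(params.radius, span)


def _opening(frame: np.ndarray, depth: np.ndarray) -> np.ndarray:
    # Opening by the structuring function S = -depth:
    #   erosion  e(x) = min_y f(x+y) + depth(y)   (apex field of the ball)
    #   dilation b(x) = max_y e(x-y) - depth(y)   (envelope traced by the cap)
    # Out-of-image samples behave as +inf for the erosion and -inf for the
    # dilation, i.e. the ball near a border rests on in-image samples only.
    structure = -depth
    eroded = ndimage.grey_erosion(
        frame, structure=structure, mode="constant", cval=_BIG
    )
    opened = ndimage.grey_dilation(
        eroded, structure=structure, mode="constant", cval=-_BIG
    )
    return np.minimum(opened, frame)  # exact up to FP dust; enforce <= frame


def _shrink_factor(radius: float) -> int:
    if radius <= 20:
        return 1
    if radius <= 30:
        return 2
    if radius <= 100:
        return 4
    return 8


def estimate_background(frame: np.ndarray, params: BackgroundParams) -> np.ndarray:
    """Estimate the illumination background of one frame.

    Exact grayscale opening by the chosen structuring element. For radii
    > 20 (and ``allow_downsample``) the frame is block-min shrunk, opened at
    the reduced radius, and bilinearly enlarged — the classical speed
    approximation; the result is still clipped to <= frame.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    if not (params.radius > 0):
        raise ValueError("radius must be > 0")

    s = _shrink_factor(params.radius) if params.allow_downsample else 1
    if s == 1:
        return _opening(frame, _structure(frame, params))

    from skimage.measure import block_reduce
    from skimage.transform import resize

    small = block_reduce(frame, (s, s), np.min, cval=frame.max())
    small_params = BackgroundParams(
        radius=params.radius / s,
        method=params.method,
        clamp_negative=params.clamp_negative,
        allow_downsample=False,
    )
    small_bg = _opening(small, _structure(small, small_params))
    bg = resize(
        small_bg, frame.shape, order=1, mode="edge", anti_aliasing=False
    )
    return np.minimum(bg, frame)


def subtract_background(stack: ImageStack, params: BackgroundParams) -> ImageStack:
    """Per-frame background subtraction over a whole stack.

    Each frame's background is estimated independently (no temporal
    smoothing) and subtracted; with ``clamp_negative`` the output is
    clipped at 0 so the stack invariants hold exactly.
    """
    out = np.empty(stack.frames.shape, dtype=np.float64)
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        out[t] = frame - estimate_background(frame, params)
    if params.clamp_negative:
        np.clip(out, 0.0, None, out=out)
    return ImageStack(
        out,
        stack.frame_interval,
        bit_depth=stack.bit_depth,
        name=f"{stack.name}_bgsub" if stack.name else "bgsub",
    )


def apply_spectrum_lut(
    frame: np.ndarray, low: float | None = None, high: float | None = None
) -> np.ndarray:
    """Render a frame through the ROYGBIV spectrum LUT (display only).

    Intensities <= ``low`` map to pure red, >= ``high`` to violet, with hue
    increasing monotonically red -> orange -> yellow -> green -> blue ->
    indigo -> violet in between. Defaults anchor at the 1st/99th intensity
    percentiles. Returns an (H, W, 3) uint8 RGB image; never used in
    quantification.
    """
    from matplotlib.colors import hsv_to_rgb

    frame = np.asarray(frame, dtype=np.float64)
    if low is None:
        low = float(np.percentile(frame, 1))
    if high is None:
        high = float(np.percentile(frame, 99))
        if high <= low:  # flat image: any anchors are as good as any other
            high = low + 1.0
    if low >= high:
        raise ValueError(f"LUT anchors require low < high, got {low} >= {high}")

    tnorm = np.clip((frame - low) / (high - low), 0.0, 1.0)
    hsv = np.stack(
        [0.75 * tnorm, np.ones_like(tnorm), np.ones_like(tnorm)], axis=-1
    )  # hue 0 = red ... 0.75 = violet
    return (hsv_to_rgb(hsv) * 255).round().astype(np.uint8)


def slice_sum(stack: ImageStack) -> Projection:
    """Sum the movie along time: values(r, c) = sum_t frames(t, r, c).

    Accumulated in int64 for integer stacks (exact up to 10^6 frames of
    16-bit data) and float64 otherwise.
    """
    acc_dtype = np.int64 if np.issubdtype(stack.frames.dtype, np.integer) else np.float64
    return Projection(stack.frames.sum(axis=0, dtype=acc_dtype))
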