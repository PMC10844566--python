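"""Circular ROIs and per-ROI fluorescence traces.

One ROI is a labeled disc placed over one cell body. Coordinates are
0-based pixels with ``(cx, cy) = (column, row)``; a pixel belongs to the
disc iff its *center* lies inside, ``(c - cx)^2 + (r - cy)^2 <= radius^2``
(ImageJ's default mask semantics, so results are bit-reproducible; no
partial-area weighting). Radius 0 selects exactly the center pixel.

A trace is the per-frame mean intensity over the mask — ImageJ's "mean gray
value" — on the stack's time base. ``normalize_dff`` converts to relative
change dF/F0 against a percentile baseline.

The canonical ROI exchange format is CSV with header ``label,cx,cy,radius``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stack_io import ImageStack

__all__ = [
    "CircleRoi",
    "Trace",
    "load_rois",
    "save_rois",
    "roi_mask",
    "extract_trace",
    "extract_traces",
    "normalize_dff",
    "traces_to_table",
]


@dataclass(frozen=True)
class CircleRoi:
    """Labeled circular region: center (cx=column, cy=row), radius in pixels."""

    label: str
    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"ROI {self.label!r}: radius must be >= 0")


@dataclass
class Trace:
    """Per-ROI intensity versus time.

    ``values[t]`` is the mean (or summed) mask intensity of frame ``t``;
    ``normalized`` marks dF/F0 traces so downstream labels axes correctly.
    """

    roi_label: str
    values: np.ndarray
    frame_interval: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval


def load_rois(
    path: str | os.PathLike, image_shape: tuple[int, int] | None = None
) -> list[CircleRoi]:
    """Load ROIs from a ``label,cx,cy,radius`` CSV, preserving file order.

    Duplicate labels are rejected (naming the duplicates); malformed rows
    raise with their line number. When ``image_shape`` is given, centers are
    validated against the image bounds.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return []
    required = ["label", "cx", "cy", "radius"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path!r}: ROI CSV is missing columns {missing}")

    rois: list[CircleRoi] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            roi = CircleRoi(
                label=str(row["label"]),
                cx=float(row["cx"]),
                cy=float(row["cy"]),
                radius=float(row["radius"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path!r} line {line_no}: malformed ROI row: {exc}") from exc
        rois.append(roi)

    labels = [r.label for r in rois]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"{path!r}: duplicate ROI labels: {dupes}")

    if image_shape is not None:
        for roi in rois:
            _check_center(roi, image_shape)
    return rois


def save_rois(rois: Sequence[CircleRoi], path: str | os.PathLike) -> str:
    from .stack_io import write_table

    return write_table(
        [{"label": r.label, "cx": r.cx, "cy": r.cy, "radius": r.radius} for r in rois],
        path,
        columns=["label", "cx", "cy", "radius"],
    )


def _check_center(roi: CircleRoi, shape: tuple[int, int]) -> None:
    H, W = shape
    if not (0 <= roi.cy <= H - 1 and 0 <= roi.cx <= W - 1):
        raise ValueError(
            f"ROI {roi.label!r}: center ({roi.cx}, {roi.cy}) outside image {W}x{H}"
        )


def roi_mask(roi: CircleRoi, shape: tuple[int, int]) -> np.ndarray:
    """Boolean disc mask on an (H, W) grid, center-of-pixel inclusion rule.

    ROIs clipping the image border are truncated with a warning; a center
    outside the image is an error.
    """
    H, W = shape
    if H < 1 or W < 1:
        raise ValueError("image shape must be positive")
    _check_center(roi, shape)
    rr, cc = np.mgrid[0:H, 0:W]
    mask = (cc - roi.cx) ** 2 + (rr - roi.cy) ** 2 <= roi.radius**2
    if (
        roi.cx - roi.radius < 0
        or roi.cy - roi.radius < 0
        or roi.cx + roi.radius > W - 1
        or roi.cy + roi.radius > H - 1
    ):
        warnings.warn(
            f"ROI {roi.label!r} clips the image border; mask truncated",
            stacklevel=2,
        )
    return mask


def extract_trace(stack: ImageStack, roi: CircleRoi, stat: str = "mean") -> Trace:
    """Mean (or summed) intensity of the ROI mask in every frame."""
    if stat not in ("mean", "sum"):
        raise ValueError(f"stat must be 'mean' or 'sum', got {stat!r}")
    mask = roi_mask(roi, stack.frames.shape[1:])
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.label!r}: mask selects no pixels")
    pix = stack.frames[:, mask].astype(np.float64)
    values = pix.sum(axis=1) if stat == "sum" else pix.mean(axis=1)
    return Trace(roi.label, values, stack.frame_interval)


def extract_traces(
    stack: ImageStack, rois: Sequence[CircleRoi], stat: str = "mean"
) -> list[Trace]:
    return [extract_trace(stack, roi, stat=stat) for roi in rois]


def normalize_dff(trace: Trace, baseline_percentile: float = 20.0) -> Trace:
    """Convert a raw trace to dF/F0 against a percentile baseline.

    F0 is the given percentile (0-100) of the trace values; output is
    ``(F - F0) / F0``. A non-positive F0 has no meaningful relative scale
    and raises.
    """
    if not (0 <= baseline_percentile <= 100):
        raise ValueError("baseline_percentile must be within [0, 100]")
    f0 = float(np.percentile(trace.values, baseline_percentile))
    if f0 <= 0:
        raise ValueError(
            f"trace {trace.roi_label!r}: degenerate baseline F0={f0}; "
            "dF/F0 undefined"
        )
    return Trace(
        trace.roi_label,
        (trace.values - f0) / f0,
        trace.frame_interval,
        normalized=True,
    )


def traces_to_table(traces: Iterable[Trace]) -> pd.DataFrame:
    """Long-format table: ``roi_label, t_index, t_seconds, value``."""
    rows = []
    for tr in traces:
        t = np.arange(len(tr.values))
        rows.append(
            pd.DataFrame(
                {
                    "roi_label": tr.roi_label,
                    "t_index": t,
                    "t_seconds": t * tr.frame_interval,
                    "value": tr.values,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["roi_label", "t_index", "t_seconds", "value"])
    return pd.concat(rows, ignore_index=True)
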