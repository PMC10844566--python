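"""Time-lapse stack and table I/O.

A recording is a sequence of grayscale fluorescence frames with a fixed
frame interval (seconds per frame). The interval owns the time base for
everything downstream: frame index ``t`` maps to ``t * frame_interval``
seconds, with t = 0 at the first frame.

Stacks are stored as multi-page grayscale TIFF (8/16-bit integer losslessly,
floating point in a lossless dialect). Tabular outputs are RFC-4180 CSV with
a header row.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "write_table"]

_DESC_KEY = "calwave_frame_interval_s"


@dataclass
class ImageStack:
    """A (T, H, W) intensity movie with its time base.

    Parameters
    ----------
    frames
        3-D array indexed ``(t, row, col)``; non-negative intensities.
    frame_interval
        Seconds per frame, > 0. Frame ``t`` is at ``t * frame_interval`` s.
    bit_depth
        Source sample depth (8 or 16); informational for float data.
    name
        Free-text identifier (defaults to the file stem on read).
    """

    frames: np.ndarray
    frame_interval: float
    bit_depth: int = 16
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (t, row, col); got shape {self.frames.shape}"
            )
        if any(s < 1 for s in self.frames.shape):
            raise ValueError(f"empty stack dimensions: {self.frames.shape}")
        if not np.all(np.isfinite(self.frames.astype(np.float64, copy=False))):
            raise ValueError("stack contains non-finite intensities")
        if self.frames.min() < 0:
            raise ValueError("stack contains negative intensities")
        if not (self.frame_interval > 0):
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    @property
    def duration(self) -> float:
        """Total recording span in seconds (T * frame interval)."""
        return self.n_frames * self.frame_interval

    def times(self) -> np.ndarray:
        """Frame times in seconds; t_seconds[0] == 0, strictly increasing."""
        return np.arange(self.n_frames) * self.frame_interval


def read_stack(path: str | os.PathLike, frame_interval: float | None = None) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    The explicit ``frame_interval`` argument wins over any interval recorded
    in the file (ImageJ ``finterval`` tag or a calwave JSON description); if
    neither is available a ``ValueError`` is raised, because the time base
    cannot be guessed.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            samples = tif.pages[0].samplesperpixel
            arr = tif.asarray()
            file_interval = _interval_from_file(tif)
    except FileNotFoundError:
        raise
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"could not read TIFF stack {path!r}: {exc}") from exc

    if samples != 1:
        raise ValueError(
            f"{path!r}: pages carry {samples} samples per pixel; only grayscale "
            "stacks are supported — pre-split channels first."
        )
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(
            f"{path!r}: expected grayscale pages; got array of shape {arr.shape}. "
            "Multichannel stacks are unsupported — pre-split channels."
        )

    if frame_interval is None:
        frame_interval = file_interval
    if frame_interval is None:
        raise ValueError(
            f"{path!r} carries no frame-interval metadata and none was passed; "
            "supply frame_interval explicitly"
        )

    bit_depth = 8 if arr.dtype.itemsize == 1 else 16
    name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return ImageStack(arr, float(frame_interval), bit_depth=bit_depth, name=name)


def _interval_from_file(tif: tifffile.TiffFile) -> float | None:
    meta = tif.imagej_metadata
    if meta and meta.get("finterval"):
        return float(meta["finterval"])
    desc = tif.pages[0].description
    if desc:
        try:
            payload = json.loads(desc)
            if isinstance(payload, dict) and _DESC_KEY in payload:
                return float(payload[_DESC_KEY])
        except (json.JSONDecodeError, TypeError, ValueError):
            pass
    return None


def write_stack(stack: ImageStack, path: str | os.PathLike) -> str:
    """Write a stack as a multi-page TIFF readable by :func:`read_stack`.

    Integer samples round-trip bit-exactly; float stacks are written as
    32/64-bit float pages (lossless). The frame interval is embedded (ImageJ
    ``finterval`` for ImageJ-compatible dtypes, a JSON description
    otherwise) so the file is self-describing.
    """
    frames = stack.frames
    try:
        if frames.dtype in (np.uint8, np.uint16, np.float32):
            tifffile.imwrite(
                path,
                frames,
                imagej=True,
                photometric="minisblack",
                metadata={"axes": "TYX", "finterval": stack.frame_interval},
            )
        else:
            tifffile.imwrite(
                path,
                frames,
                photometric="minisblack",
                description=json.dumps({_DESC_KEY: stack.frame_interval}),
            )
    except OSError as exc:
        raise OSError(f"could not write TIFF stack {path!r}: {exc}") from exc
    return os.fspath(path)


def write_table(
    rows: Iterable[Mapping] | pd.DataFrame,
    path: str | os.PathLike,
    columns: Sequence[str] | None = None,
) -> str:
    """Write homogeneous records as RFC-4180 CSV with a header row.

    Numbers are serialized at full precision (``repr`` round-trip). An empty
    record sequence still produces a header-only file when ``columns`` is
    given.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))

    import csv

    def _cell(value):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return ""
        if isinstance(value, (np.integer,)):
            return int(value)
        if isinstance(value, (np.floating,)):
            return float(value)  # str() of a Python float round-trips exactly
        return value

    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\r\n")
            writer.writerow(df.columns.tolist())
            for row in df.itertuples(index=False, name=None):
                writer.writerow([_cell(v) for v in row])
    except OSError as exc:
        raise OSError(f"could not write table {path!r}: {exc}") from exc
    return os.fspath(path)
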