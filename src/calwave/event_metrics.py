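"""Event-rate histograms and per-cell / per-condition activity summaries.

Detected transients are reduced to the quantities used to describe network
activity: spikes-per-second histograms over time (per cell and pooled over
the whole field as a "network" series), per-cell counts/rates/prominences,
and a descriptive side-by-side of experimental conditions (basal versus
pharmacological stimulation). The condition comparison is intentionally
descriptive — medians and interquartile ranges, no hypothesis test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .prominence_peaks import Peak
from .roi_traces import Trace

__all__ = [
    "EventRateSeries",
    "CellSummary",
    "event_rate_histogram",
    "summarize_cells",
    "compare_conditions",
    "rates_to_table",
    "summaries_to_table",
]

NETWORK_SCOPE = "network"


@dataclass
class EventRateSeries:
    """Binned event counts and rates for one scope (an ROI or the network).

    Bins are half-open ``[edge_i, edge_{i+1})``; the final bin may be
    shorter when the recording length is not a bin-width multiple, and its
    rate uses its actual width.
    """

    scope: str
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def rate(self) -> np.ndarray:
        """Events per second in each bin (count / actual bin width)."""
        return self.counts / np.diff(self.bin_edges)


@dataclass
class CellSummary:
    """Per-ROI activity: event count, mean rate, prominence stats, IEI."""

    roi_label: str
    n_peaks: int
    mean_rate: float
    mean_prominence: float | None
    max_prominence: float | None
    mean_inter_event_interval: float | None


def _bin_edges(duration: float, bin_width: float) -> np.ndarray:
    n_full = int(math.floor(duration / bin_width + 1e-12))
    edges = list(np.arange(n_full + 1) * bin_width)
    if edges[-1] < duration - 1e-12:
        edges.append(duration)
    return np.asarray(edges, dtype=np.float64)


def event_rate_histogram(
    peaks_by_roi: Mapping[str, Sequence[Peak]],
    bin_width: float,
    duration: float,
    pooled: bool = True,
) -> list[EventRateSeries]:
    """Spikes-per-second histograms per ROI, plus a pooled network series.

    Every peak time must lie in ``[0, duration)``. With ``pooled`` a
    "network" series summing all ROIs bin-by-bin is appended after the
    per-ROI series.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if duration < bin_width:
        raise ValueError("duration must be >= bin_width")
    edges = _bin_edges(duration, bin_width)

    series: list[EventRateSeries] = []
    total = np.zeros(len(edges) - 1, dtype=np.int64)
    for label, peaks in peaks_by_roi.items():
        times = np.asarray([p.t_seconds for p in peaks], dtype=np.float64)
        for i, t in enumerate(times):
            if not (0 <= t < duration):
                raise ValueError(
                    f"ROI {label!r} peak #{i} at t={t} s outside [0, {duration}) s"
                )
        # np.histogram closes the last bin on the right; [0, duration) peaks
        # never reach the last edge, so bins behave as half-open throughout.
        counts, _ = np.histogram(times, bins=edges)
        series.append(EventRateSeries(label, edges, counts))
        total += counts
    if pooled:
        series.append(EventRateSeries(NETWORK_SCOPE, edges, total))
    return series


def summarize_cells(
    peaks_by_roi: Mapping[str, Sequence[Peak]],
    duration: float,
    traces: Mapping[str, Trace] | None = None,
) -> list[CellSummary]:
    """One summary per ROI (zero-peak ROIs included).

    ``mean_rate = n_peaks / duration``; inter-event intervals are
    consecutive differences of peak times (undefined below 2 peaks).
    ``traces`` only extends the ROI universe to cells with no detections.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    labels = list(peaks_by_roi.keys())
    if traces is not None:
        labels += [l for l in traces.keys() if l not in peaks_by_roi]

    out: list[CellSummary] = []
    for label in labels:
        peaks = list(peaks_by_roi.get(label, []))
        n = len(peaks)
        proms = np.asarray([p.prominence for p in peaks])
        times = np.asarray([p.t_seconds for p in peaks])
        iei = float(np.mean(np.diff(times))) if n >= 2 else None
        out.append(
            CellSummary(
                roi_label=label,
                n_peaks=n,
                mean_rate=n / duration,
                mean_prominence=float(proms.mean()) if n else None,
                max_prominence=float(proms.max()) if n else None,
                mean_inter_event_interval=iei,
            )
        )
    return out


def compare_conditions(
    summaries_by_condition: Mapping[str, Sequence[CellSummary]],
) -> pd.DataFrame:
    """Descriptive per-condition table: n_cells, median/IQR of rate and prominence."""
    if len(summaries_by_condition) < 2:
        raise ValueError("need at least 2 labeled conditions to compare")
    rows = []
    for condition, summaries in summaries_by_condition.items():
        if len(summaries) == 0:
            raise ValueError(f"condition {condition!r} has no cells")
        rates = np.asarray([s.mean_rate for s in summaries])
        proms = np.asarray(
            [s.mean_prominence for s in summaries if s.mean_prominence is not None]
        )
        q1r, medr, q3r = np.percentile(rates, [25, 50, 75])
        if len(proms):
            q1p, medp, q3p = np.percentile(proms, [25, 50, 75])
        else:
            q1p = medp = q3p = np.nan
        rows.append(
            {
                "condition": condition,
                "n_cells": len(summaries),
                "median_rate_per_s": medr,
                "iqr_rate_per_s": q3r - q1r,
                "median_mean_prominence": medp,
                "iqr_mean_prominence": q3p - q1p,
            }
        )
    return pd.DataFrame(rows)


def rates_to_table(series: Sequence[EventRateSeries]) -> pd.DataFrame:
    """Flat table: ``scope,bin_start_s,bin_end_s,count,rate_per_s``."""
    rows = []
    for s in series:
        widths = np.diff(s.bin_edges)
        for i in range(len(s.counts)):
            rows.append(
                {
                    "scope": s.scope,
                    "bin_start_s": s.bin_edges[i],
                    "bin_end_s": s.bin_edges[i + 1],
                    "count": int(s.counts[i]),
                    "rate_per_s": s.counts[i] / widths[i],
                }
            )
    return pd.DataFrame(
        rows, columns=["scope", "bin_start_s", "bin_end_s", "count", "rate_per_s"]
    )


def summaries_to_table(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_label": s.roi_label,
                "n_peaks": s.n_peaks,
                "mean_rate_per_s": s.mean_rate,
                "mean_prominence": s.mean_prominence,
                "max_prominence": s.max_prominence,
                "mean_inter_event_interval_s": s.mean_inter_event_interval,
            }
            for s in summaries
        ],
        columns=[
            "roi_label",
            "n_peaks",
            "mean_rate_per_s",
            "mean_prominence",
            "max_prominence",
            "mean_inter_event_interval_s",
        ],
    )
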