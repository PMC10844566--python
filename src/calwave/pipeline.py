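"""End-to-end analysis pipeline with reproducible configuration.

One call runs the whole workflow on a stack: read -> background-correct ->
slice-sum projection (QC image) -> extract per-ROI traces -> detect
transients by topographic prominence -> rate histograms and per-cell
summaries. Every artifact is written next to a fully resolved copy of the
configuration, so any run is reproducible from its output directory alone.
Tabular outputs are byte-deterministic for identical inputs and config.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import event_metrics, preprocess, prominence_peaks, roi_traces, stack_io

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("calwave")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully resolvable pipeline configuration.

    ``ball_radius`` may be the string ``"auto"`` (3 x the median ROI radius)
    and ``min_prominence`` may be ``"auto"`` (k x robust noise per trace).
    """

    stack_path: str
    roi_path: str
    out_dir: str
    frame_interval: float | None = None
    ball_radius: float | str = "auto"
    background_method: str = "rolling_ball"
    clamp_negative: bool = True
    stat: str = "mean"
    dff: bool = False
    dff_percentile: float = 20.0
    min_prominence: float | str = "auto"
    noise_k: float = 3.8
    min_separation: int = 1
    smooth_frames: int = 0
    bin_width: float = 1.0
    pooled: bool = True

    def resolved_dict(self, extra: dict | None = None) -> dict:
        d = dataclasses.asdict(self)
        if extra:
            d.update(extra)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
            log.info("stage %-12s done in %.2f s", name, time.perf_counter() - t0)
            return result

        return wrapper

    return deco


def run_pipeline(config: RunConfig, stack: stack_io.ImageStack | None = None) -> dict:
    """Execute the full workflow; returns a manifest of written artifacts.

    ``stack`` bypasses file reading when the movie is already in memory
    (e.g. freshly synthesized); ``config.stack_path`` then only labels the
    provenance record.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if stack is None:
        stack = _stage("read")(stack_io.read_stack)(
            config.stack_path, config.frame_interval
        )
    rois = _stage("rois")(roi_traces.load_rois)(
        config.roi_path, image_shape=stack.frames.shape[1:]
    )
    if not rois:
        raise PipelineError("rois", ValueError(f"no ROIs in {config.roi_path!r}"))

    if config.ball_radius == "auto":
        radius = 3.0 * float(np.median([r.radius for r in rois]))
    else:
        radius = float(config.ball_radius)
    bg_params = preprocess.BackgroundParams(
        radius=radius,
        method=config.background_method,  # type: ignore[arg-type]
        clamp_negative=config.clamp_negative,
    )
    corrected = _stage("background")(preprocess.subtract_background)(stack, bg_params)

    projection = _stage("project")(preprocess.slice_sum)(corrected)
    projection_png = out / "projection.png"
    _stage("project_png")(_save_projection)(projection, rois, projection_png)

    traces = _stage("trace")(roi_traces.extract_traces)(
        corrected, rois, stat=config.stat
    )
    if config.dff:
        traces = [
            roi_traces.normalize_dff(t, config.dff_percentile) for t in traces
        ]
    traces_csv = out / "traces.csv"
    stack_io.write_table(roi_traces.traces_to_table(traces), traces_csv)

    peak_params = prominence_peaks.PeakCallParams(
        min_prominence=config.min_prominence,
        k=config.noise_k,
        min_separation=config.min_separation,
        smooth_frames=config.smooth_frames,
    )
    peaks_by_roi = {}
    for tr in traces:
        peaks_by_roi[tr.roi_label] = _stage("peaks")(prominence_peaks.detect_peaks)(
            tr, peak_params
        )
    peaks_csv = out / "peaks.csv"
    stack_io.write_table(prominence_peaks.peaks_to_table(peaks_by_roi), peaks_csv)
    n_peaks = sum(len(p) for p in peaks_by_roi.values())
    log.info("detected %d peaks across %d ROIs", n_peaks, len(rois))

    duration = stack.duration
    series = _stage("rates")(event_metrics.event_rate_histogram)(
        peaks_by_roi, config.bin_width, duration, pooled=config.pooled
    )
    rates_csv = out / "rates.csv"
    stack_io.write_table(event_metrics.rates_to_table(series), rates_csv)

    summaries = _stage("summaries")(event_metrics.summarize_cells)(
        peaks_by_roi, duration
    )
    summaries_csv = out / "summaries.csv"
    stack_io.write_table(event_metrics.summaries_to_table(summaries), summaries_csv)

    config_yaml = out / "config_resolved.yaml"
    with open(config_yaml, "w") as fh:
        yaml.safe_dump(
            config.resolved_dict(
                extra={
                    "resolved_ball_radius_px": radius,
                    "frame_interval_s": stack.frame_interval,
                    "n_frames": stack.n_frames,
                    "n_rois": len(rois),
                }
            ),
            fh,
            sort_keys=True,
        )

    return {
        "traces": str(traces_csv),
        "peaks": str(peaks_csv),
        "rates": str(rates_csv),
        "summaries": str(summaries_csv),
        "projection": str(projection_png),
        "config": str(config_yaml),
        "n_peaks": n_peaks,
        "n_rois": len(rois),
    }


def _save_projection(projection, rois, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(projection.values, cmap="magma", interpolation="nearest")
    for roi in rois:
        circ = plt.Circle(
            (roi.cx, roi.cy), roi.radius, fill=False, color="cyan", lw=0.8
        )
        ax.add_patch(circ)
        ax.annotate(
            roi.label, (roi.cx, roi.cy), color="white", fontsize=6, ha="center"
        )
    ax.set_title("slice-sum projection")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
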