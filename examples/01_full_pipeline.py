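"""Run the complete analysis pipeline on a synthetic ground-truth movie.

Generates a 20-cell, 600-s recording (one frame every 5 s) with uneven
illumination, photobleaching and noise, then runs: background correction ->
slice-sum projection -> ROI traces -> topographic-prominence peak detection
-> rate histograms and per-cell summaries. Compares the recovered per-cell
event rates with the generator's true rate.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from calwave import (
    RunConfig,
    SceneConfig,
    generate_movie,
    ground_truth_rois,
    run_pipeline,
)
from calwave.roi_traces import save_rois

config = SceneConfig(seed=7)  # 256x256, 20 cells, 120 frames at 5 s/frame
stack, truth = generate_movie(config)
n_true = sum(len(v) for v in truth.events.values())
print(f"synthetic movie: {config.n_cells} cells, {config.duration:.0f} s, "
      f"{n_true} ground-truth Ca2+ transients")

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp)
    roi_path = out / "rois.csv"
    save_rois(ground_truth_rois(truth), roi_path)
    manifest = run_pipeline(
        RunConfig(
            stack_path="synthetic(seed=7)",
            roi_path=str(roi_path),
            out_dir=str(out / "results"),
            bin_width=60.0,
        ),
        stack=stack,
    )
    summaries = pd.read_csv(manifest["summaries"])

print(f"detected peaks: {manifest['n_peaks']} (truth: {n_true})")
rates = summaries["mean_rate_per_s"].to_numpy()
se = rates.std(ddof=1) / np.sqrt(len(rates))
print(f"grand mean event rate: {rates.mean():.5f} /s "
      f"(generator rate {config.event_rate} /s, standard error {se:.5f})")
print("\nper-cell summaries (first 5):")
print(summaries.head().to_string(index=False))
print("\nThe grand mean rate should sit within a few SE of the generator "
      "rate; each row gives one cell's event count, rate, and prominences.")
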