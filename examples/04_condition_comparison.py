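"""Compare Ca2+ activity across pharmacological conditions.

Simulates three recordings — basal, agonist-stimulated (event rate x3,
larger amplitudes), and antagonist-then-agonist (back to basal) — runs the
detection on each with a threshold calibrated once on the basal recording,
and prints the descriptive condition table.

Holding the threshold fixed across conditions matters: the per-trace
adaptive rule reads densely stimulated activity as "noise" and would
under-detect exactly where activity is highest.
"""

import numpy as np

from calwave import (
    PeakCallParams,
    calibrate_min_prominence,
    compare_conditions,
    detect_peaks,
    generate_movie,
    ground_truth_rois,
    preset,
    subtract_background,
    summarize_cells,
    BackgroundParams,
)
from calwave.roi_traces import extract_traces

SEEDS = {"basal": 1, "agonist": 2, "antagonist+agonist": 3}

traces_by_condition = {}
for name, seed in SEEDS.items():
    config = preset(name, seed=seed)
    stack, truth = generate_movie(config)
    corrected = subtract_background(stack, BackgroundParams(radius=30))
    traces_by_condition[name] = extract_traces(corrected, ground_truth_rois(truth))

threshold = calibrate_min_prominence(traces_by_condition["basal"])
print(f"detection threshold calibrated on basal traces: {threshold:.2f} units\n")

params = PeakCallParams(min_prominence=threshold)
summaries = {}
for name, traces in traces_by_condition.items():
    peaks = {tr.roi_label: detect_peaks(tr, params) for tr in traces}
    summaries[name] = summarize_cells(peaks, duration=600.0)

table = compare_conditions(summaries)
print(table.to_string(index=False))
basal = table.set_index("condition").loc["basal", "median_rate_per_s"]
agonist = table.set_index("condition").loc["agonist", "median_rate_per_s"]
print(f"\nagonist / basal median-rate ratio: {agonist / basal:.2f} "
      "(the generator stimulates at 3x the basal rate)")
print("Receptor blockade before stimulation returns the median rate to "
      "the basal level — the qualitative pharmacology pattern.")
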