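"""Topographic-prominence peak detection on a single fluorescence trace.

Builds one noisy synthetic trace with known transient times, walks through
the detection (local maxima -> prominence -> threshold), and prints the
detected peaks next to the ground truth.
"""

import numpy as np

from calwave import PeakCallParams, detect_peaks, estimate_noise, generate_trace

trace, true_peaks = generate_trace(
    n_frames=120, frame_interval=5.0, event_rate=0.02,
    amplitude=10.0, noise_sigma=1.0, seed=42,
)
sigma_hat = estimate_noise(trace)
params = PeakCallParams()  # auto threshold = 3.8 x robust noise
print(f"trace: {len(trace)} frames at {trace.frame_interval} s/frame; "
      f"robust noise estimate {sigma_hat:.2f} (true sigma 1.0)")
print(f"prominence threshold: {params.k} x {sigma_hat:.2f} = "
      f"{params.k * sigma_hat:.2f} trace units\n")

peaks = detect_peaks(trace, params)
print(f"{'frame':>6} {'t (s)':>7} {'height':>8} {'prominence':>11} {'bases':>10}")
for p in peaks:
    print(f"{p.t_index:>6} {p.t_seconds:>7.0f} {p.height:>8.2f} "
          f"{p.prominence:>11.2f} ({p.left_base:>3},{p.right_base:>3})")

detected = [p.t_index for p in peaks]
print(f"\nground-truth peak frames: {true_peaks}")
print(f"detected peak frames:     {detected}")
hits = sum(1 for t in true_peaks if any(abs(t - d) <= 1 for d in detected))
print(f"{hits}/{len(true_peaks)} true transients recovered within 1 frame.")
print("Each prominence is the peak's height above the lowest contour that "
      "encircles it but no higher peak — transients stand ~10x above noise.")
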