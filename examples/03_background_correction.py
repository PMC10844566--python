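"""Rolling-ball background correction of an unevenly illuminated frame.

Builds a frame = smooth illumination gradient + small bright cells, removes
the background by morphological opening with a ball, and shows that the
gradient is removed while the cells survive.
"""

import numpy as np

from calwave import BackgroundParams, estimate_background

rng = np.random.default_rng(0)
n = 128
y, x = np.mgrid[0:n, 0:n]
gradient = 40 * (x / n) + 25 * (y / n) ** 2  # smooth uneven illumination
cells = np.zeros((n, n))
for cx, cy in [(30, 40), (70, 90), (100, 30)]:
    d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    cells += 80 * np.clip(6 - d, 0, 1)
frame = gradient + cells + rng.uniform(0, 2, (n, n))

# radius must exceed the largest cell structure (cells are ~6 px here)
params = BackgroundParams(radius=20, method="rolling_ball")
background = estimate_background(frame, params)
corrected = frame - background

print(f"frame range:      [{frame.min():7.2f}, {frame.max():7.2f}]")
print(f"background range: [{background.min():7.2f}, {background.max():7.2f}]")
print(f"corrected range:  [{corrected.min():7.2f}, {corrected.max():7.2f}]")
print(f"background <= frame everywhere: {bool(np.all(background <= frame + 1e-9))}")

residual = np.abs(corrected - cells)
off_cells = residual[cells == 0]
print(f"residual off the cells (should be ~ the 0-2 noise band): "
      f"mean {off_cells.mean():.2f}, max {off_cells.max():.2f}")
on_cells = corrected[cells > 40]
print(f"cell peak intensity after correction: {on_cells.max():.1f} "
      f"(cells were drawn at 80)")
print("The ~65-unit illumination gradient is gone; cell amplitudes survive "
      "because the ball cannot enter structures narrower than its radius.")
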