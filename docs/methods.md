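# Methods

## Scope and data model

calwave analyzes time-lapse fluorescence recordings of 2-D cell cultures
loaded with a Ca²⁺ indicator. A recording is a T×H×W grayscale stack
(multi-page TIFF, 8/16-bit integer or float) plus one number that owns the
time base: the frame interval Δt in seconds. Frame *t* is at *t*·Δt s, with
t = 0 at the first frame. All geometry is in pixels; physical pixel size is
deliberately not modeled (nothing downstream needs it). Explicit
`frame_interval` arguments override file metadata (ImageJ `finterval` or a
calwave JSON description); a stack with neither is an error rather than a
guess.

## Background correction

The illumination background of each frame is the grayscale **opening** of
the frame by a non-flat structuring function: a spherical cap
b(d) = r − √(r² − d²) ("rolling ball") or a paraboloid h(d) = d²/(2r) with
the same apex curvature ("sliding paraboloid"). Opening = erosion then
dilation with the same profile; it is exactly the upper envelope traced by
the element rolled beneath the intensity surface. Implementation is
`scipy.ndimage.grey_erosion/grey_dilation`; out-of-image samples act as +∞
for the erosion and −∞ for the dilation, i.e. near borders the element
rests on in-image samples only. The paraboloid's support is truncated where
its depth exceeds the frame's dynamic range, which provably cannot change
the result.

Consequences used as test oracles: background ≤ frame (anti-extensive),
opening∘opening = opening (idempotent), f ≤ g ⇒ bg(f) ≤ bg(g) (increasing),
translation equivariance, and exact agreement with a brute-force
erosion/dilation over all offsets. One caveat worth knowing: a *non-flat*
cap can ride up the flank of a structure narrower than the ball by at most
one "curvature step" r − √(r² − w²) for half-width w — so "background is 0
under an isolated spike" holds only to that bound, not exactly.

The radius is the caller's choice and must exceed the largest genuine
structure; the CLI's `--ball-radius auto` uses 3× the median ROI radius.
For r > 20 px a classical speed path (block-min shrink by 2/4/8, open at
r/shrink, bilinear enlarge, clip to ≤ frame) is enabled by default; it is
off in every exactness test and can be disabled
(`allow_downsample=False`).

Per-frame independence: the background is estimated on each frame
separately, with no temporal smoothing.

The spectrum LUT (red = low → violet = high, hue monotone through the
ROYGBIV ramp, anchors defaulting to the 1st/99th percentile) is rendering
only and is never used in quantification.

## ROIs and traces

ROIs are labeled discs, CSV `label,cx,cy,radius` with 0-based pixel
coordinates, (cx, cy) = (column, row). A pixel is inside iff its *center*
satisfies (c−cx)² + (r−cy)² ≤ radius² — ImageJ's mask semantics, no
partial-area weighting, so masks and traces are bit-reproducible. Radius 0
selects exactly the center pixel; border-clipping ROIs are truncated with a
warning; a center outside the image is an error. The trace statistic is the
mask mean (sum available); extraction is linear in the stack. ΔF/F₀ uses a
percentile baseline (default 20th) and refuses non-positive F₀.

## Topographic prominence

The prominence of a local maximum is its height above the lowest contour
line that encircles it but no higher sample. On a 1-D trace this reduces
to: walk left and right from the peak until a strictly higher sample or the
trace end; each side's *base* is the minimum of its excursion; the key
contour level is

* max(left min, right min) if both sides met higher ground,
* the bounded side's min if only one side did,
* min(left min, right min) if neither did — the "island" convention, which
  gives the global maximum prominence = height − global minimum.

Conventions chosen where tools differ (all are enforced by tests):
plateaus count once, reported at their leftmost index; endpoints can be
maxima only when strictly above their inner non-equal neighbor; equal
height does *not* terminate an excursion, so tied maxima each get their own
prominence. Trace ends are open ends, not walls — this is the geographic
convention and differs from scipy's wall-like handling, which is why the
implementations agree exactly only for peaks with higher ground on both
sides (that agreement is itself a test).

Correctness is established against an independent flood-fill oracle that,
for each maximum, floods the level set above each candidate contour level
and accepts the lowest level whose connected component contains no higher
sample. The oracle binary-searches the candidate levels — valid because the
acceptance predicate is monotone in the level (raising the level shrinks
the component) — and is itself cross-checked by full linear enumeration on
short traces. Implementation and oracle agree exactly on thousands of
randomized traces including plateaus, ties and boundary maxima.

Useful invariants: prominence is invariant under adding a constant and
scales linearly under positive scaling; every prominence ≤ height − global
min with equality exactly at a unique global maximum.

## Detection and thresholds

`detect_peaks` keeps all maxima with prominence ≥ `min_prominence`, then
enforces `min_separation` (default 1 = off) greedily from the most
prominent peak down. Detection runs on raw traces by default; a
moving-average pre-filter exists but is off.

The threshold is absolute, or "auto" = k × a robust noise scale
σ̂ = 1.4826·MAD(ΔF)/√2 (first-differencing removes slow drift, the MAD
ignores sparse transient jumps, √2 undoes the differencing variance).

**Calibration of k.** Two facts make the naive "3σ" intuition wrong here.
First, σ̂ is *not* σ on a working trace: with ~12 transients in 120 frames
a large fraction of first differences lie on transient slopes, and σ̂ runs
1.4–1.7× the true noise scale. Second, both error modes have heavy
structure: pure-noise excursions between transients attain prominences of
3–5 σ̂ (their cols are minima over many samples), while true transients
lose effective prominence when their cols sit on a neighbor's decay tail.
Monte-Carlo calibration on the synthetic study conditions (10:1
amplitude-to-noise, ~12 events per 120-frame trace) puts the error-rate
optimum at k ≈ 3.8–4.0, where misses and false alarms are each ≲ 0.5% of
traces; k = 3.8 is the default. Exact event-count recovery at these
conditions is 98.7–99.5% depending on the random set — the residual ~1% is
the irreducible rate of noise excursions colliding with depressed true
prominences, not a tunable margin.

**Cross-condition comparisons.** The per-trace auto rule assumes sparse
transients. On a strongly stimulated culture (events every few frames) the
MAD of first differences measures signal, not noise, and the rule
under-detects precisely where activity is highest — enough to invert a
rate comparison. Comparisons must therefore hold detection fixed:
`calibrate_min_prominence` resolves k×σ̂ on every trace of the reference
(basal) recording and returns the median, which is then applied to all
conditions as one absolute threshold. The condition table itself is
descriptive (n, median, IQR); no hypothesis test is attached.

## Event metrics

Histograms bin peak times into half-open [edge, edge+w) bins; the final
bin may be shorter and its rate uses its actual width; default bin width
1 s (so counts read as spikes per second). Counts are conserved exactly
(Σ bins = Σ peaks, per ROI and for the pooled "network" series, at any bin
width). Per-cell summaries: n_peaks, mean rate = n/duration, mean/max
prominence, mean inter-event interval (undefined below 2 peaks; empty CSV
field).

## Synthetic movies

The generator emulates the target data regime — sparse bright somata on a
dim background imaged at one frame per 5 s — with these defaults (all
overridable):

| parameter | default | meaning |
| --- | --- | --- |
| shape, n_cells | 256×256, 20 | field of view, non-overlapping soft-disc cells |
| cell radius | 6–12 px | soma size; discs have a 1-px linear edge |
| baseline / resting | 10 / 30 counts | scene background / cell resting brightness |
| amplitude | 40–80 counts | per-event transient amplitude (uniform) |
| rise / decay | 1 frame / 2 frames | linear rise to peak, then exp(−t/decay) |
| event_rate | 0.02 /s per cell | target mean rate, hit exactly in expectation |
| refractory | 6 frames (30 s) | minimum inter-event separation |
| gradient | 20 counts p-p | smooth 2nd-order polynomial illumination |
| bleach_tau | 600 frames | global exponential photobleaching (∞ = off) |
| noise_sigma | 2 counts | additive Gaussian; `shot_noise` swaps in Poisson |

Pixel model: clean = baseline + Σ cells profile·(resting + Σ events
A·kernel); observed = (clean + gradient)·exp(−t/bleach_tau) + noise,
quantized to uint16 camera counts. The ground truth keeps the float clean
stack (noise-, gradient- and bleach-free) plus every cell and event.

Event times are a **dead-time renewal process**: gap = refractory +
Exp(1/λ − refractory), so the mean gap is exactly 1/λ. The refractory
period reflects that somatic transients do not stack within a frame or two
— and without it "exact event recovery" would be ill-defined, since two
events in the same frame interval are indistinguishable from one at any
frame rate. The first arrival is drawn from the gap law's equilibrium
forward-recurrence distribution, making counts stationary
(E[N(T)] = λT, unbiased) while placing no events before t = 0 — so no
orphan decay tails enter the first frames. Events whose peak frame falls
past the last frame are dropped (a ~0.1-event edge trim per 600 s cell).
Cells are independent; intercellular waves are not simulated.

Condition presets mirror a basal / agonist / antagonist+agonist design:
`agonist` = rate ×3 with amplitudes ×1.5 (its refractory shortens to 2
frames, as a ×3 rate is infeasible under a 30-s dead time);
`antagonist+agonist` = basal. The ratios are this package's constructs for
qualitative ordering checks, not measured pharmacology.

All randomness flows from one integer seed through numpy's PCG64;
identical configs give bit-identical movies across runs and platforms.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: cell morphology beyond discs (no processes or
microdomains), intercellular wave propagation or any cell-cell correlation,
motion/drift, focus changes, indicator saturation or nonlinear
dye-buffering kinetics, and structured camera noise (fixed-pattern, read
glow). Results on real recordings additionally depend on manual ROI quality,
which the synthetic protocol sidesteps by reusing the generator's cells as
ROIs.

## Problem sizes and numerics

The validation suite uses: 1,000 random traces of length 5–300 (with
plateaus, ties, boundary maxima) for exact oracle agreement; 50 random
32–64-px images at radii 2–12 for exact opening agreement (tolerance 1e-9,
float dust only); 1,000 traces at 10:1 SNR for recovery; and full-scale
20-cell, 600-s, 256×256 movies (gradient and bleaching on) for end-to-end
rate recovery, judged against the generator rate at 3 standard errors of
the per-cell rates. The slice-sum accumulates in int64 for integer input
(exact up to 10⁶ frames of 16-bit data). CSV output writes shortest
round-trip float representations with CRLF line endings; reruns with
identical configuration are byte-identical.

## Known limitations

* Manual (or ground-truth) ROIs only; automatic segmentation is out of
  scope.
* No transient kinetics fitting, deconvolution, or spike inference beyond
  prominence thresholding; no wave-speed or connectivity analysis.
* The auto threshold is calibrated for sparse-transient traces; use
  `calibrate_min_prominence` (or an absolute threshold) whenever recordings
  are compared or activity is dense.
* The downsampled background path for large radii is an approximation
  (clipped to stay ≤ frame); use `allow_downsample=False` where exactness
  matters more than speed.
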