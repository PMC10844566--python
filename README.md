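# calwave

Calcium-imaging analysis for 2-D astrocyte cultures: background correction
of time-lapse fluorescence stacks, ROI-based trace extraction,
**topographic-prominence** detection of Ca²⁺ transients, and
event-rate/network summary metrics — validated end-to-end on synthetic
movies with known ground truth.

Astrocytes signal through intracellular Ca²⁺ rather than action
potentials. A fluorescent indicator (e.g. Fluo-8) turns those Ca²⁺
transients into brightness transients in a time-lapse movie, typically one
frame every 5 s for spontaneous activity. calwave turns such a movie into
per-cell event rates:

1. **Background correction** — uneven illumination is estimated by the
   *rolling-ball* filter: the background at each pixel is the upper
   envelope traced by a ball of radius *r* rolled beneath the intensity
   surface, i.e. the grayscale morphological opening of the frame by a
   spherical-cap structuring function *b(d) = r − √(r² − d²)*. A
   *sliding-paraboloid* variant (*h(d) = d²/2r*, same apex curvature)
   handles intensities much larger than the object scale. *r* must exceed
   the largest cell structure.
2. **ROI placement** — the *slice-sum* projection
   *P(x, y) = Σₜ F(t, x, y)* reveals every cell that was ever active;
   circular ROIs (label, center, radius — CSV) are placed on it and
   transposed onto the movie.
3. **Trace extraction** — *F(t)* = mean intensity over the ROI disc per
   frame (optionally ΔF/F₀ = (F − F₀)/F₀ against a percentile baseline).
4. **Peak detection** — each local maximum is scored by its *topographic
   prominence*: its height above the lowest contour line that encircles it
   but no higher peak (the geographers' measure of how much a summit
   stands out). Maxima with prominence ≥ a threshold — absolute, or
   *k* × a robust noise scale — are the detected transients. Prominence is
   invariant to baseline offset and equivariant under intensity scaling,
   which makes it well suited to drifting, bleaching fluorescence traces.
5. **Event metrics** — spikes-per-second histograms per cell and pooled
   over the network, per-cell summaries (count, mean rate, prominences,
   inter-event intervals), and descriptive condition tables (median/IQR)
   for e.g. basal vs. agonist-stimulated recordings.

A first-class synthetic-movie generator (`calwave.synth_movies`) simulates
the whole data regime — soft-disc cells, fast-rise/exponential-decay
transient kinetics, refractory dead-time event statistics with an exact
target mean rate, smooth polynomial illumination gradients, exponential
photobleaching, Gaussian or Poisson noise — with full ground truth, so
every stage of the pipeline is testable without a microscope.

## Worked example

Detect transients on a synthetic trace with known event times
(`examples/02_prominence_detection.py`):

```text
trace: 120 frames at 5.0 s/frame; robust noise estimate 1.02 (true sigma 1.0)
prominence threshold: 3.8 x 1.02 = 3.88 trace units

 frame   t (s)   height  prominence      bases
    16      80    40.43       12.10 (  4, 81)
    31     155    40.12       10.84 ( 25, 81)
    ...
   110     550    41.66       13.34 ( 81,118)

ground-truth peak frames: [16, 31, 39, 45, 57, 68, 87, 93, 103, 110]
detected peak frames:     [16, 31, 39, 45, 57, 68, 87, 93, 103, 110]
10/10 true transients recovered within 1 frame.
```

Each row is one detected transient: the frame (and second) of the maximum,
its height, its prominence (height above the key contour), and the indices
of the bounding excursion minima. At 10:1 amplitude-to-noise the detector
recovers every injected event.

The other examples cover the full pipeline on a 20-cell movie
(`01_full_pipeline.py`), rolling-ball background correction
(`03_background_correction.py`), and a basal / agonist /
antagonist+agonist comparison (`04_condition_comparison.py`). Each prints
the numbers it computes and a line on what they mean.

## Command line

```sh
calwave synth --preset basal --seed 7 --out movie.tif --rois-out rois.csv
calwave run --stack movie.tif --rois rois.csv --interval 5 \
            --ball-radius auto --min-prominence auto --bin-width 1 --out results/
```

`calwave run` writes `traces.csv`, `peaks.csv`, `rates.csv`,
`summaries.csv`, `projection.png` and the fully resolved configuration, so
any run is reproducible from its output directory. Per-stage subcommands
(`background`, `project`, `trace`, `peaks`, `rates`) expose each step
individually.

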