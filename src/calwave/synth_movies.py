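"""Synthetic fluorescence movies and traces with known ground truth.

The generator emulates the data regime of a 2-D astrocyte culture imaged at
one frame every 5 s: sparse bright cell bodies (soft-edged discs) on a dim
background, Ca2+ transients with a fast (one-frame) rise and a slower
exponential decay, a smooth low-order-polynomial illumination gradient,
slow monotone photobleaching, and additive Gaussian or Poisson shot noise.

Event times per cell form a dead-time renewal process: each inter-event gap
is a refractory period plus an exponential tail whose scale is chosen so
the *mean* rate equals ``event_rate`` exactly. The refractory period (a few
frames) reflects that somatic Ca2+ transients do not stack within a frame
or two of each other; without it, arbitrarily close events would be
fundamentally unresolvable by any detector and "ground truth" would be
ill-defined at the frame grid. Cells are independent; intercellular waves
are not simulated.

All randomness flows from one integer seed through ``numpy``'s PCG64
generator, so identical configs give bit-identical movies across runs and
platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .roi_traces import CircleRoi, Trace
from .stack_io import ImageStack

__all__ = [
    "SceneConfig",
    "CellTruth",
    "EventTruth",
    "GroundTruth",
    "generate_movie",
    "generate_trace",
    "preset",
    "PRESETS",
    "ground_truth_rois",
]


@dataclass
class SceneConfig:
    """Scene parameters; defaults mirror the study conditions.

    Units: pixels for geometry, frames for kinetics, seconds for rates and
    the frame interval, camera counts for intensities.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 20
    cell_radius_range: tuple[float, float] = (6.0, 12.0)
    baseline_intensity: float = 10.0
    resting_intensity: float = 30.0
    amplitude_range: tuple[float, float] = (40.0, 80.0)
    rise_frames: int = 1
    decay_frames: float = 2.0
    event_rate: float = 0.02  # events per second per cell
    refractory_frames: float = 6.0  # minimum inter-event separation
    frame_interval: float = 5.0  # seconds per frame
    n_frames: int = 120
    illumination_gradient: float = 20.0  # peak-to-peak counts; 0 = flat
    bleach_tau: float = 600.0  # frames; inf = no bleaching
    noise_sigma: float = 2.0  # additive Gaussian counts
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_frames < 1:
            raise ValueError("n_cells and n_frames must be >= 1")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if min(self.cell_radius_range) <= 0:
            raise ValueError("cell radii must be > 0")
        if self.rise_frames < 0 or self.decay_frames <= 0:
            raise ValueError("rise_frames >= 0 and decay_frames > 0 required")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        if self.event_rate > 0:
            dead = self.refractory_frames * self.frame_interval
            if 1.0 / self.event_rate <= dead:
                raise ValueError(
                    f"event_rate {self.event_rate}/s is infeasible with a "
                    f"{dead:.0f} s refractory period (mean gap must exceed it); "
                    "lower the rate or the refractory_frames"
                )

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class CellTruth:
    label: str
    cx: float
    cy: float
    radius: float


@dataclass(frozen=True)
class EventTruth:
    onset_frame: int
    peak_frame: int
    amplitude: float


@dataclass
class GroundTruth:
    """Everything the generator knows: cells, events, and the clean movie."""

    cells: list[CellTruth]
    events: dict[str, list[EventTruth]]
    clean_stack: ImageStack  # noiseless, gradient-free, bleach-free


# Condition presets mirroring a basal / agonist / antagonist+agonist design.
# The agonist multiplies the event rate x3 and amplitudes x1.5 (and must
# shorten the refractory period for the x3 rate to be feasible); blocking
# the receptor before stimulating returns activity to basal. The ratios are
# this package's constructs for qualitative comparisons, not measured values.
PRESETS: dict[str, dict] = {
    "basal": {},
    "agonist": {
        "event_rate": 0.06,
        "amplitude_range": (60.0, 120.0),
        "refractory_frames": 2.0,
    },
    "antagonist+agonist": {},
}


def preset(name: str, **overrides) -> SceneConfig:
    """A :class:`SceneConfig` for a named condition preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


def _transient_kernel(n_frames: int, rise: int, decay: float) -> np.ndarray:
    """Kernel sampled on the frame grid: linear rise to 1, then exp decay."""
    k = np.zeros(n_frames, dtype=np.float64)
    dt = np.arange(n_frames, dtype=np.float64)
    if rise > 0:
        rising = dt <= rise
        k[rising] = dt[rising] / rise
        k[~rising] = np.exp(-(dt[~rising] - rise) / decay)
    else:
        k = np.exp(-dt / decay)
    return k


def _sample_event_frames(
    rng: np.random.Generator,
    rate: float,
    refractory_frames: float,
    n_frames: int,
    frame_interval: float,
    rise_frames: int,
) -> list[int]:
    """Onset frames of a dead-time renewal process with mean rate ``rate``.

    gap = refractory + Exp(1/rate - refractory), so the mean gap is exactly
    1/rate. The first arrival is drawn from the equilibrium forward-
    recurrence distribution of that gap law, which makes the counting
    process stationary (E[N(T)] = rate * T, no start-up bias) while still
    placing no events before t=0 — so no truncated decay tails enter
    frame 0. Only events whose *peak* frame lands inside the recording are
    kept.
    """
    if rate <= 0:
        return []
    dead = refractory_frames * frame_interval
    theta = 1.0 / rate - dead  # exponential mean; > 0 by config validation
    mean_gap = 1.0 / rate
    duration = n_frames * frame_interval

    # forward recurrence time W of gap = dead + Exp(theta):
    # density (1 - F_gap(w)) / mean_gap -> uniform on [0, dead] with mass
    # dead/mean_gap, else dead + Exp(theta)
    u = rng.uniform()
    if u < dead / mean_gap:
        t = rng.uniform(0.0, dead)
    else:
        t = dead + rng.exponential(theta)

    onsets: list[int] = []
    while t < duration:
        onset = int(t // frame_interval)
        if 0 <= onset + rise_frames < n_frames:
            onsets.append(onset)
        t += dead + rng.exponential(theta)
    return onsets


def _cell_profile(
    shape: tuple[int, int], cx: float, cy: float, radius: float
) -> np.ndarray:
    """Soft-edged disc: 1 inside, linear roll-off over the outermost pixel."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    d = np.sqrt((cc - cx) ** 2 + (rr - cy) ** 2)
    return np.clip(radius + 0.5 - d, 0.0, 1.0)


def _place_cells(rng: np.random.Generator, config: SceneConfig) -> list[CellTruth]:
    H, W = config.shape
    r_lo, r_hi = config.cell_radius_range
    cells: list[CellTruth] = []
    attempts = 0
    max_attempts = 2000 * config.n_cells
    while len(cells) < config.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_cells} non-overlapping cells of radius "
                f"{config.cell_radius_range} in a {W}x{H} field; "
                "use fewer or smaller cells"
            )
        r = rng.uniform(r_lo, r_hi)
        margin = r + 2.0
        if 2 * margin >= min(H, W):
            raise ValueError("cell radius too large for the field of view")
        cx = rng.uniform(margin, W - 1 - margin)
        cy = rng.uniform(margin, H - 1 - margin)
        if all(
            math.hypot(cx - c.cx, cy - c.cy) >= r + c.radius for c in cells
        ):
            cells.append(CellTruth(f"cell{len(cells):02d}", cx, cy, r))
    return cells


def _illumination(rng: np.random.Generator, config: SceneConfig) -> np.ndarray:
    """Smooth second-order polynomial surface scaled to [0, peak-to-peak]."""
    H, W = config.shape
    if config.illumination_gradient <= 0:
        return np.zeros((H, W))
    y, x = np.mgrid[0:H, 0:W]
    X = 2.0 * x / max(W - 1, 1) - 1.0
    Y = 2.0 * y / max(H - 1, 1) - 1.0
    c = rng.uniform(-1.0, 1.0, size=5)
    poly = c[0] * X + c[1] * Y + c[2] * X * Y + c[3] * X**2 + c[4] * Y**2
    span = poly.max() - poly.min()
    if span == 0:
        return np.zeros((H, W))
    return (poly - poly.min()) / span * config.illumination_gradient


def generate_movie(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate one recording; deterministic given ``config.seed``.

    Pixel model::

        clean(t, p)    = baseline + sum_cells profile(p) * course_cell(t)
        course_cell(t) = resting + sum_events A * kernel(t - onset)
        observed(t, p) = (clean + gradient(p)) * exp(-t / bleach_tau) + noise

    With ``shot_noise`` the additive noise is replaced by Poisson sampling
    of the bleached mean. Output is quantized to uint16 like camera counts;
    the returned ground truth keeps the float clean stack (noise-, gradient-
    and bleach-free).
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.shape
    T = config.n_frames

    cells = _place_cells(rng, config)
    kernel = _transient_kernel(T, config.rise_frames, config.decay_frames)

    clean = np.full((T, H, W), config.baseline_intensity, dtype=np.float64)
    events: dict[str, list[EventTruth]] = {}
    for cell in cells:
        onsets = _sample_event_frames(
            rng,
            config.event_rate,
            config.refractory_frames,
            T,
            config.frame_interval,
            config.rise_frames,
        )
        cell_events = []
        course = np.full(T, config.resting_intensity, dtype=np.float64)
        for onset in onsets:
            amp = rng.uniform(*config.amplitude_range)
            cell_events.append(
                EventTruth(onset, onset + config.rise_frames, float(amp))
            )
            course[onset:] += amp * kernel[: T - onset]
        events[cell.label] = cell_events

        # add only within the cell's bounding box to keep this O(cells * box)
        r_int = int(np.ceil(cell.radius)) + 1
        y0, y1 = max(0, int(cell.cy) - r_int), min(H, int(cell.cy) + r_int + 2)
        x0, x1 = max(0, int(cell.cx) - r_int), min(W, int(cell.cx) + r_int + 2)
        patch = _cell_profile(
            (y1 - y0, x1 - x0), cell.cx - x0, cell.cy - y0, cell.radius
        )
        clean[:, y0:y1, x0:x1] += course[:, None, None] * patch[None]

    gradient = _illumination(rng, config)
    if math.isfinite(config.bleach_tau):
        bleach = np.exp(-np.arange(T) / config.bleach_tau)
    else:
        bleach = np.ones(T)
    mean = (clean + gradient[None]) * bleach[:, None, None]

    if config.shot_noise:
        observed = rng.poisson(mean).astype(np.float64)
    else:
        observed = mean
        if config.noise_sigma > 0:
            observed = mean + rng.normal(0.0, config.noise_sigma, size=mean.shape)

    observed = np.clip(np.rint(observed), 0, 65535).astype(np.uint16)
    stack = ImageStack(
        observed, config.frame_interval, bit_depth=16, name=f"synth_seed{config.seed}"
    )
    clean_stack = ImageStack(
        clean, config.frame_interval, bit_depth=16, name=f"clean_seed{config.seed}"
    )
    return stack, GroundTruth(cells=cells, events=events, clean_stack=clean_stack)


def generate_trace(
    n_frames: int = 120,
    frame_interval: float = 5.0,
    event_rate: float = 0.02,
    refractory_frames: float = 6.0,
    amplitude: float = 10.0,
    noise_sigma: float = 1.0,
    resting: float = 30.0,
    rise_frames: int = 1,
    decay_frames: float = 2.0,
    seed: int = 0,
    label: str = "synth",
) -> tuple[Trace, list[int]]:
    """1-D shortcut for detector tests: one cell's trace plus ground-truth
    peak frames, with the same kinetics, event statistics and noise model
    as :func:`generate_movie`."""
    cfg = SceneConfig(  # reuse validation of the rate/refractory pairing
        n_frames=n_frames,
        frame_interval=frame_interval,
        event_rate=event_rate,
        refractory_frames=refractory_frames,
        rise_frames=rise_frames,
        decay_frames=decay_frames,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    kernel = _transient_kernel(n_frames, rise_frames, decay_frames)
    onsets = _sample_event_frames(
        rng, event_rate, refractory_frames, n_frames, frame_interval, rise_frames
    )
    values = np.full(n_frames, float(resting))
    for onset in onsets:
        values[onset:] += amplitude * kernel[: n_frames - onset]
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, size=n_frames)
    values = np.clip(values, 0.0, None)
    peak_frames = [o + rise_frames for o in onsets]
    return Trace(label, values, frame_interval), peak_frames


def ground_truth_rois(truth: GroundTruth) -> list[CircleRoi]:
    """The generator's cells as circular ROIs (what a careful user would draw)."""
    return [CircleRoi(c.label, c.cx, c.cy, c.radius) for c in truth.cells]
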