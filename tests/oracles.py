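"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: the opening oracle
enumerates every structuring-element offset explicitly, and the prominence
oracle enumerates contour levels by flood-filling level sets. Slow but
transparent.
"""

from __future__ import annotations

import numpy as np

_BIG = 1e30


# ---------------------------------------------------------------- morphology
def oracle_ball_depth(radius: float) -> np.ndarray:
    R = int(np.ceil(radius))
    yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
    d2 = (yy * yy + xx * xx).astype(float)
    depth = np.full(d2.shape, _BIG)
    inside = d2 <= radius * radius
    depth[inside] = radius - np.sqrt(radius * radius - d2[inside])
    return depth


def oracle_paraboloid_depth(radius: float, max_depth: float) -> np.ndarray:
    if max_depth <= 0:
        max_depth = 1.0
    R = int(np.ceil(np.sqrt(2.0 * radius * max_depth))) + 1
    yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
    depth = (yy * yy + xx * xx) / (2.0 * radius)
    depth[depth > max_depth] = _BIG
    return depth


def oracle_opening(frame: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Erosion-then-dilation with the explicit height profile, all offsets.

    Out-of-image samples act as +inf for the erosion and -inf for the
    dilation (the ball rests on in-image samples only).
    """
    frame = np.asarray(frame, float)
    H, W = frame.shape
    R = depth.shape[0] // 2

    fpad = np.full((H + 2 * R, W + 2 * R), _BIG)
    fpad[R : R + H, R : R + W] = frame
    eroded = np.full((H, W), np.inf)
    for dy in range(-R, R + 1):
        for dx in range(-R, R + 1):
            d = depth[dy + R, dx + R]
            if d >= _BIG:
                continue
            eroded = np.minimum(
                eroded, fpad[R + dy : R + dy + H, R + dx : R + dx + W] + d
            )

    epad = np.full((H + 2 * R, W + 2 * R), -_BIG)
    epad[R : R + H, R : R + W] = eroded
    opened = np.full((H, W), -np.inf)
    for dy in range(-R, R + 1):
        for dx in range(-R, R + 1):
            d = depth[dy + R, dx + R]
            if d >= _BIG:
                continue
            opened = np.maximum(
                opened, epad[R + dy : R + dy + H, R + dx : R + dx + W] - d
            )
    return opened


# ---------------------------------------------------------------- prominence
def oracle_local_maxima(v: np.ndarray) -> list[int]:
    """Plateau-aware local maxima, leftmost plateau index."""
    v = np.asarray(v, float)
    n = len(v)
    out = []
    for i in range(n):
        if i > 0 and v[i - 1] == v[i]:
            continue  # not the leftmost sample of its plateau
        r = i + 1
        while r < n and v[r] == v[i]:
            r += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = r >= n or v[r] < v[i]
        whole_trace = i == 0 and r >= n
        if left_ok and right_ok and not whole_trace:
            out.append(i)
    return out


def _component_ok(v: np.ndarray, peak: int, level: float) -> bool:
    """Does the >level component containing ``peak`` avoid samples above v[peak]?"""
    mask = v > level
    lo = peak
    while lo - 1 >= 0 and mask[lo - 1]:
        lo -= 1
    hi = peak
    while hi + 1 < len(v) and mask[hi + 1]:
        hi += 1
    return not np.any(v[lo : hi + 1] > v[peak])


def oracle_prominence(v: np.ndarray, peak: int) -> float:
    """Lowest contour encircling the peak but no higher sample.

    Candidate contour levels are the trace values below the peak height.
    The acceptance predicate is monotone in the level: raising the level
    shrinks the flooded component, so a component free of higher samples
    stays free. Binary search therefore finds the lowest accepted level;
    ``oracle_prominence_linear`` cross-checks it by full enumeration.
    """
    v = np.asarray(v, float)
    h = v[peak]
    cands = np.unique(v[v < h])
    assert len(cands) > 0, "a local maximum has at least one lower sample"
    lo, hi = 0, len(cands) - 1
    # invariant: cands[hi] is accepted (level just below the peak always is)
    if _component_ok(v, peak, cands[lo]):
        return float(h - cands[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _component_ok(v, peak, cands[mid]):
            hi = mid
        else:
            lo = mid
    return float(h - cands[hi])


def oracle_prominence_linear(v: np.ndarray, peak: int) -> float:
    """Same enumeration without binary search (for short traces)."""
    v = np.asarray(v, float)
    h = v[peak]
    for level in np.unique(v[v < h]):
        if _component_ok(v, peak, level):
            return float(h - level)
    raise AssertionError("no accepted contour level found")


def oracle_all_prominences(v: np.ndarray) -> dict[int, float]:
    return {p: oracle_prominence(v, p) for p in oracle_local_maxima(v)}
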