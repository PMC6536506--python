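"""Photobleaching trace extraction and step counting.

A diffraction-limited spot whose background-subtracted intensity drops to
zero in a single abrupt step is the signature of a single fluorophore;
two-step traces indicate two fluorophores (e.g. a tandem double tag).
Steps are found by least-squares binary segmentation with a BIC-style
penalty, then filtered to downward steps of at least a minimum height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from halocount.io import ImageStack


@dataclass(eq=False)
class Trace:
    """Background-subtracted intensity time series of one spot."""

    values: np.ndarray
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs at least 2 frames")
        if not np.isfinite(self.values).all():
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


def extract_trace(
    time_stack: ImageStack | np.ndarray,
    position: tuple[int, int],
    aperture_radius: int = 3,
    bg_annulus: tuple[int, int] = (5, 8),
) -> Trace:
    """Aperture intensity minus local background, per frame.

    Signal is the mean over a circular aperture of ``aperture_radius``
    around ``position``; background is the *median* over an annulus of
    radii ``bg_annulus`` (robust to neighbouring spots).  The annulus must
    fit inside the image.
    """
    data = time_stack.data if isinstance(time_stack, ImageStack) else np.asarray(time_stack)
    if data.ndim != 3:
        raise ValueError("time stack must be 3D (t, y, x)")
    inner, outer = bg_annulus
    if not (0 < aperture_radius <= inner < outer):
        raise ValueError("need 0 < aperture_radius <= inner < outer")
    r, c = position
    nt, ny, nx = data.shape
    if r - outer < 0 or r + outer >= ny or c - outer < 0 or c + outer >= nx:
        raise ValueError(
            f"annulus of radius {outer} around {position} clipped by image {ny}x{nx}"
        )
    yy, xx = np.mgrid[-outer : outer + 1, -outer : outer + 1]
    d2 = yy**2 + xx**2
    ap = d2 <= aperture_radius**2
    ann = (d2 > inner**2) & (d2 <= outer**2)
    patch = data[:, r - outer : r + outer + 1, c - outer : c + outer + 1]
    signal = patch[:, ap].mean(axis=1)
    background = np.median(patch[:, ann], axis=1)
    frame_interval = None
    if isinstance(time_stack, ImageStack):
        frame_interval = time_stack.meta.get("frame_interval_s")
    return Trace(values=signal - background, frame_interval_s=frame_interval)


def _sse(csum: np.ndarray, csum2: np.ndarray, a: int, b: int) -> float:
    """Sum of squared residuals about the mean of values[a:b]."""
    n = b - a
    s = csum[b] - csum[a]
    s2 = csum2[b] - csum2[a]
    return float(s2 - s * s / n)


def _best_split(csum, csum2, a: int, b: int) -> tuple[int, float]:
    """Split point in (a, b) maximising the SSE reduction."""
    base = _sse(csum, csum2, a, b)
    best_t, best_gain = -1, 0.0
    for t in range(a + 1, b):
        gain = base - _sse(csum, csum2, a, t) - _sse(csum, csum2, t, b)
        if gain > best_gain:
            best_t, best_gain = t, gain
    return best_t, best_gain


def _estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise SD from first differences (steps are sparse outliers)."""
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * float(mad) / np.sqrt(2.0)


def count_steps(
    trace: Trace | np.ndarray,
    min_step: float,
    penalty: float = 3.0,
) -> tuple[int, list[int]]:
    """Count downward photobleaching steps in a trace.

    Change points are found by binary segmentation on the piecewise-
    constant least-squares model: a split is accepted while its SSE
    reduction exceeds ``penalty · sigma² · log(n)`` (sigma estimated
    robustly from first differences), a BIC-style criterion.  Candidate
    change points are then kept only if the level drop across them is
    downward with magnitude at least ``min_step``; weakest violators are
    removed first and heights re-estimated.  Returns the step count and
    the frame index of the first frame at each lowered level.  Invariant
    to a constant offset of the whole trace.
    """
    values = trace.values if isinstance(trace, Trace) else np.asarray(trace, dtype=float)
    if min_step <= 0:
        raise ValueError("min_step must be positive")
    n = values.size
    sigma = _estimate_noise_sd(values)
    # noiseless traces: any true step still has to clear min_step
    threshold = penalty * max(sigma, 1e-12) ** 2 * np.log(n)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csum2 = np.concatenate([[0.0], np.cumsum(values**2)])

    change_points: list[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        t, gain = _best_split(csum, csum2, a, b)
        if t < 0 or gain <= threshold:
            continue
        change_points.append(t)
        stack.append((a, t))
        stack.append((t, b))

    change_points.sort()
    # prune: keep only downward steps of at least min_step, re-merging
    # neighbours after each removal so heights stay consistent
    while change_points:
        bounds = [0] + change_points + [n]
        means = [
            (csum[bounds[i + 1]] - csum[bounds[i]]) / (bounds[i + 1] - bounds[i])
            for i in range(len(bounds) - 1)
        ]
        heights = [means[i + 1] - means[i] for i in range(len(means) - 1)]
        bad = [i for i, h in enumerate(heights) if h > -min_step]
        if not bad:
            break
        weakest = min(bad, key=lambda i: abs(heights[i]))
        change_points.pop(weakest)
    return len(change_points), change_points
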