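"""Diffraction-limited spot counting.

The counting procedure: maximum projection of the z-stack omitting the
first plane (which carries most of the autofluorescence), a fixed-size
crop around each cell centroid, a band-pass filter in the style of the
Crocker–Grier particle-tracking kernels, local-maximum peak calling in a
6×6 window above a robust local threshold, and assignment of peaks to the
cell whose mask contains them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from halocount.io import ImageStack
from halocount.segmentation import CellRegion


@dataclass(frozen=True)
class Spot:
    """A detected diffraction-limited peak in full-image coordinates."""

    position: tuple[int, int]
    peak_intensity: float
    cell_id: int | None = None


@dataclass(frozen=True)
class SpotConfig:
    """Spot-detection parameters.

    window
        Side of the local-maximum neighbourhood in pixels (default 6; the
        even window is anchored as offsets -w//2 .. w//2 - 1).
    noise_size / feature_size
        Band-pass scales: Gaussian smoothing sigma for pixel noise and the
        size of the local-mean kernel for slow background, pixels.
    threshold_k
        Local threshold = robust mean + threshold_k × robust SD of the
        band-passed crop.
    crop_shape
        (rows, cols) of the per-cell crop around the centroid.
    """

    window: int = 6
    noise_size: float = 1.0
    feature_size: int = 7
    threshold_k: float = 3.0
    crop_shape: tuple[int, int] = (30, 35)

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if not (self.feature_size > self.noise_size >= 1):
            raise ValueError("need feature_size > noise_size >= 1")
        if min(self.crop_shape) < 1:
            raise ValueError("crop_shape must be positive")


def max_projection(stack: ImageStack | np.ndarray, skip_first: bool = True) -> np.ndarray:
    """Per-pixel maximum over z-planes, optionally omitting plane 0.

    The first plane is skipped by default because it carries most of the
    cellular autofluorescence haze.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.ndim != 3:
        raise ValueError("stack must be 3D (z, y, x)")
    if skip_first:
        if data.shape[0] < 2:
            raise ValueError("need at least 2 planes to skip the first")
        data = data[1:]
    return data.max(axis=0)


def crop_around(
    image: np.ndarray,
    centroid: tuple[float, float],
    crop_shape: tuple[int, int] = (30, 35),
) -> tuple[np.ndarray, tuple[int, int]]:
    """Fixed-size crop centred on ``centroid`` (row, col).

    The crop always has exactly ``crop_shape``; parts falling outside the
    image are padded with the image median (not zero, to avoid edge
    artefacts in the band-pass).  Returns ``(crop, offset)`` where a crop
    pixel at (r, c) maps to full-image (r + offset[0], c + offset[1]).
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    r, c = int(round(centroid[0])), int(round(centroid[1]))
    if not (0 <= r < ny and 0 <= c < nx):
        raise ValueError(f"centroid {centroid} outside image {image.shape}")
    h, w = crop_shape
    r0, c0 = r - h // 2, c - w // 2
    crop = np.full((h, w), float(np.median(image)))
    src_r0, src_r1 = max(r0, 0), min(r0 + h, ny)
    src_c0, src_c1 = max(c0, 0), min(c0 + w, nx)
    crop[src_r0 - r0 : src_r1 - r0, src_c0 - c0 : src_c1 - c0] = image[
        src_r0:src_r1, src_c0:src_c1
    ]
    return crop, (r0, c0)


def bandpass(image: np.ndarray, noise_size: float = 1.0, feature_size: int = 7) -> np.ndarray:
    """Band-pass filter: small-scale Gaussian smoothing minus local mean.

    Suppresses pixel-scale noise (Gaussian of sigma ``noise_size``) and
    slowly varying background (boxcar mean over a
    (2·feature_size + 1)-pixel square); negative output is clipped to 0,
    so a constant image maps to zeros.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("bandpass input must be 2D")
    if not feature_size > noise_size:
        raise ValueError("feature_size must exceed noise_size")
    box = 2 * int(feature_size) + 1
    if box > min(image.shape):
        raise ValueError(
            f"feature kernel ({box} px) larger than image {image.shape}"
        )
    smoothed = ndimage.gaussian_filter(image, sigma=noise_size, mode="nearest")
    background = ndimage.uniform_filter(image, size=box, mode="nearest")
    return np.clip(smoothed - background, 0.0, None)


def _robust_stats(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    mad_sd = 1.4826 * float(np.median(np.abs(values - med)))
    return med, mad_sd


def find_peaks(
    image: np.ndarray,
    window: int = 6,
    threshold_k: float = 3.0,
    threshold: float | None = None,
) -> list[Spot]:
    """Local maxima above a robust local threshold.

    A pixel is a peak when it attains the maximum over the window×window
    neighbourhood at offsets -w//2 .. w//2 - 1 (the anchoring convention
    for even windows) and exceeds the threshold.  When no explicit
    ``threshold`` is given it defaults to median + ``threshold_k`` ×
    MAD-SD of the image; note that on a clipped band-passed image this
    robust SD collapses towards zero, so :func:`count_spots` passes a
    threshold derived from the raw crop's noise instead.  Plateau ties
    keep only the topmost-then-leftmost pixel.
    """
    image = np.asarray(image, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3")
    if threshold is None:
        med, mad_sd = _robust_stats(image.ravel())
        threshold = med + threshold_k * mad_sd
    lo, hi = window // 2, window - window // 2 - 1
    # a size-w filter is anchored at element w//2, so offsets span
    # -w//2 .. w - w//2 - 1 — exactly the even-window convention
    local_max = ndimage.maximum_filter(image, size=window, mode="nearest")
    cand = np.argwhere((image >= local_max) & (image > threshold))
    # greedy raster-order suppression resolves plateaus deterministically
    kept: list[tuple[int, int]] = []
    for r, c in cand:
        clash = False
        for kr, kc in kept:
            dr, dc = r - kr, c - kc
            if (-lo <= dr <= hi and -lo <= dc <= hi) or (
                -lo <= -dr <= hi and -lo <= -dc <= hi
            ):
                clash = True
                break
        if not clash:
            kept.append((int(r), int(c)))
    return [Spot(position=p, peak_intensity=float(image[p])) for p in kept]


def count_spots(
    stack: ImageStack | np.ndarray,
    regions: Sequence[CellRegion],
    config: SpotConfig = SpotConfig(),
    return_spots: bool = False,
    assign_tolerance: int = 1,
):
    """Count diffraction-limited spots in each segmented cell.

    Pipeline: max projection (first plane skipped) → per-cell crop around
    the centroid → band-pass → peak calling → assignment of each peak to
    the region whose mask contains it.  The local threshold is
    median(band-passed crop) + ``threshold_k`` × MAD-SD of the *raw* crop:
    the raw shot-noise scale survives the band-pass attenuated, so this is
    a conservative noise floor that is immune to the degenerate MAD of the
    mostly-zero clipped band-pass output.  Peaks falling inside a crop but
    outside the owning cell's mask (with an ``assign_tolerance``-pixel
    guard band for peak-pixel rounding at the membrane) are dropped, which
    resolves overlapping crops of neighbouring cells.  Returns a table
    with columns cell_id, length_um, n_spots (and the spot list when
    ``return_spots``).
    """
    proj = max_projection(stack, skip_first=True)
    rows = []
    all_spots: list[Spot] = []
    for region in regions:
        mask = region.mask
        if assign_tolerance > 0:
            mask = ndimage.binary_dilation(
                mask, structure=np.ones((3, 3), dtype=bool), iterations=assign_tolerance
            )
        crop, (r0, c0) = crop_around(proj, region.centroid, config.crop_shape)
        _, raw_mad_sd = _robust_stats(crop.ravel())
        bp = bandpass(crop, config.noise_size, config.feature_size)
        thr = float(np.median(bp)) + config.threshold_k * raw_mad_sd
        peaks = find_peaks(bp, window=config.window, threshold=thr)
        n = 0
        for s in peaks:
            rr, cc = s.position[0] + r0, s.position[1] + c0
            if (
                0 <= rr < mask.shape[0]
                and 0 <= cc < mask.shape[1]
                and mask[rr, cc]
            ):
                n += 1
                all_spots.append(
                    Spot(position=(rr, cc), peak_intensity=s.peak_intensity,
                         cell_id=region.cell_id)
                )
        rows.append(
            {"cell_id": region.cell_id, "length_um": region.length_um, "n_spots": n}
        )
    table = pd.DataFrame(rows, columns=["cell_id", "length_um", "n_spots"]).astype(
        {"cell_id": int, "length_um": float, "n_spots": int}
    )
    if return_spots:
        return table, all_spots
    return table
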