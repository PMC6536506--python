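"""Monte-Carlo simulation of diffraction-limited undercounting.

Two or more molecules closer than the diffraction limit (~250 nm) appear
as one spot, and the 2D projection of the 3D molecule distribution merges
molecules separated only along the optical axis.  The simulation places
N ~ Poisson(λ) molecules uniformly in a spherocylindrical cell, projects
them to the image plane, clusters them with DBSCAN (minimum cluster size
1, i.e. eps-connected components), and compares the cluster count with N
to quantify undercounting as a function of the mean copy number λ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from halocount.simgen import (
    Spherocylinder,
    _draw_total_lengths,
    sample_molecule_positions,
    LENGTH_TRUNCATION,
)

#: default λ grid: 0.5 to 15 in steps of 0.5
DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.arange(0.5, 15.0 + 1e-9, 0.5).round(2))


@dataclass(frozen=True)
class UndercountConfig:
    """Configuration of the undercounting simulation.

    eps is the clustering distance — the diffraction limit in μm.  Cell
    geometry is drawn per cell from ``length_distribution`` (total
    pole-to-pole length) with fixed ``radius``; newborn-like defaults.
    """

    eps: float = 0.25
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_cells_per_lambda: int = 10_000
    length_distribution: tuple[str, dict] = ("lognormal", {"mean": 2.5, "sigma": 0.15})
    radius: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if any(lam < 0 for lam in self.lambda_grid):
            raise ValueError("all Poisson means must be >= 0")
        if self.n_cells_per_lambda < 1:
            raise ValueError("n_cells_per_lambda must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(eq=False)
class UndercountResult:
    """Aggregated undercounting outcome at one Poisson mean."""

    lam: float
    mean_true: float
    mean_detected: float
    detection_ratio: float
    records: pd.DataFrame

    @property
    def relative_bias(self) -> float:
        """Fractional undercounting of the mean: 1 - detection_ratio."""
        return 1.0 - self.detection_ratio


def project_2d(points: np.ndarray) -> np.ndarray:
    """Project 3D molecule positions to the image plane.

    Drops the optical-axis (third) coordinate; in-plane coordinates are
    unchanged, so pairwise distances can only shrink.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    return pts[:, :2].copy()


def cluster_points(points2d: np.ndarray, eps: float) -> tuple[np.ndarray, int]:
    """Cluster projected molecules at the diffraction limit.

    DBSCAN with minimum cluster size 1: every point belongs to a cluster,
    which makes the clustering identical to the connected components of
    the graph joining points at Euclidean distance <= eps (chaining
    allowed).  Returns (labels, number of clusters).  eps = 0 merges only
    exactly coincident points.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    pts = np.asarray(points2d, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=int), 0
    pts = np.atleast_2d(pts)
    n = pts.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int), 1
    if eps == 0.0:
        _, labels = np.unique(pts, axis=0, return_inverse=True)
        return labels.astype(int), int(labels.max()) + 1
    labels = DBSCAN(eps=eps, min_samples=1).fit(pts).labels_
    return labels, int(labels.max()) + 1


def simulate_undercount(config: UndercountConfig) -> list[UndercountResult]:
    """Run the undercounting simulation over the λ grid.

    For each λ and each of ``n_cells_per_lambda`` cells: draw the cell
    geometry, draw N ~ Poisson(λ), place the N molecules uniformly in the
    spherocylinder, project to 2D, cluster at eps, and record
    (N, clusters).  Returns one result per λ with the mean input count,
    mean detected cluster count and their ratio.
    """
    rng = np.random.default_rng(config.rng_seed)
    results = []
    for lam in config.lambda_grid:
        lengths = _draw_total_lengths(
            config.n_cells_per_lambda,
            config.length_distribution,
            rng,
            truncation=LENGTH_TRUNCATION,
        )
        counts = rng.poisson(lam, size=config.n_cells_per_lambda)
        detected = np.empty(config.n_cells_per_lambda, dtype=int)
        for i, (L, N) in enumerate(zip(lengths, counts)):
            if N <= 1:
                detected[i] = N
                continue
            geom = Spherocylinder(max(L - 2 * config.radius, 0.0), config.radius)
            pos = sample_molecule_positions(geom, int(N), rng)
            _, k = cluster_points(project_2d(pos), config.eps)
            detected[i] = k
        mean_true = float(counts.mean())
        mean_detected = float(detected.mean())
        ratio = mean_detected / mean_true if mean_true > 0 else float("nan")
        results.append(
            UndercountResult(
                lam=float(lam),
                mean_true=mean_true,
                mean_detected=mean_detected,
                detection_ratio=ratio,
                records=pd.DataFrame({"n_true": counts, "n_clusters": detected}),
            )
        )
    return results


def results_table(results: Sequence[UndercountResult]) -> pd.DataFrame:
    """Bias curve as a table: lambda, mean_true, mean_detected, detection_ratio."""
    return pd.DataFrame(
        {
            "lambda": [r.lam for r in results],
            "mean_true": [r.mean_true for r in results],
            "mean_detected": [r.mean_detected for r in results],
            "detection_ratio": [r.detection_ratio for r in results],
        }
    )


def bias_threshold(
    results: Sequence[UndercountResult], max_relative_bias: float = 0.05
) -> float:
    """Largest mean copy number with acceptable undercounting of the mean.

    Scans the bias curve (1 - detection_ratio versus λ, sorted) for the
    last grid point where the relative bias is within
    ``max_relative_bias`` and linearly interpolates to where the bias
    crosses the limit.  Returns ``math.inf`` when the limit is never
    exceeded on the grid, and 0.0 when it is exceeded already at the
    smallest λ.
    """
    if not results:
        raise ValueError("no results")
    rs = sorted(results, key=lambda r: r.lam)
    lams = np.array([r.lam for r in rs])
    bias = np.array([r.relative_bias for r in rs])
    ok = bias <= max_relative_bias
    if ok.all():
        return math.inf
    if not ok[0]:
        return 0.0
    j = int(np.nonzero(~ok)[0][0]) - 1  # last ok index before first violation
    b0, b1 = bias[j], bias[j + 1]
    if b1 == b0:
        return float(lams[j])
    return float(lams[j] + (max_relative_bias - b0) * (lams[j + 1] - lams[j]) / (b1 - b0))
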