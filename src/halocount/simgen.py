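"""Synthetic microscopy generator with known ground truth.

Emulates the experimental data the counting pipeline consumes: rod-shaped
bacterial cells modelled as spherocylinders lying flat on the coverslip,
per-cell molecule numbers drawn from a Poisson distribution, molecules
placed uniformly in the cell volume, diffraction-limited Gaussian spots
rendered over a short z-stack with defocus, shot and read noise, an
autofluorescence channel for segmentation, and stepwise photobleaching
traces.  Every sampler takes an explicit seed and is bit-reproducible.

Geometry conventions
--------------------
Field coordinates are (x, y) in micrometres; the optical (z) axis is
perpendicular to the field with z = 0 at the plane containing the cell
axes.  Pixel (row, col) has its centre at x = col * pixel_size,
y = row * pixel_size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spherocylinder:
    """Cylinder of length ``cyl_length`` capped by two hemispheres.

    The standard geometric model of a rod-shaped bacterium.  The axis lies
    in the focal plane (z = 0), at in-plane angle ``orientation`` through
    ``center``.  All dimensions in micrometres.
    """

    cyl_length: float
    radius: float
    center: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.cyl_length < 0:
            raise ValueError(f"cyl_length must be >= 0, got {self.cyl_length}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")

    @property
    def total_length(self) -> float:
        """Pole-to-pole length: cylinder plus both hemispherical caps."""
        return self.cyl_length + 2.0 * self.radius

    @property
    def volume(self) -> float:
        return (
            math.pi * self.radius**2 * self.cyl_length
            + 4.0 / 3.0 * math.pi * self.radius**3
        )

    def axis_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the cylinder axis segment, field (x, y) coords."""
        h = 0.5 * self.cyl_length
        d = np.array([math.cos(self.orientation), math.sin(self.orientation)])
        c = np.asarray(self.center, dtype=float)
        return c - h * d, c + h * d

    def to_field(self, local_points: np.ndarray) -> np.ndarray:
        """Map local-frame points (axis along +x) into field coordinates."""
        pts = np.atleast_2d(np.asarray(local_points, dtype=float))
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        out = pts.copy()
        out[:, 0] = c * pts[:, 0] - s * pts[:, 1] + self.center[0]
        out[:, 1] = s * pts[:, 0] + c * pts[:, 1] + self.center[1]
        return out

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """True where 3D field-coordinate points lie inside the body.

        A point is inside iff its distance to the axis segment (which lies
        at z = 0) is at most ``radius``.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        a, b = self.axis_endpoints()
        a3 = np.array([a[0], a[1], 0.0])
        b3 = np.array([b[0], b[1], 0.0])
        return _dist_point_segment(pts, a3, b3) <= self.radius + tol


def _dist_point_segment(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to segment [a, b] (any dimension)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def _segment_segment_distance(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> float:
    """Minimum distance between 2D segments [p1,p2] and [q1,q2]."""
    if _segments_intersect(p1, p2, q1, q2):
        return 0.0
    return min(
        float(_dist_point_segment(p1[None, :], q1, q2)[0]),
        float(_dist_point_segment(p2[None, :], q1, q2)[0]),
        float(_dist_point_segment(q1[None, :], p1, p2)[0]),
        float(_dist_point_segment(q2[None, :], p1, p2)[0]),
    )


def _segments_intersect(p1, p2, q1, q2) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(q1, q2, p1)
    d2 = cross(q1, q2, p2)
    d3 = cross(p1, p2, q1)
    d4 = cross(p1, p2, q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True
    return False


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging model parameters.

    pixel_size
        Lateral sampling, μm/pixel.  Default 0.16 μm corresponds to a 100×
        objective with a 16 μm camera pixel.
    psf_sigma
        In-focus lateral Gaussian PSF width, μm.  Default 0.084 μm
        (≈ 0.21 λ/NA for λ = 0.58 μm emission, NA = 1.45), consistent with
        a ~250 nm two-point resolution limit.
    z_spacing, n_planes
        Axial plane separation (μm) and plane count of the acquired
        z-stack; planes are centred on the cell mid-plane.
    defocus_scale
        Linear growth of the PSF sigma per μm of defocus (dimensionless).
    photons_per_molecule
        Expected integrated signal of one molecule per plane, camera counts.
    background_level, read_noise_sd
        Constant offset and Gaussian read-noise SD, counts.
    autofluorescence_level
        Extra haze added inside cell footprints on the *first* z-plane of
        the spot channel (emulating residual cellular autofluorescence), and
        the cell-interior brightness of the segmentation channel.
    shot_noise
        If False, Poisson shot noise is disabled (noiseless renders for
        testing; read noise is controlled separately by read_noise_sd).
    """

    pixel_size: float = 0.16
    psf_sigma: float = 0.084
    z_spacing: float = 0.2
    n_planes: int = 5
    defocus_scale: float = 0.5
    photons_per_molecule: float = 2000.0
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    autofluorescence_level: float = 50.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        for name in (
            "pixel_size",
            "psf_sigma",
            "z_spacing",
            "photons_per_molecule",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        for name in (
            "defocus_scale",
            "background_level",
            "read_noise_sd",
            "autofluorescence_level",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def plane_z(self) -> np.ndarray:
        """Focal z of each plane, μm, relative to the cell mid-plane.

        The stack starts below the cell so that the planes remaining after
        the first (autofluorescence-heavy, discarded by the max
        projection) frame cover the cell symmetrically: plane p sits at
        (p - n/2) * z_spacing.
        """
        return (np.arange(self.n_planes) - self.n_planes / 2.0) * self.z_spacing


@dataclass(eq=False)
class GroundTruth:
    """Per-cell truth for a synthetic field.

    ``positions[i]`` is an (n_i, 3) array of (x, y, z) molecule positions
    in μm, all inside ``cells[i]``; ``counts[i]`` = n_i.
    """

    cells: list[Spherocylinder]
    counts: np.ndarray
    positions: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.cells) != len(self.counts):
            raise ValueError("cells and counts length mismatch")
        if self.positions and len(self.positions) != len(self.cells):
            raise ValueError("positions and cells length mismatch")

    def all_positions(self) -> np.ndarray:
        if not self.positions:
            return np.empty((0, 3))
        return (
            np.vstack([p for p in self.positions if len(p)])
            if any(len(p) for p in self.positions)
            else np.empty((0, 3))
        )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

#: default truncation of total cell length, μm (typical E. coli range)
LENGTH_TRUNCATION = (1.5, 6.0)


def _draw_total_lengths(
    n: int,
    distribution: tuple[str, dict] | Sequence,
    rng: np.random.Generator,
    truncation: tuple[float, float] = LENGTH_TRUNCATION,
) -> np.ndarray:
    """Draw total (pole-to-pole) cell lengths, μm, truncated to ``truncation``.

    ``distribution`` is (name, params):
      - ("lognormal", {"mean": m, "sigma": s}): lognormal with arithmetic
        mean m and log-scale SD s
      - ("uniform", {"low": a, "high": b})
      - ("fixed", {"length": L})
      - ("empirical", {"lengths": [...]}) resampled with replacement
    """
    name, params = distribution[0], dict(distribution[1])
    lo, hi = truncation
    if name == "fixed":
        out = np.full(n, float(params["length"]))
        return out
    if name == "empirical":
        lengths = np.asarray(params["lengths"], dtype=float)
        if lengths.size == 0:
            raise ValueError("empirical length list is empty")
        return rng.choice(lengths, size=n, replace=True)
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        need = n - filled
        if need == 0:
            break
        if name == "lognormal":
            m, s = float(params["mean"]), float(params.get("sigma", 0.15))
            if m <= 0 or s <= 0:
                raise ValueError("lognormal mean and sigma must be positive")
            mu = math.log(m) - 0.5 * s * s
            draw = rng.lognormal(mean=mu, sigma=s, size=need)
        elif name == "uniform":
            a, b = float(params["low"]), float(params["high"])
            if not (0 < a <= b):
                raise ValueError("uniform bounds must satisfy 0 < low <= high")
            draw = rng.uniform(a, b, size=need)
        else:
            raise ValueError(f"unknown length distribution: {name!r}")
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = keep[: n - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    if filled < n:
        raise ValueError(
            f"could not draw {n} lengths inside truncation {truncation}; "
            f"distribution {name} with {params} rarely lands in range"
        )
    return out


def sample_cell_geometries(
    n_cells: int,
    length_distribution: tuple[str, dict] = ("lognormal", {"mean": 2.5, "sigma": 0.15}),
    radius: float = 0.5,
    field_size: tuple[float, float] = (40.0, 40.0),
    rng_seed: int | np.random.Generator = 0,
    min_gap: float = 0.3,
    max_retries: int = 2000,
    length_truncation: tuple[float, float] = LENGTH_TRUNCATION,
    edge_margin: float = 0.5,
) -> list[Spherocylinder]:
    """Place non-overlapping spherocylindrical cells in a field.

    Total lengths are drawn from ``length_distribution`` (see
    ``_draw_total_lengths``); centres and orientations are uniform.  Cells
    are kept entirely inside the ``field_size`` (x, y) extent with at least
    ``edge_margin`` μm of clearance (border-touching cells are discarded by
    segmentation, so the generator keeps footprints in view) and at least
    ``min_gap`` μm apart surface-to-surface, by rejection with a retry cap.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    total_lengths = _draw_total_lengths(
        n_cells, length_distribution, rng, truncation=length_truncation
    )
    fw, fh = field_size
    placed: list[Spherocylinder] = []
    for L in total_lengths:
        cyl = max(L - 2 * radius, 0.0)
        half = L / 2.0 + edge_margin
        if 2 * half > min(fw, fh):
            raise ValueError(f"cell of length {L:.2f} μm cannot fit in field {field_size}")
        ok = False
        for _ in range(max_retries):
            cx = rng.uniform(half, fw - half)
            cy = rng.uniform(half, fh - half)
            theta = rng.uniform(0.0, math.pi)
            cand = Spherocylinder(cyl, radius, (cx, cy), theta)
            a, b = cand.axis_endpoints()
            clash = False
            for other in placed:
                oa, ob = other.axis_endpoints()
                if (
                    _segment_segment_distance(a, b, oa, ob)
                    < cand.radius + other.radius + min_gap
                ):
                    clash = True
                    break
            if not clash:
                placed.append(cand)
                ok = True
                break
        if not ok:
            density = sum(c.volume for c in placed) / (fw * fh * 2 * radius)
            raise RuntimeError(
                f"failed to place cell {len(placed)} after {max_retries} retries; "
                f"field density ~{density:.2f} is too high for field {field_size}"
            )
    return placed


def sample_molecule_positions(
    geom: Spherocylinder,
    count: int,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Place ``count`` molecules uniformly in the spherocylinder volume.

    Returns an (count, 3) array of (x, y, z) field coordinates in μm.
    Sampling is exact: a volume-weighted choice between the cylindrical
    body (uniform axial position × uniform disc) and the two hemispherical
    caps (uniform in the sphere, folded to the outward side).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return np.empty((0, 3))
    rng = np.random.default_rng(rng_seed)
    L, r = geom.cyl_length, geom.radius
    v_cyl = math.pi * r * r * L
    v_caps = 4.0 / 3.0 * math.pi * r**3
    in_cyl = rng.random(count) < v_cyl / (v_cyl + v_caps)
    local = np.empty((count, 3))

    n_c = int(in_cyl.sum())
    if n_c:
        x = rng.uniform(-L / 2.0, L / 2.0, size=n_c)
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n_c)
        rho = r * np.sqrt(rng.random(n_c))
        local[in_cyl] = np.column_stack([x, rho * np.cos(phi), rho * np.sin(phi)])

    n_s = count - n_c
    if n_s:
        # uniform in the ball: direction from normals, radius ~ r * U^(1/3)
        v = rng.normal(size=(n_s, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        rad = r * rng.random(n_s) ** (1.0 / 3.0)
        sph = v * rad[:, None]
        side = np.where(rng.random(n_s) < 0.5, -1.0, 1.0)
        sph[:, 0] = side * (L / 2.0 + np.abs(sph[:, 0]))
        local[~in_cyl] = sph

    out = np.empty((count, 3))
    out[:, :2] = geom.to_field(local[:, :2])
    out[:, 2] = local[:, 2]
    return out


def _dispersed_positions(
    geom: Spherocylinder,
    count: int,
    min_separation: float,
    rng: np.random.Generator,
    metric: str,
) -> np.ndarray | None:
    """Near-capacity separated placement by greedy farthest-point selection.

    Candidate positions form a fine grid inside the cell footprint; points
    are selected one at a time, each maximising its minimum distance to
    those already chosen (max-min dispersion).  Returns None when even the
    greedy packing cannot keep all pairs ``min_separation`` apart.  Used
    as a deterministic backstop when random dart throwing cannot reach a
    dense packing.
    """
    a, b = geom.axis_endpoints()
    r = geom.radius
    step = min_separation / 6.0
    a3 = np.array([a[0], a[1], 0.0])
    b3 = np.array([b[0], b[1], 0.0])
    ox, oy = rng.uniform(0.0, step, size=2)
    xs = np.arange(min(a[0], b[0]) - r + ox, max(a[0], b[0]) + r, step)
    ys = np.arange(min(a[1], b[1]) - r + oy, max(a[1], b[1]) + r, step)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    d_axis = _dist_point_segment(nodes, a3, b3)
    keep = d_axis <= 0.95 * r
    nodes, d_axis = nodes[keep], d_axis[keep]
    if len(nodes) < count:
        return None

    def dist2d(diff):
        if metric == "chebyshev":
            return np.abs(diff).max(axis=-1)
        return np.linalg.norm(diff, axis=-1)

    first = int(rng.integers(len(nodes)))
    chosen = [first]
    dmin = dist2d(nodes[:, :2] - nodes[first, :2])
    while len(chosen) < count:
        i = int(np.argmax(dmin))
        if dmin[i] < min_separation:
            return None
        chosen.append(i)
        dmin = np.minimum(dmin, dist2d(nodes[:, :2] - nodes[i, :2]))
    out = nodes[chosen]
    zmax = np.sqrt(np.clip(r * r - d_axis[chosen] ** 2, 0.0, None)) * 0.95
    out[:, 2] = rng.uniform(-zmax, zmax)
    return out


def sample_separated_positions(
    geom: Spherocylinder,
    count: int,
    min_separation: float,
    rng_seed: int | np.random.Generator = 0,
    max_tries: int = 10_000,
    on_failure: str = "raise",
    metric: str = "euclidean",
) -> np.ndarray:
    """Uniform positions conditioned on pairwise in-plane separation.

    Like :func:`sample_molecule_positions` but all *projected* (x, y)
    pairwise distances are at least ``min_separation`` μm — the spatially
    resolvable regime used to test the spot counter without
    diffraction-limited merging.  Molecules are placed sequentially (dart
    throwing with restarts), which reaches dense packings but is not
    exactly uniform over admissible configurations.  When the packing is
    infeasible, ``on_failure='best'`` returns the densest configuration
    found instead of raising.

    ``metric`` may be "euclidean" or "chebyshev"; the latter matches the
    square local-maximum window of a grid-based peak caller, whose
    resolution element is a box rather than a disc.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return np.empty((0, 3))
    if metric == "euclidean":
        dist = lambda d: np.linalg.norm(d, axis=-1)  # noqa: E731
    elif metric == "chebyshev":
        dist = lambda d: np.abs(d).max(axis=-1)  # noqa: E731
    else:
        raise ValueError("metric must be 'euclidean' or 'chebyshev'")
    rng = np.random.default_rng(rng_seed)
    best: np.ndarray | None = None
    best_minsep = -1.0
    for _ in range(20):
        placed = np.empty((count, 3))
        n_placed = 0
        tries = 0
        while n_placed < count and tries < max_tries:
            batch = sample_molecule_positions(geom, 64, rng)
            tries += 64
            for p in batch:
                if n_placed and (
                    dist(placed[:n_placed, :2] - p[:2]).min() < min_separation
                ):
                    continue
                placed[n_placed] = p
                n_placed += 1
                if n_placed == count:
                    break
        if n_placed == count:
            return placed
        # remember the densest packing seen: complete the partial one by
        # farthest-point placement so only a few pairs violate the spacing
        full = placed.copy()
        for j in range(n_placed, count):
            cand = sample_molecule_positions(geom, 256, rng)
            dmin = dist(full[None, :j, :2] - cand[:, None, :2]).min(axis=1)
            full[j] = cand[int(np.argmax(dmin))]
        d = dist(full[None, :, :2] - full[:, None, :2])
        ms = float(d[np.triu_indices(count, k=1)].min())
        if ms > best_minsep:
            best, best_minsep = full, ms
    for _ in range(5):
        packed = _dispersed_positions(geom, count, min_separation, rng, metric)
        if packed is not None and geom.contains(packed).all():
            return packed
    if on_failure == "best":
        return best
    raise RuntimeError(
        f"could not place {count} molecules {min_separation} um apart in a "
        f"{geom.total_length:.2f} um cell after {max_tries} tries x 20 restarts"
    )


def sample_poisson_counts(
    mean: float, n: int, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """``n`` independent Poisson(mean) draws."""
    if mean < 0:
        raise ValueError("Poisson mean must be >= 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng_seed)
    return rng.poisson(lam=mean, size=n)


def sample_ground_truth(
    cells: list[Spherocylinder],
    mean_count: float,
    rng_seed: int | np.random.Generator = 0,
) -> GroundTruth:
    """Draw Poisson counts and uniform molecule positions for each cell."""
    rng = np.random.default_rng(rng_seed)
    counts = sample_poisson_counts(mean_count, len(cells), rng)
    positions = [sample_molecule_positions(c, int(k), rng) for c, k in zip(cells, counts)]
    return GroundTruth(cells=list(cells), counts=counts, positions=positions)


def simulate_counting_field(
    n_cells: int,
    mean_count: float,
    optics: "OpticsConfig | None" = None,
    field_size: tuple[float, float] = (110.0, 110.0),
    length_distribution: tuple[str, dict] = ("uniform", {"low": 2.8, "high": 3.4}),
    min_separation: float | None = 0.75,
    separation_metric: str = "chebyshev",
    min_gap: float = 1.6,
    rng_seed: int | np.random.Generator = 0,
):
    """Build a ground-truthed validation field for the counting pipeline.

    Newborn-sized cells are placed in the field, per-cell molecule numbers
    drawn from Poisson(``mean_count``), and molecules placed uniformly —
    subject, when ``min_separation`` is given, to all projected pairwise
    distances being at least that far apart, so every remaining spot is
    spatially resolvable.  Cells whose draw cannot be packed at that
    spacing (large Poisson outliers in small cells) are dropped: the
    fixture promises resolvable spots, and for those cells no such
    configuration exists.  Without ``min_separation`` all cells are kept
    and molecules are placed freely (diffraction-limited merging then
    behaves as in real data).

    Returns ``(stack, autofluorescence_image, truth)`` with ``truth``
    covering exactly the rendered cells.
    """
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(rng_seed)
    cells = sample_cell_geometries(
        n_cells,
        length_distribution,
        field_size=field_size,
        rng_seed=rng,
        min_gap=min_gap,
    )
    counts = sample_poisson_counts(mean_count, len(cells), rng)
    kept_cells: list[Spherocylinder] = []
    kept_counts: list[int] = []
    positions: list[np.ndarray] = []
    for cell, k in zip(cells, counts):
        if min_separation is None:
            positions.append(sample_molecule_positions(cell, int(k), rng))
        else:
            try:
                positions.append(
                    sample_separated_positions(
                        cell, int(k), min_separation, rng,
                        max_tries=2000, metric=separation_metric,
                    )
                )
            except RuntimeError:
                continue
        kept_cells.append(cell)
        kept_counts.append(int(k))
    truth = GroundTruth(
        cells=kept_cells, counts=np.array(kept_counts, dtype=int), positions=positions
    )
    stack = render_zstack(kept_cells, truth, optics, rng, field_size=field_size)
    autofluo = render_autofluorescence(kept_cells, optics, rng, field_size=field_size)
    return stack, autofluo, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _field_shape(
    cells: Sequence[Spherocylinder],
    optics: OpticsConfig,
    field_size: tuple[float, float] | None,
) -> tuple[int, int, tuple[float, float]]:
    if field_size is None:
        if cells:
            ext = max(
                max(c.center[0], c.center[1]) + c.total_length / 2.0 for c in cells
            )
            field_size = (ext + 2.0, ext + 2.0)
        else:
            field_size = (10.0, 10.0)
    ny = int(round(field_size[1] / optics.pixel_size))
    nx = int(round(field_size[0] / optics.pixel_size))
    return ny, nx, field_size


def footprint_mask(
    cells: Sequence[Spherocylinder], shape: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside any cell footprint."""
    ny, nx = shape
    mask = np.zeros((ny, nx), dtype=bool)
    for c in cells:
        a, b = c.axis_endpoints()
        pad = c.radius + 2 * pixel_size
        r0 = max(int((min(a[1], b[1]) - pad) / pixel_size), 0)
        r1 = min(int((max(a[1], b[1]) + pad) / pixel_size) + 2, ny)
        c0 = max(int((min(a[0], b[0]) - pad) / pixel_size), 0)
        c1 = min(int((max(a[0], b[0]) + pad) / pixel_size) + 2, nx)
        rows, cols = np.mgrid[r0:r1, c0:c1]
        pts = np.column_stack([cols.ravel() * pixel_size, rows.ravel() * pixel_size])
        d = _dist_point_segment(pts, a, b)
        sub = (d <= c.radius).reshape(rows.shape)
        mask[r0:r1, c0:c1] |= sub
    return mask


def _render_molecule(
    img: np.ndarray, x_um: float, y_um: float, sigma_um: float, photons: float, px: float
) -> None:
    """Add one pixel-integrated Gaussian spot to ``img`` in place.

    Pixel (row, col) covers [col-0.5, col+0.5] × [row-0.5, row+0.5] in
    pixel units; the spot integrates exactly to ``photons`` over the plane.
    """
    ny, nx = img.shape
    cx, cy = x_um / px, y_um / px
    s = sigma_um / px
    halfw = int(math.ceil(5.0 * s)) + 2
    r0 = max(int(math.floor(cy)) - halfw, 0)
    r1 = min(int(math.ceil(cy)) + halfw + 1, ny)
    c0 = max(int(math.floor(cx)) - halfw, 0)
    c1 = min(int(math.ceil(cx)) + halfw + 1, nx)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    sq2 = s * math.sqrt(2.0)
    fy = 0.5 * (erf((rows + 0.5 - cy) / sq2) - erf((rows - 0.5 - cy) / sq2))
    fx = 0.5 * (erf((cols + 0.5 - cx) / sq2) - erf((cols - 0.5 - cx) / sq2))
    img[r0:r1, c0:c1] += photons * np.outer(fy, fx)


def render_zstack(
    cells: Sequence[Spherocylinder],
    truth: GroundTruth,
    optics: OpticsConfig,
    rng_seed: int | np.random.Generator = 0,
    field_size: tuple[float, float] | None = None,
):
    """Render the spot-channel z-stack for a synthetic field.

    Each molecule appears in every plane as a pixel-integrated 2D Gaussian
    whose sigma grows linearly with its defocus |z - plane focus|; the
    integrated signal per plane is ``photons_per_molecule`` (photon
    conservation under defocus).  Plane 0 additionally carries an
    autofluorescence haze inside cell footprints, so a max projection that
    skips the first plane is cleaner than one that does not.  Pixel values
    are background + signal with optional Poisson shot noise, plus Gaussian
    read noise.

    Returns an :class:`halocount.io.ImageStack` with (z, y, x) data.
    """
    from halocount.io import ImageStack

    rng = np.random.default_rng(rng_seed)
    ny, nx, field_size = _field_shape(cells, optics, field_size)
    px = optics.pixel_size
    pos = truth.all_positions()
    if pos.size:
        if (
            (pos[:, 0] < 0).any()
            or (pos[:, 0] > field_size[0]).any()
            or (pos[:, 1] < 0).any()
            or (pos[:, 1] > field_size[1]).any()
        ):
            raise ValueError("molecule position outside the field")
    planes = optics.plane_z()
    data = np.zeros((optics.n_planes, ny, nx), dtype=float)
    for p, zf in enumerate(planes):
        img = data[p]
        for m in range(pos.shape[0]):
            x, y, z = pos[m]
            sigma = optics.psf_sigma + optics.defocus_scale * abs(z - zf)
            _render_molecule(img, x, y, sigma, optics.photons_per_molecule, px)
    if optics.autofluorescence_level > 0 and len(cells):
        haze = footprint_mask(cells, (ny, nx), px) * optics.autofluorescence_level
        data[0] += haze
    data += optics.background_level
    if optics.shot_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if optics.read_noise_sd > 0:
        data += rng.normal(0.0, optics.read_noise_sd, size=data.shape)
    return ImageStack(
        data=data,
        pixel_size_um=px,
        z_spacing_um=optics.z_spacing,
        meta={"kind": "synthetic-zstack", "field_size_um": list(field_size)},
    )


def render_autofluorescence(
    cells: Sequence[Spherocylinder],
    optics: OpticsConfig,
    rng_seed: int | np.random.Generator = 0,
    field_size: tuple[float, float] | None = None,
) -> np.ndarray:
    """Single segmentation-channel image: bright cell interiors on background.

    Interior pixels sit ``autofluorescence_level`` counts above the
    background; the same noise model as the z-stack applies.
    """
    rng = np.random.default_rng(rng_seed)
    ny, nx, _ = _field_shape(cells, optics, field_size)
    img = np.full((ny, nx), float(optics.background_level))
    if cells:
        img += footprint_mask(cells, (ny, nx), optics.pixel_size) * float(
            optics.autofluorescence_level
        )
    if optics.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if optics.read_noise_sd > 0:
        img += rng.normal(0.0, optics.read_noise_sd, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# photobleaching traces
# ---------------------------------------------------------------------------


def simulate_bleach_trace(
    n_fluorophores: int,
    step_height: float,
    frames: int,
    bleach_probability_per_frame: float,
    noise_sd: float,
    rng_seed: int | np.random.Generator = 0,
):
    """Piecewise-constant photobleaching trace with known step frames.

    The trace starts at ``n_fluorophores * step_height`` and loses one
    ``step_height`` whenever a fluorophore bleaches; per-fluorophore bleach
    frames are geometric with the given per-frame probability, so a
    fluorophore may outlive the trace.  Gaussian noise of SD ``noise_sd``
    is added.  Returns ``(trace, true_step_frames)`` where the step frames
    (sorted, possibly repeated for simultaneous bleaches) are the first
    frame at the lowered level.
    """
    from halocount.photobleach import Trace

    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    if frames < 2:
        raise ValueError("frames must be >= 2")
    if not (0.0 <= bleach_probability_per_frame <= 1.0):
        raise ValueError("bleach probability must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    p = bleach_probability_per_frame
    if n_fluorophores and p > 0:
        bleach_frames = rng.geometric(p, size=n_fluorophores)
    else:
        bleach_frames = np.full(n_fluorophores, np.iinfo(np.int64).max)
    t = np.arange(frames)
    alive = (bleach_frames[:, None] > t[None, :]).sum(axis=0)
    values = alive.astype(float) * step_height
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=frames)
    true_steps = sorted(int(f) for f in bleach_frames if f < frames)
    return Trace(values=values), true_steps
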