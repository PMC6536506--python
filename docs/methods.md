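# Methods

## Scope and model

`halocount` quantifies very low-abundance proteins (of order 10 copies per
cell or fewer) in chemically fixed rod-shaped bacteria imaged by
conventional epifluorescence. Each protein carries a self-labelling tag
bound by one organic dye, so in a fixed cell every molecule appears as one
immobile diffraction-limited spot, and the per-cell copy number is the
number of spots. The package implements the four quantitative procedures
such an experiment needs — cell segmentation, spot counting, photobleaching
validation, and a Monte-Carlo bound on diffraction-limited undercounting —
plus a synthetic-microscopy generator that provides ground truth for all of
them.

## Synthetic data generator (`simgen`)

Cells are spherocylinders (cylinder of length L capped by two hemispheres
of radius r) lying flat in the focal plane. Defaults: radius 0.5 μm, total
pole-to-pole length drawn from a lognormal with arithmetic mean 2.5 μm and
log-scale SD 0.15, truncated to [1.5, 6] μm — typical *E. coli* dimensions;
the distribution (lognormal/uniform/fixed/empirical list) is configurable
because real cell-size distributions are strain- and medium-specific.
Placement is uniform with uniform orientation, rejected until cells are at
least `min_gap` (default 1.6 μm) apart surface-to-surface.

Molecule counts are Poisson(λ) per cell; positions are uniform over the
spherocylinder volume, sampled exactly by a volume-weighted choice between
the cylindrical body (uniform axial × uniform disc) and the caps (uniform
in the ball, folded outward). Rejection sampling in the bounding box is
kept in the tests as the independent oracle.

Optics: a molecule renders in each z-plane as a pixel-integrated 2D
Gaussian (difference of error functions, so the integral is exact) of
integrated signal `photons_per_molecule`; its width is
σ(z) = σ₀ + defocus_scale·|z − z_plane| with σ₀ = 0.084 μm
(≈ 0.21 λ/NA at λ = 0.58 μm, NA = 1.45 — consistent with a ~250 nm
two-point limit) and defocus_scale = 0.5 per μm, the growth rate implied by
the Gaussian-beam Rayleigh range at this NA. Pixel size defaults to
0.16 μm (100× objective, 16 μm camera pixels). The z-stack has 5 planes
200 nm apart positioned at (p − n/2)·Δz relative to the cell mid-plane: the
first (lowest) plane carries an extra autofluorescence haze inside cell
footprints and is the one the max projection discards, and the remaining
planes straddle the cell symmetrically, as one would position a stack whose
bottom frame is sacrificial. Noise is Poisson shot noise on
(background + signal) followed by Gaussian read noise; the EMCCD
excess-noise factor is not modelled. `shot_noise=False` gives noiseless
renders for exact tests.

The segmentation channel is background + `autofluorescence_level` inside
cell footprints, same noise model, no blur — segmentation operates on
contrast, and a sub-pixel-accurate rim is not what it is tested on.

Photobleaching traces are piecewise constant: `n_fluorophores` independent
survival times, geometric per frame, each step dropping the level by
`step_height`, plus Gaussian noise. A fluorophore may outlive the trace;
the recorded truth is the steps that occur within it.

`sample_separated_positions` additionally enforces a minimum pairwise
distance between the *projected* molecule positions (dart throwing, then a
greedy farthest-point packing over a fine in-footprint grid as backstop).
It supports Euclidean and Chebyshev metrics; the Chebyshev option exists
because the spot detector's local-maximum window is a square, so its
resolution element is a box. This conditioned sampler is a test fixture —
real molecules do not avoid each other — and `simulate_counting_field`
documents that cells whose Poisson draw cannot be packed at the requested
spacing are dropped from the fixture.

## Segmentation

`segment_cells` (autofluorescence channel): Gaussian smoothing (σ = 1 px),
Sobel gradient magnitude, Otsu threshold on the gradient, dilation with a
2-px disk, hole filling, erosion with a 3-px disk, connected components.
The erosion is one pixel larger than the dilation because the thresholded
gradient band straddles the true edge by about a pixel on each side;
without the correction cell lengths come out ~0.3 μm long. Regions smaller
than `min_area` (50 px) or touching the border are removed, and an explicit
exclusion list keyed on label id replaces interactive manual curation; every
removal is reported with its reason.

Cell length and width are the pixel extents of the region projected onto
its principal axes (+1 px for pixel width) times the pixel size; this gives
the pole-to-pole length of a rod (a moment-based ellipse axis would not),
is exact for axis-aligned rectangles, and is invariant under rotation and
translation. The newborn filter keeps cells with length strictly below
3.5 μm, the operational definition of a recently divided cell; conditioning
on size avoids the ~2× count inflation from pre-division cells.

`segment_by_intensity` (concentration quantification): subtract a
morphological opening (structuring disk larger than a cell width, so
opening erases cells), Gaussian-smooth, and threshold against a robust fit
of the non-cell intensity distribution — median + k·(MAD-based SD), k = 5,
fitted on the lowest 80% of pixels. From each connected component the
dimmest `low_fraction` (default 0.2) of pixels is trimmed, which splits
touching cells; components are then re-labelled. `mean_intensity_per_area`
is the plain mask mean — the per-cell protein-concentration proxy.

## Spot counting

The counting pipeline is: maximum projection over z omitting the first
plane (which carries most of the cellular autofluorescence) → a 30 × 35 px
crop around each cell centroid (median-padded at borders so the shape is
always exact) → band-pass filter → local-maximum peak calling → assignment
of peaks to cells.

The band-pass is the particle-tracking classic: Gaussian smoothing at the
noise scale (σ = 1 px) minus a boxcar local mean at the feature scale
(half-width 7 px), negatives clipped. Peaks are pixels that attain the
maximum of their 6 × 6 neighbourhood (offsets −3..+2 — the anchoring
convention for an even window; plateau ties keep the topmost-then-leftmost
pixel) and exceed the local threshold. The threshold is the median of the
band-passed crop plus `threshold_k` (default 3) times the MAD-SD of the
*raw* crop: after clipping, most band-passed pixels are exactly zero and a
MAD on them degenerates, while the raw crop's robust SD is the shot-noise
scale the band-pass attenuates — an intentionally conservative floor.
Measured on blank noise fields it yields zero false calls; a single
in-focus molecule at default signal levels exceeds it ~20-fold.

A peak belongs to the cell whose mask contains it; masks are dilated by
`assign_tolerance` (1 px) for this test because the peak pixel of a
membrane-proximal molecule rounds outside the segmented boundary about
half the time. Peaks in a crop but in no (dilated) mask are dropped, which
resolves overlapping crops of neighbouring cells. Counting is deterministic
and monotone in `threshold_k`.

Resolution: the 6 × 6 window merges any two maxima whose pixel offsets both
lie within ±3, i.e. within a ~0.5 μm box at the default pixel size —
considerably coarser than the ~250 nm optical limit. Two same-brightness
spots 2 px apart merge into one call; 10 px apart they are always two. The
end-to-end recovery fixture therefore enforces ≥ 0.75 μm Chebyshev
separation; on such cells exact per-cell recovery is 97–100% and the mean
is recovered within ~1%. On unconditioned Poisson(5) placements the counts
are biased low by ~5%, which is the expected diffraction/window merging —
quantified independently by the undercounting simulation.

## Photobleaching analysis

`extract_trace`: per frame, mean over a circular aperture (radius 3 px)
minus the median over a 5–8 px annulus (median, not mean, so a neighbouring
spot in the annulus does not bias the background). `count_steps`: binary
segmentation on the piecewise-constant least-squares model; a split is
accepted while its SSE reduction exceeds penalty·σ²·ln n with σ estimated
robustly from first differences and penalty = 3 (the BIC cost of one change
point is ≈ 2σ²ln n; the margin suppresses spurious splits). Candidate
change points are then pruned to downward steps of at least `min_step`,
weakest first, re-estimating heights after each removal. At step SNR 5 the
0/1/2-step classification is 97–99% correct with step locations within ±1
frame; errors are dominated by two fluorophores bleaching on the same or
adjacent frames, which no step counter can separate. The count is invariant
to a constant trace offset.

## Undercounting simulation

Molecules are placed uniformly in a spherocylinder (newborn-like lognormal
length, mean 2.5 μm), projected to the image plane by dropping the optical
axis coordinate, and clustered with DBSCAN at eps = 0.25 μm (the two-point
diffraction limit) with minimum cluster size 1 — equivalent to connected
components of the ≤ eps proximity graph, which is how the brute-force
union-find oracle checks it. The detected count is the number of clusters;
the detection ratio mean(clusters)/mean(N) as a function of λ is the bias
curve, and `bias_threshold` interpolates the largest λ whose relative bias
stays within a tolerance (default 5%).

With these defaults the ratio is ≈ 0.92 at λ = 2, ≈ 0.80 at λ = 5 and
≈ 0.64 at λ = 10 (10⁴ cells per λ), so the 5% threshold sits near λ ≈ 1.2.
The threshold is highly sensitive to the unquantified tolerance: a 25%
tolerance puts it near λ ≈ 7. Both the cell-size distribution and the
tolerance are exposed as parameters for this reason. eps = 0 gives a ratio
of exactly 1 (nothing merges), and the ratio is monotone non-increasing in
both λ and eps.

## Statistics

`ks_two_sample` wraps the asymptotic two-sample Kolmogorov–Smirnov test
(samples are hundreds of cells; no exact small-sample enumeration), with
the 5% significance convention for declaring two count distributions
similar. `aggregate_replicates` bins per-cell counts (tail pooled into the
last bin), averages proportions across replicates and reports the spread as
the SD across replicates by default with a SEM option — the two readings of
"standard deviation of the mean" in common usage. `dose_response`
summarises per-cell mean intensities per induction condition, preserving
input order.

## Reproducibility and problem sizes

Every sampler takes an explicit seed and identical seeds give bit-identical
outputs. Output tables carry a hash of the full parameter set, and the run
report enumerates every dropped region with its reason. The validation
suite uses 10⁵ draws for sampler moments, 10⁴ cells per λ for the
undercounting monotonicity checks (3 × 10³ per grid point for the bias
curve), 200 cells for end-to-end recovery, 500 traces for bleaching
classification and 10³ random point sets for the clustering oracle — sizes
at which the Monte-Carlo error is several times smaller than the margins
being asserted.

## Known limitations

The generator does not model EMCCD excess noise, camera gain calibration,
non-Gaussian PSF structure, cell growth, or spatially varying background;
passing tests show the analysis logic is correct under the stated imaging
model, not that the defaults match any particular microscope. Segmentation
is contrast-based and untested on phase-contrast or crowded fields. The
undercounting model treats resolvability as a hard distance threshold and
ignores localization noise. Step counting does not model blinking or
intensity-based stoichiometry beyond 0/1/2 steps.
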