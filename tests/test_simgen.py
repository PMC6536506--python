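"""Generator tests: geometry sampling, molecule placement, rendering, traces."""

import numpy as np
import pytest

from halocount.io import ImageStack
from halocount.simgen import (
    GroundTruth,
    OpticsConfig,
    Spherocylinder,
    footprint_mask,
    render_autofluorescence,
    render_zstack,
    sample_cell_geometries,
    sample_molecule_positions,
    sample_poisson_counts,
    sample_separated_positions,
    simulate_bleach_trace,
    _segment_segment_distance,
)


class TestSpherocylinder:
    def test_total_length_and_volume(self):
        g = Spherocylinder(2.0, 0.5)
        assert g.total_length == pytest.approx(3.0)
        assert g.volume == pytest.approx(np.pi * 0.25 * 2.0 + 4 / 3 * np.pi * 0.125)

    @pytest.mark.parametrize("bad", [dict(cyl_length=-0.1, radius=0.5),
                                     dict(cyl_length=1.0, radius=0.0)])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ValueError):
            Spherocylinder(**bad)

    def test_contains_axis_points_and_outside(self, single_cell):
        inside = np.array([[5.0, 5.0, 0.0], [6.0, 5.0, 0.4], [6.45, 5.0, 0.0]])
        outside = np.array([[5.0, 5.0, 0.6], [6.6, 5.0, 0.0], [5.0, 5.6, 0.0]])
        assert single_cell.contains(inside).all()
        assert not single_cell.contains(outside).any()


class TestCellGeometries:
    def test_zero_cells(self):
        assert sample_cell_geometries(0) == []

    def test_uniform_lengths_satisfy_newborn_bound(self):
        cells = sample_cell_geometries(
            1000, ("uniform", {"low": 2.0, "high": 3.4}),
            field_size=(400.0, 400.0), rng_seed=0,
        )
        lengths = np.array([c.total_length for c in cells])
        assert len(cells) == 1000
        assert (lengths < 3.5).all()

    def test_lognormal_sample_mean(self):
        cells = sample_cell_geometries(
            1000, ("lognormal", {"mean": 2.5, "sigma": 0.15}),
            field_size=(400.0, 400.0), rng_seed=1,
        )
        lengths = np.array([c.total_length for c in cells])
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 2.5) < 3 * se

    def test_cells_do_not_overlap(self):
        cells = sample_cell_geometries(30, field_size=(50.0, 50.0), rng_seed=2,
                                       min_gap=0.3)
        for i, a in enumerate(cells):
            for b in cells[i + 1:]:
                pa, pb = a.axis_endpoints()
                qa, qb = b.axis_endpoints()
                d = _segment_segment_distance(pa, pb, qa, qb)
                assert d >= a.radius + b.radius + 0.3 - 1e-9

    def test_placement_failure_reports_density(self):
        with pytest.raises((RuntimeError, ValueError)):
            sample_cell_geometries(200, field_size=(8.0, 8.0), rng_seed=3,
                                   max_retries=50)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError):
            sample_cell_geometries(3, ("weibull", {"k": 2}), rng_seed=0)

    def test_seed_determinism(self):
        a = sample_cell_geometries(10, rng_seed=7)
        b = sample_cell_geometries(10, rng_seed=7)
        assert all(
            x.center == y.center and x.cyl_length == y.cyl_length for x, y in zip(a, b)
        )


class TestMoleculePositions:
    def test_empty(self, single_cell):
        assert sample_molecule_positions(single_cell, 0).shape == (0, 3)

    def test_negative_count_rejected(self, single_cell):
        with pytest.raises(ValueError):
            sample_molecule_positions(single_cell, -1)

    def test_degenerate_radius_collapses_to_axis(self):
        g = Spherocylinder(2.0, 1e-6, center=(0.0, 0.0))
        pts = sample_molecule_positions(g, 200, rng_seed=0)
        assert np.abs(pts[:, 1]).max() <= 1e-6
        assert np.abs(pts[:, 2]).max() <= 1e-6

    def test_all_points_inside(self, single_cell):
        pts = sample_molecule_positions(single_cell, 5000, rng_seed=1)
        assert single_cell.contains(pts).all()

    def test_cap_fraction_matches_rejection_oracle(self, single_cell):
        """Volume-weighted sampler agrees with brute-force rejection sampling."""
        n = 20_000
        pts = sample_molecule_positions(single_cell, n, rng_seed=2)
        x_local = pts[:, 0] - single_cell.center[0]  # orientation 0
        frac = float((np.abs(x_local) > single_cell.cyl_length / 2).mean())

        # oracle: rejection sampling in the bounding box
        rng = np.random.default_rng(3)
        box = rng.uniform(
            [-1.5, -0.5, -0.5], [1.5, 0.5, 0.5], size=(4 * n, 3)
        )
        ref = Spherocylinder(2.0, 0.5)
        kept = box[ref.contains(box)][:n]
        frac_oracle = float((np.abs(kept[:, 0]) > 1.0).mean())

        analytic = (4 * 0.5 / 3) / (2.0 + 4 * 0.5 / 3)  # = 0.25
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(frac - analytic) < 4 * se
        assert abs(frac_oracle - analytic) < 4 * se

    def test_separated_positions_respect_spacing(self, single_cell):
        for metric, dist in (
            ("euclidean", lambda d: np.linalg.norm(d, axis=-1)),
            ("chebyshev", lambda d: np.abs(d).max(axis=-1)),
        ):
            pts = sample_separated_positions(
                single_cell, 6, 0.6, rng_seed=4, metric=metric
            )
            assert single_cell.contains(pts).all()
            d = dist(pts[None, :, :2] - pts[:, None, :2])
            iu = np.triu_indices(6, k=1)
            assert d[iu].min() >= 0.6 - 1e-9


class TestPoissonCounts:
    def test_zero_mean(self):
        assert (sample_poisson_counts(0.0, 100, 0) == 0).all()

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            sample_poisson_counts(-1.0, 5, 0)

    def test_moments(self):
        draws = sample_poisson_counts(5.0, 100_000, 1)
        se_mean = np.sqrt(5.0 / draws.size)
        assert abs(draws.mean() - 5.0) < 3 * se_mean
        # Var[S^2] for Poisson ~ (2*lam^2 + lam)/n
        se_var = np.sqrt((2 * 25 + 5) / draws.size)
        assert abs(draws.var(ddof=1) - 5.0) < 3 * se_var

    def test_fixed_seed_reproducible(self):
        a = sample_poisson_counts(4.9, 10, 11)
        b = sample_poisson_counts(4.9, 10, 11)
        assert (a == b).all()


class TestRendering:
    def test_no_molecules_no_noise_constant_background(self, noiseless_optics):
        cells = [Spherocylinder(2.0, 0.5, (5.0, 5.0))]
        truth = GroundTruth(cells=cells, counts=np.array([0]), positions=[np.empty((0, 3))])
        stack = render_zstack(cells, truth, noiseless_optics, 0, field_size=(10.0, 10.0))
        assert np.allclose(stack.data, noiseless_optics.background_level)

    def test_stack_depth_and_z_range(self, optics, single_cell):
        truth = GroundTruth(cells=[single_cell], counts=np.array([0]),
                            positions=[np.empty((0, 3))])
        stack = render_zstack([single_cell], truth, optics, 0, field_size=(10.0, 10.0))
        assert isinstance(stack, ImageStack)
        assert stack.n_planes == 5
        assert stack.z_range_um == pytest.approx(0.8)

    def test_integrated_signal_matches_photon_budget(self, noiseless_optics):
        """The pixel-integrated Gaussian sums to photons_per_molecule."""
        cell = Spherocylinder(2.0, 0.5, (5.0, 5.0))
        pos = np.array([[5.0, 5.0, 0.0]])
        truth = GroundTruth(cells=[cell], counts=np.array([1]), positions=[pos])
        stack = render_zstack([cell], truth, noiseless_optics, 0, field_size=(10.0, 10.0))
        # the in-focus plane (z=+0.1 given the plane layout) integrates fully
        plane = stack.data[3] - noiseless_optics.background_level
        assert plane.sum() == pytest.approx(
            noiseless_optics.photons_per_molecule, rel=0.01
        )

    def test_rendering_is_linear(self, noiseless_optics):
        cell = Spherocylinder(2.0, 0.5, (5.0, 5.0))
        p1 = np.array([[4.5, 5.0, 0.0]])
        p2 = np.array([[5.5, 5.2, 0.1]])
        def render(pos, k):
            truth = GroundTruth(cells=[cell], counts=np.array([k]), positions=[pos])
            return render_zstack([cell], truth, noiseless_optics, 0,
                                 field_size=(10.0, 10.0)).data
        both = render(np.vstack([p1, p2]), 2)
        a, b = render(p1, 1), render(p2, 1)
        assert np.allclose(both, a + b - noiseless_optics.background_level, atol=1e-9)

    def test_molecule_outside_field_rejected(self, noiseless_optics):
        cell = Spherocylinder(2.0, 0.5, (5.0, 5.0))
        pos = np.array([[20.0, 5.0, 0.0]])
        truth = GroundTruth(cells=[cell], counts=np.array([1]), positions=[pos])
        with pytest.raises(ValueError, match="outside"):
            render_zstack([cell], truth, noiseless_optics, 0, field_size=(10.0, 10.0))

    def test_first_plane_carries_autofluorescence_haze(self, single_cell):
        opt = OpticsConfig(shot_noise=False, read_noise_sd=0.0,
                           autofluorescence_level=40.0)
        truth = GroundTruth(cells=[single_cell], counts=np.array([0]),
                            positions=[np.empty((0, 3))])
        stack = render_zstack([single_cell], truth, opt, 0, field_size=(10.0, 10.0))
        mask = footprint_mask([single_cell], stack.data.shape[1:], opt.pixel_size)
        assert stack.data[0][mask].mean() > stack.data[1][mask].mean() + 30


class TestAutofluorescence:
    def test_no_cells_pure_background(self, optics):
        img = render_autofluorescence([], optics, 0, field_size=(8.0, 8.0))
        assert abs(img.mean() - optics.background_level) < 2.0

    def test_interior_brighter_than_exterior_noiseless(self, noiseless_optics, single_cell):
        opt = OpticsConfig(shot_noise=False, read_noise_sd=0.0, autofluorescence_level=50.0)
        img = render_autofluorescence([single_cell], opt, 0, field_size=(10.0, 10.0))
        mask = footprint_mask([single_cell], img.shape, opt.pixel_size)
        assert img[mask].min() > img[~mask].max()

    def test_component_count_matches_cells(self, optics):
        from skimage.measure import label

        cells = sample_cell_geometries(5, field_size=(30.0, 30.0), rng_seed=5,
                                       min_gap=1.0)
        mask = footprint_mask(cells, (188, 188), optics.pixel_size)
        assert label(mask).max() == 5


class TestBleachTraces:
    def test_zero_fluorophores(self):
        trace, steps = simulate_bleach_trace(0, 100.0, 50, 0.05, 1.0, 0)
        assert steps == []
        assert np.abs(trace.values).max() < 6.0

    def test_single_step_noiseless(self):
        trace, steps = simulate_bleach_trace(1, 100.0, 100, 0.1, 0.0, 3)
        assert len(steps) == 1
        t = steps[0]
        assert np.allclose(trace.values[:t], 100.0)
        assert np.allclose(trace.values[t:], 0.0)

    def test_two_fluorophores_two_steps(self):
        # tandem double-tag emulation: two independent bleach events
        for seed in range(5):
            trace, steps = simulate_bleach_trace(2, 100.0, 200, 0.1, 0.0, seed)
            assert trace.values[0] == pytest.approx(200.0)
            assert len(steps) == 2

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_bleach_trace(1, 100.0, 50, 1.5, 1.0, 0)
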