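import numpy as np
import pytest

from halocount.simgen import (
    GroundTruth,
    OpticsConfig,
    Spherocylinder,
    render_autofluorescence,
    render_zstack,
    sample_cell_geometries,
    sample_separated_positions,
)


@pytest.fixture(scope="session")
def optics() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture(scope="session")
def noiseless_optics() -> OpticsConfig:
    return OpticsConfig(shot_noise=False, read_noise_sd=0.0, autofluorescence_level=0.0)


@pytest.fixture(scope="session")
def five_cell_field(optics):
    """High-contrast field of 5 well-separated cells with counts {0,1,3,2,4}.

    Spots inside each cell are mutually resolvable (>= 0.75 um apart on
    both image axes).  Returns (cells, truth, stack, autofluorescence).
    """
    rng = np.random.default_rng(101)
    cells = sample_cell_geometries(
        5,
        ("uniform", {"low": 2.4, "high": 3.2}),
        field_size=(30.0, 30.0),
        rng_seed=rng,
        min_gap=1.6,
    )
    counts = np.array([0, 1, 3, 2, 4])
    positions = [
        sample_separated_positions(c, int(k), 0.75, rng, metric="chebyshev")
        for c, k in zip(cells, counts)
    ]
    truth = GroundTruth(cells=list(cells), counts=counts, positions=positions)
    stack = render_zstack(cells, truth, optics, rng, field_size=(30.0, 30.0))
    autofluo = render_autofluorescence(cells, optics, rng, field_size=(30.0, 30.0))
    return cells, truth, stack, autofluo


def match_region_to_cell(region, cells, pixel_size):
    """Index of the generating cell nearest to a segmented region centroid."""
    rc = np.array([region.centroid[1] * pixel_size, region.centroid[0] * pixel_size])
    return int(np.argmin([np.hypot(*(np.asarray(c.center) - rc)) for c in cells]))


@pytest.fixture
def single_cell() -> Spherocylinder:
    return Spherocylinder(cyl_length=2.0, radius=0.5, center=(5.0, 5.0), orientation=0.0)
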