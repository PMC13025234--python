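"""Shared fixtures: small noiseless synthetic fields with ground truth."""

import numpy as np
import pytest

from nucarch.geometry import ImageGeometry
from nucarch.synthdata import (
    CompartmentSpec,
    NoiseSpec,
    NuclearPhenotypeSpec,
    generate_image,
)


@pytest.fixture(scope="session")
def geom2d():
    return ImageGeometry((1024, 1024), (0.1, 0.1))


@pytest.fixture(scope="session")
def image2d_noiseless(geom2d):
    """12 perturbed nuclei with nested compartments, no noise or blur."""
    spec = NuclearPhenotypeSpec(
        n_cells=12, mean_size=100.0, size_cv=0.15,
        irregularity_amplitude=0.08, irregularity_harmonics=4,
    )
    comps = [
        CompartmentSpec("nucleolin", 2.5, 1.6, 0.35),
        CompartmentSpec("fibrillarin", 2.0, 0.5, 0.35, nesting="nucleolin"),
        CompartmentSpec("sc35", 6.0, 0.9, 0.3),
    ]
    return generate_image(spec, comps, NoiseSpec.none(), geom2d, seed=424242)


@pytest.fixture(scope="session")
def geom3d():
    return ImageGeometry((48, 256, 256), (0.3, 0.3, 0.3))


@pytest.fixture(scope="session")
def image3d_noiseless(geom3d):
    """8 spherical nuclei with compartments, no noise or blur."""
    spec = NuclearPhenotypeSpec(
        n_cells=8, mean_size=250.0, size_cv=0.15,
        irregularity_amplitude=0.0, irregularity_harmonics=0,
    )
    comps = [
        CompartmentSpec("nucleolin", 2.0, 6.0, 0.3),
        CompartmentSpec("fibrillarin", 1.5, 0.8, 0.3, nesting="nucleolin"),
        CompartmentSpec("sc35", 5.0, 1.2, 0.3),
    ]
    return generate_image(spec, comps, NoiseSpec.none(), geom3d, seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
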