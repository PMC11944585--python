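import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for reference_table

from chromoplate.synthetic import (
    PlateSpec,
    generate_dataset,
    make_profile_set,
    render_plate,
)


@pytest.fixture(scope="session")
def profiles4():
    return make_profile_set(4, seed=11)


@pytest.fixture(scope="session")
def plate_render(profiles4):
    """One noise-free-ish plate with known geometry, plus its spec."""
    spec = PlateSpec(center_xy=(150.0, 160.0), radius=80.0,
                     background="light", noise_sd=6.0)
    img, truth = render_plate(profiles4[0], spec, canvas=(512, 512), seed=7)
    return img, truth, profiles4[0]


@pytest.fixture(scope="session")
def dataset4x30(tmp_path_factory, profiles4):
    """The default study-scale synthetic dataset: 4 species x 30 images."""
    root = tmp_path_factory.mktemp("synth4x30")
    manifest = generate_dataset(profiles4, 30, root, seed=202)
    return root, manifest


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 2-species x 3-image dataset on a small canvas, for fast I/O tests."""
    root = tmp_path_factory.mktemp("synth_tiny")
    profiles = make_profile_set(2, seed=5)
    manifest = generate_dataset(
        profiles, 3, root, seed=9, canvas=(160, 160), radius_range=(40.0, 60.0)
    )
    return root, manifest


@pytest.fixture(scope="session")
def color_arrays():
    """Directly synthesized colour-separable arrays (no rendering/IO):
    4 classes of 64x64 images distinguished by mean colour."""
    rng = np.random.default_rng(77)
    centroids = np.array(
        [[0.8, 0.2, 0.2], [0.2, 0.8, 0.2], [0.2, 0.2, 0.8], [0.75, 0.75, 0.15]]
    )
    n_per = 12
    y = np.repeat(np.arange(4), n_per)
    x = centroids[y][:, None, None, :] + rng.normal(0, 0.06, (4 * n_per, 64, 64, 3))
    return np.clip(x, 0, 1), y
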