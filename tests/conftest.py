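import numpy as np
import pytest

from fluormargin.synthetic import (
    SimulationConfig,
    generate_label_map,
    render_fluorescence_image,
    sample_biopsies,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(dose_group="high", seed=1)


@pytest.fixture(scope="session")
def specimen(default_config):
    """One simulated high-dose specimen shared across tests (read-only)."""
    label_map, border = generate_label_map(default_config, 0)
    image = render_fluorescence_image(label_map, default_config)
    records = sample_biopsies(label_map, border, default_config)
    return label_map, border, image, records


def uniform_image(rgb, shape=(32, 32), pixel_size_mm=0.5, dose_group="high"):
    """Single-color 8-bit test image."""
    from fluormargin.types import SpecimenImage

    arr = np.zeros(shape + (3,), dtype=np.uint8)
    arr[..., 0], arr[..., 1], arr[..., 2] = rgb
    return SpecimenImage(arr, pixel_size_mm, dose_group).validate()


@pytest.fixture
def make_uniform_image():
    return uniform_image
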