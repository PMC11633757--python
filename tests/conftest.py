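import numpy as np
import pytest

from endoseg.images import AcquisitionSpec, MultimodalImage
from endoseg.synthetic import PhantomSpec, generate_label_map, render_multimodal


@pytest.fixture(scope="session")
def phantom_spec():
    """Small six-class phantom specification used across tests."""
    return PhantomSpec(shape=(320, 320), seed=7, blob_scale_px=20)


@pytest.fixture(scope="session")
def label_map(phantom_spec):
    return generate_label_map(phantom_spec)


@pytest.fixture(scope="session")
def mosaic(label_map):
    return render_multimodal(label_map, seed=1)


@pytest.fixture(scope="session")
def acquisition():
    """Tile geometry with exact 10%-overlap arithmetic (tile 120, step 108)."""
    return AcquisitionSpec(tile_px=120, overlap_frac=0.10, vignette_strength=0.0, grid=(2, 2))


@pytest.fixture
def flat_field_image():
    return MultimodalImage(np.full((3, 512, 512), 0.5))
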