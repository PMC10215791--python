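import numpy as np
import pytest

from vesica import phantom_sim as ps


@pytest.fixture(scope="session")
def small_cfg():
    """Coarse-pixel imaging grid covering the same physical field of view
    as the default scanner (so 300 mL phantoms still fit), cheap to render."""
    return ps.ImagingConfig(grid_height=128, grid_width=192, pixel_spacing=0.9)


@pytest.fixture(scope="session")
def tiny_samples(small_cfg):
    """16 positive + 16 negative biplane samples with an 75/25 split."""
    rng = np.random.default_rng(42)
    samples, splits = [], []
    for i in range(16):
        samples.append(ps.generate_sample(rng.uniform(50, 300), small_cfg, rng))
        splits.append("train" if i < 12 else "val")
    for i in range(16):
        samples.append(ps.generate_negative(small_cfg, rng))
        splits.append("train" if i < 12 else "val")
    return samples, splits
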