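import os

# pin BLAS threading before numpy loads: on a single core, oversubscribed
# thread pools make small GEMMs erratically slow
for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np
import pytest

from denseunet.phantom import PhantomConfig, generate_case, preset
from denseunet.preprocess import save_slice_dataset, slice_and_filter


@pytest.fixture
def rng():
    return np.random.default_rng(20240118)


@pytest.fixture(scope="session")
def small_case():
    """One small phantom case (64x64x24), deterministic."""
    cfg = preset("small", seed=11, n_cases=1)
    return generate_case(cfg, 0)


@pytest.fixture(scope="session")
def tiny_store(tmp_path_factory):
    """A small on-disk slice store: 4 phantom cases at 32x32x12, crop 24.

    Sized so a couple of training epochs run in seconds; the 24-pixel crop
    is divisible by 4, matching the 3-scale test model.
    """
    cfg = PhantomConfig(
        volume_shape=(32, 32, 12),
        compartment_radii=(6.0, 3.5, 2.0),
        center_jitter=1.0,
        seed=5,
        n_cases=4,
    )
    samples = []
    for i in range(cfg.n_cases):
        vol, lab = generate_case(cfg, i)
        samples.extend(
            slice_and_filter(vol, lab, crop_size=(24, 24), case_id=f"case{i:03d}")
        )
    out = tmp_path_factory.mktemp("store")
    save_slice_dataset(samples, out)
    return out
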