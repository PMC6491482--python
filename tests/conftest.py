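import numpy as np
import pytest

from spherostack.synthetic import SpheroidSpec, generate_stack


@pytest.fixture(scope="session")
def small_stack():
    """One 32-slice hemisphere stack with ground truth, shared."""
    spec = SpheroidSpec(seed=1, n_slices=32)
    return generate_stack(spec)


@pytest.fixture(scope="session")
def tiny_stack():
    """A fast 12-slice, 128 px stack for pipeline/CLI plumbing tests."""
    spec = SpheroidSpec(
        seed=4,
        n_slices=12,
        height=128,
        width=128,
        radius_um=18.0,
        nuclei_per_slice=(5, 10),
    )
    return generate_stack(spec)


def disc_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
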