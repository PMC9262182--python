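import numpy as np
import pytest

from lungdens.densitometry import DensityVolume, LungMask, Phase
from lungdens.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic phantom with moderate trapping, shared across tests."""
    spec = PhantomSpec(
        mu_ins=-880.0,
        sigma_parenchyma=30.0,
        delta_exp=150.0,
        trapped_fraction=0.3,
        noise_sigma=0.0,
        seed=11,
    )
    ins, exp, ins_mask, exp_mask, expected = generate_phantom(spec)
    return spec, ins, exp, ins_mask, exp_mask, expected


def random_grid(rng, max_edge=5):
    """Random tiny labelled HU grid for oracle-equivalence checks.

    HU values are drawn on a coarse lattice so threshold ties occur.
    """
    shape = tuple(rng.integers(1, max_edge + 1, size=3))
    values = rng.choice(np.arange(-1000, 101, 50), size=shape).astype(float)
    labels = rng.choice([0, 1, 2], size=shape, p=[0.3, 0.35, 0.35]).astype(np.uint8)
    if not (labels > 0).any():
        labels.flat[rng.integers(labels.size)] = 1
    spacing = tuple(rng.uniform(0.5, 3.0, size=3))
    vol = DensityVolume(values, spacing, Phase.EXPIRATORY)
    return vol, LungMask(labels)
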