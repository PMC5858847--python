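import numpy as np
import pytest

import hsibrain as hb


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: 40x40 pixels, 120 bands, default class angles."""
    return hb.PhantomSpec(H=40, W=40, B=120, seed=7)


@pytest.fixture(scope="session")
def small_ppcfg():
    """Crop/average config scaled to the 120-band phantom (keeps 103, -> 32)."""
    return hb.PreprocessConfig(crop_low=8, crop_high=112, target_bands=32)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return hb.make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_chain(small_phantom, small_ppcfg):
    raw, refs, _truth = small_phantom
    return hb.run_chain(raw, refs, small_ppcfg)


@pytest.fixture(scope="session")
def small_dataset(small_phantom, small_chain, small_spec):
    _raw, _refs, truth = small_phantom
    reduced, _ = small_chain
    sparse = hb.sample_gold_standard(truth, 0.25, seed=small_spec.seed)
    return hb.extract_dataset([(reduced, sparse)])


def random_prob_map(rng, H, W, C=4):
    p = rng.random((H, W, C)) + 1e-6
    return hb.ProbabilityMap(p / p.sum(axis=2, keepdims=True))
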