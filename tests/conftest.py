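import numpy as np
import pytest

from fafseg import generate_scene, simulate_expert_annotations


def random_blob_mask(rng, shape=(64, 64), n_blobs=2, radius_range=(3, 9)) -> np.ndarray:
    """Small random multi-blob mask: the shapes the metrics operate on."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        r = rng.uniform(*radius_range)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


@pytest.fixture(scope="session")
def small_scene():
    """A compact synthetic scene shared by tests that only read it."""
    return generate_scene(width=160, height=160, n_hf_components=3,
                          n_ra_components=1, seed=11)


@pytest.fixture(scope="session")
def expert_stack(small_scene):
    return simulate_expert_annotations(small_scene, n_experts=5, edge_jitter_px=2,
                                       area_disagreement_prob=0.3, seed=7)
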