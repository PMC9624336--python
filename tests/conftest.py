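import numpy as np
import pytest

import chromoseg as cs


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def light_scene():
    """One deterministic light-phenotype scene with ground truth."""
    return cs.generate_scene(cs.preset_config("light", seed=3))


@pytest.fixture(scope="session")
def wide_hf_config():
    """Scene config with a wide natural spread of ground-truth HF,
    used for correlation-based checks of the learned cascade."""

    def make(seed):
        return cs.SceneConfig(
            cc_count_range=(2, 12), cc_radius_range=(1.5, 4.0), cc_contrast=2.5, seed=seed
        )

    return make


@pytest.fixture(scope="session")
def wide_hf_fragments(wide_hf_config):
    """64 training and 30 held-out single-nucleus fragments from
    wide-HF scenes (session-scoped: shared by the learning tests)."""

    def frags(seed0, n_scenes):
        out = []
        for s in range(n_scenes):
            stack, gt = cs.generate_scene(wide_hf_config(seed0 + s))
            out += cs.fragments_from_scene(stack, gt)
        return out

    return frags(1000, 22)[:64], frags(5000, 12)[:30]
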