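import numpy as np
import pytest

from leafless import occlusion

CLASSES = np.array([0, 127, 255], dtype=np.uint8)


def random_mask(rng, shape=(16, 16), p=(0.6, 0.2, 0.2)):
    return CLASSES[rng.choice(3, size=shape, p=p)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def toy_leaves():
    return occlusion.make_toy_leaves(24, np.random.default_rng(11), size=30)


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory, toy_leaves):
    """Small paired dataset shared by occlusion/evaluation tests."""
    rng = np.random.default_rng(5)
    spec = occlusion.ToySceneSpec()
    patches = []
    for _ in range(10):
        gray, mask, _ = occlusion.generate_toy_scene(spec, rng)
        patches.append((gray, mask))
    root = tmp_path_factory.mktemp("toy_dataset")
    manifest = occlusion.build_dataset(patches, toy_leaves, root,
                                       train_multiplicity=4, test_multiplicity=3,
                                       seed=99)
    return manifest, patches
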