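import numpy as np
import pytest
from scipy import ndimage as ndi

from headrice import concavity, preprocessing, synthetic

STRUCT8 = np.ones((3, 3), dtype=bool)

#: Template size matching the acquisition geometry the variety profiles
#: emulate (a full bulk frame is ~3000 px across); small fixture scenes
#: carry the same ~100 px kernels, so tests pass this size explicitly.
TEMPLATE = 9


def chain_scene(size: int, variety: str = "japonica", seed: int = 0) -> synthetic.GrainScene:
    """One touching chain of ``size`` kernels."""
    return synthetic.make_scene(
        n_grains=size,
        cluster_size_weights={size: 1.0},
        variety_profile=variety,
        seed=seed,
    )


def preprocessed_single_component(scene):
    """Preprocess a one-cluster scene and return (mask, boundary)."""
    mask = preprocessing.preprocess(scene.image)
    labels, n = ndi.label(mask, structure=STRUCT8)
    assert n == 1, f"expected one component, got {n}"
    return mask, concavity.trace_boundary(labels, 1)


def detect(scene, a: float):
    """Run boundary trace + ECMP + threshold + concave detection on a
    one-cluster scene; returns (mask, boundary, profile)."""
    mask, boundary = preprocessed_single_component(scene)
    profile = concavity.ecmp_profile(mask, boundary, TEMPLATE)
    concavity.compute_lambda(profile, a)
    concavity.find_concave_points(profile)
    return mask, boundary, profile


@pytest.fixture(scope="session")
def two_grain():
    """A two-kernel touching cluster with detection run (japonica, a=3)."""
    scene = chain_scene(2, seed=3)
    mask, boundary, profile = detect(scene, 3.0)
    return scene, mask, boundary, profile


@pytest.fixture(scope="session")
def three_chain():
    """A three-kernel chain with detection run."""
    scene = chain_scene(3, seed=5)
    mask, boundary, profile = detect(scene, 3.0)
    return scene, mask, boundary, profile


@pytest.fixture(scope="session")
def singleton_scene():
    """30 free (non-touching) kernels, 20% broken."""
    return synthetic.make_scene(
        n_grains=30,
        cluster_size_weights={1: 1.0},
        broken_fraction=0.2,
        variety_profile="japonica",
        noise_speck_count=10,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
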