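import numpy as np
import pytest
from hypothesis import settings

from magfiber import synthetic as syn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def masked_model():
    return syn.MaskedLengthModel(90.0, 13.5)


@pytest.fixture(scope="session")
def aligned_fiber_scene(masked_model):
    """Strongly aligned fiber field (axis 0 deg), non-overlapping rods."""
    spec = syn.FiberFieldSpec(n_fibers=60, length_model=masked_model,
                              orientation_kappa=1e6, image_shape=(900, 900),
                              placement="spread", seed=42)
    return syn.generate_fiber_image(spec)


@pytest.fixture(scope="session")
def tenocyte_scene():
    return syn.generate_tenocyte_image(n_cells=80, orientation_kappa=4.0,
                                       aspect_ratio=4.0, seed=7)


@pytest.fixture(scope="session")
def spheroid_scene():
    """Fixed-composition spheroid scene: 2 strands, 1 cluster, 1 single."""
    body = syn.BodySpec(cx_px=384, cy_px=384, a_px=80, b_px=64, n_nuclei=50)
    outgrowths = (
        syn.OutgrowthSpec(syn.STRAND, 20.0, 120.0, 5),
        syn.OutgrowthSpec(syn.STRAND, 200.0, 90.0, 4),
        syn.OutgrowthSpec(syn.CLUSTER, 110.0, 60.0, 3, gap_to_body_um=25.0),
        syn.OutgrowthSpec(syn.SINGLE, 300.0, 22.0, 1, gap_to_body_um=40.0),
    )
    spec = syn.SpheroidSceneSpec(body=body, outgrowths=outgrowths, seed=9)
    return syn.generate_spheroid_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
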