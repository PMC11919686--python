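import numpy as np
import pytest

from memcurve import synthetic_scenes as syn


@pytest.fixture(scope="session")
def sphere_solid_100():
    return syn.sphere_label_volume(100.0, voxel_size=10.0)


@pytest.fixture(scope="session")
def sphere_shell_250():
    return syn.sphere_label_volume(250.0, voxel_size=12.0,
                                   shell_thickness=35.0)


@pytest.fixture(scope="session")
def small_vesicle_scene():
    """A quick 8-vesicle scene spanning both regimes of the coverage ramp."""
    curv = np.linspace(0.025, 0.08, 8)
    return syn.make_vesicle_scene(10.0 / curv, seed=11)


@pytest.fixture(scope="session")
def tube_map_default():
    return syn.make_tube_map(noise_sd=0.1, seed=2)


@pytest.fixture(scope="session")
def c20_patch_map():
    return syn.make_cn_map(n=20, ring_radius=110.0, patch_wedge=150.0,
                           snr=1.0, seed=0, shape=(96, 96, 48),
                           voxel_size=2.0)
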