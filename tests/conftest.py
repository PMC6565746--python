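import numpy as np
import pytest

from ploidykit.synth import (
    CountsSimParams,
    Nucleus,
    SceneSpec,
    simulate_confocal_scene,
    simulate_counts,
)


def small_scene_spec(**overrides) -> SceneSpec:
    """A compact two-nucleus (2n + 4n) scene used across imaging tests.

    Coarser voxels than the acquisition default keep the arrays tiny while
    preserving the geometry the statistics depend on.
    """
    defaults = dict(
        shape=(16, 90, 90),
        voxel_size_um=(0.4, 0.2, 0.2),
        nuclei=[
            Nucleus(center_um=(3.2, 4.5, 4.5), semi_axes_um=(2.0, 2.5, 2.5), ploidy=2),
            Nucleus(center_um=(3.2, 13.0, 13.0), semi_axes_um=(2.0, 2.5, 2.5), ploidy=4),
        ],
        seed=7,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


@pytest.fixture
def two_nucleus_scene():
    spec = small_scene_spec()
    return simulate_confocal_scene(spec)


@pytest.fixture
def noiseless_scene():
    spec = small_scene_spec(noiseless=True, background_rate=0.0, read_noise_sd=0.0)
    return simulate_confocal_scene(spec)


@pytest.fixture(scope="session")
def default_counts():
    """One medium synthetic droplet experiment shared by scrna tests."""
    params = CountsSimParams(n_cells=800, seed=42)
    return simulate_counts(params), params


def grid_ploidy_scene(ploidies, seed=0, voxel=(0.4, 0.2, 0.2), **overrides):
    """Scene with one nucleus per requested ploidy on a coarse grid."""
    from ploidykit.synth import layout_scene

    return layout_scene(
        list(ploidies), seed=seed, voxel_size_um=voxel, n_slices=16, **overrides
    )
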