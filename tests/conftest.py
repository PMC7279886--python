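"""Shared fixtures: small synthetic beads sized for fast unit tests."""

import numpy as np
import pytest

from mcbead import (
    SphereModel,
    SynthParams,
    build_narrow_band,
    build_surface_grid,
    generate_bead_stack,
)


def small_params(**overrides) -> SynthParams:
    """A bead that fits a 64^3 stack: R = 2.2 µm, two 1 µm² domains."""
    kwargs = dict(
        stack_shape=(64, 64, 64),
        voxel_size=(0.1, 0.1, 0.1),
        bead_radius=2.2,
        shell_sigma=0.15,
        n_domains=2,
        cap_area=1.0,
        enrichment=3.0,
        baseline_out=100.0,
        membrane_intensity=100.0,
        min_separation=2.0,
        rng_seed=11,
    )
    kwargs.update(overrides)
    return SynthParams(**kwargs)


@pytest.fixture(scope="session")
def small_bead():
    """Noise-free small bead with two domains and one dark patch."""
    params = small_params(n_dark_patches=1, dark_patch_area=1.0)
    vol, truth = generate_bead_stack(params)
    return params, vol, truth


@pytest.fixture(scope="session")
def unit_sphere_grid():
    sphere = SphereModel(center=(0.0, 0.0, 0.0), radius=5.0)
    return build_surface_grid(sphere, 3.0)


@pytest.fixture()
def small_grid_and_band(small_bead):
    params, vol, truth = small_bead
    grid = build_surface_grid(truth.sphere, 3.0)
    band = build_narrow_band(grid, vol.voxel_size, 5)
    return grid, band


def make_grid(radius=5.0, center=(0.0, 0.0, 0.0), resolution=3.0):
    return build_surface_grid(SphereModel(center=center, radius=radius), resolution)


def geodesic_um(sphere, t1, p1, t2, p2) -> float:
    c = (np.cos(t1) * np.cos(t2) + np.sin(t1) * np.sin(t2) * np.cos(p1 - p2))
    return sphere.radius * float(np.arccos(np.clip(c, -1, 1)))
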