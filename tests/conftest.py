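"""Shared synthetic fixtures (all generated at test time, nothing on disk)."""

from __future__ import annotations

import numpy as np
import pytest

from nucorg.phantom import PhantomSpec, generate_phantom, make_nucleus_mask

ISO = (0.25, 0.25, 0.25)


@pytest.fixture(scope="session")
def sphere_spec() -> PhantomSpec:
    """Isotropic 5-um sphere, noise and NPBs off."""
    return PhantomSpec(
        grid_shape=(48, 48, 48), spacing=ISO, nucleus_semiaxes=(5.0, 5.0, 5.0),
        n_npb=0, noise_gaussian=0.0, noise_poisson_gain=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def sphere_mask(sphere_spec) -> np.ndarray:
    return make_nucleus_mask(sphere_spec)


@pytest.fixture(scope="session")
def ellipsoid_spec() -> PhantomSpec:
    """2:1 oblate ellipsoid at the study's anisotropic spacing."""
    return PhantomSpec(
        grid_shape=(32, 104, 104), spacing=(0.37, 0.2, 0.2),
        nucleus_semiaxes=(4.5, 9.0, 9.0), n_npb=0,
        noise_gaussian=0.0, noise_poisson_gain=0.0, seed=12,
    )


@pytest.fixture(scope="session")
def ellipsoid_mask(ellipsoid_spec) -> np.ndarray:
    return make_nucleus_mask(ellipsoid_spec)


@pytest.fixture(scope="session")
def deformed_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(44, 120, 120), spacing=(0.37, 0.2, 0.2),
        nucleus_semiaxes=(6.0, 8.0, 7.0), deform_amplitude=0.2, n_npb=0,
        noise_gaussian=0.0, noise_poisson_gain=0.0, seed=13,
    )


@pytest.fixture(scope="session")
def deformed_mask(deformed_spec) -> np.ndarray:
    return make_nucleus_mask(deformed_spec)


def small_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Compact but realistic phantom used by batch tests (fast EDT/render)."""
    kwargs = dict(
        grid_shape=(30, 88, 88), spacing=(0.37, 0.2, 0.2),
        nucleus_semiaxes=(4.5, 7.0, 6.5), n_npb=2, npb_radius=1.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free rendered phantom with 24 + 12 spots and ground truth."""
    spec = small_phantom_spec(seed=7, noise_gaussian=0.0, noise_poisson_gain=0.0)
    channels, truth = generate_phantom(spec)
    return spec, channels, truth
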