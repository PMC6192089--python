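"""Shared fixtures: small phantom geometries sized for fast tests."""

import numpy as np
import pytest

from octlayers import ScanGeometry
from octlayers.synth import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """A reduced raster: 3 B-scans x 160 depth px x 200 A-scans, with the
    standard physical spacings."""
    return ScanGeometry(n_bscans=3, n_ascans=200, n_depth=160)


@pytest.fixture(scope="session")
def clean_phantom(small_geometry):
    """Noise-free default phantom with its ground truth."""
    spec = PhantomSpec(geometry=small_geometry, inner_surface_um=120.0, noise_sigma=0.0)
    volume, truth, annotations = generate_phantom(spec, seed=1)
    return spec, volume, truth, annotations


@pytest.fixture(scope="session")
def noisy_phantom(small_geometry):
    """Default phantom with the study noise level (sigma = 0.05)."""
    spec = PhantomSpec(geometry=small_geometry, inner_surface_um=120.0, noise_sigma=0.05)
    volume, truth, annotations = generate_phantom(spec, seed=2)
    return spec, volume, truth, annotations


@pytest.fixture(scope="session")
def subfield_geometry() -> ScanGeometry:
    """Geometry wide enough to hold the full 1-mm ETDRS central subfield:
    17 B-scans at 62 um spacing and 200 A-scans at 5.7 um."""
    return ScanGeometry(n_bscans=17, n_ascans=200, n_depth=160)


def random_phantom_spec(rng: np.random.Generator, geometry, noise_sigma=0.0):
    """A phantom spec with randomized layer thicknesses and pit shape."""
    base = np.array([18.0, 28.0, 21.0, 21.0, 114.0, 44.0, 30.0])
    thickness = tuple(base * rng.uniform(0.8, 1.2, size=7))
    return PhantomSpec(
        geometry=geometry,
        inner_surface_um=120.0,
        layer_thickness_um=thickness,
        pit_depth_fraction=float(rng.uniform(0.3, 0.7)),
        pit_sigma_um=float(rng.uniform(250.0, 350.0)),
        noise_sigma=noise_sigma,
    )
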