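"""Shared fixtures: phantoms and registration results are expensive, so
they are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import herniamech as hm
from herniamech.core import BinaryMask


@pytest.fixture(scope="session")
def phantom3() -> hm.PhantomBundle:
    """Default phantom (25 mm bulge, hernia sac, 3 mm grid)."""
    return hm.generate_phantom(hm.PhantomSpec(grid_spacing_mm=3.0, seed=7))


@pytest.fixture(scope="session")
def phantom_nohernia() -> hm.PhantomBundle:
    """Smooth torso without a sac: ground-truth unstable area is defined
    on the analytic ellipsoid surface."""
    return hm.generate_phantom(hm.PhantomSpec(grid_spacing_mm=3.0, hernia=None, seed=7))


@pytest.fixture(scope="session")
def recovered_field(phantom3) -> hm.DisplacementField:
    """Demons-recovered field for the default phantom."""
    return hm.register_masks(phantom3.rest_mask, phantom3.valsalva_mask)


def make_sphere_mask(radius_mm: float, spacing: float, pad_mm: float = 10.0) -> BinaryMask:
    half = radius_mm + pad_mm
    n = int(2 * half / spacing) + 1
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return BinaryMask(
        x**2 + y**2 + z**2 <= radius_mm**2,
        np.full(3, spacing),
        np.full(3, ax[0]),
    )


@pytest.fixture(scope="session")
def sphere50():
    return make_sphere_mask(50.0, 1.0)
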