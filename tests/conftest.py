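"""Shared fixtures: phantom geometries and one cached full-chain segmentation.

The segmentation of the standard cylinder phantom is expensive (a few
seconds), so it is computed once per session and shared by the pipeline,
end-to-end and acceptance tests.
"""

from __future__ import annotations

import pytest

from octa_surface import cylinder_phantom_spec, generate_phantom, segment_vessels

LATERAL_PITCH_MM = 3.0 / 245.0


def make_cylinder_phantom(radius_vox, length_vox, margin_vox=6.0, iso=True, axis="x", **kwargs):
    """Rendered single-tube phantom; sizes in lateral voxels (see cylinder_phantom_spec)."""
    spec = cylinder_phantom_spec(
        radius_vox, length_vox, margin_vox=margin_vox, iso=iso, axis=axis, **kwargs
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def standard_phantom():
    """Speckle-background cylinder phantom matched to the default filter scales.

    Radius 12 lateral voxels sits inside the default vesselness scale range
    (sigma 10-15 voxels); background 40 with speckle sigma 15 mimics the
    noise floor the adaptive equalisation stage expects.
    """
    return make_cylinder_phantom(
        radius_vox=12,
        length_vox=100,
        margin_vox=32,
        background_level=40.0,
        vessel_level=255.0,
        speckle_sigma=15.0,
        noise_seed=1,
    )


@pytest.fixture(scope="session")
def standard_segmentation(standard_phantom):
    """Full-chain segmentation of the standard phantom with default parameters."""
    return segment_vessels(standard_phantom["volume"])
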