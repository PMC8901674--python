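"""Stage-wise and whole-chain tests of the vessel segmentation pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from octa_surface import (
    OCTAVolume,
    PipelineConfig,
    VesselMask,
    VolumeMeta,
    apply_clahe,
    hysteresis_threshold,
    remove_small_components,
    segment_vessels,
    unsharp_mask,
    vesselness_filter,
)
from tests.conftest import make_cylinder_phantom

UNIT_META3 = VolumeMeta(n_fast=64, n_slow=64, n_depth=3, extent_mm=(64, 64, 3))


def _vol(arr, meta=None):
    arr = np.asarray(arr, dtype=float)
    if meta is None:
        meta = VolumeMeta(*arr.shape, extent_mm=tuple(float(s) for s in arr.shape))
    return OCTAVolume(arr, meta)


# ---------------------------------------------------------------------------
# config


@pytest.mark.parametrize(
    "kwargs",
    [
        {"clahe_clip_limit": 0.0},
        {"vesselness_scale_min": 15, "vesselness_scale_max": 10},
        {"hysteresis_low": 50, "hysteresis_high": 45},
        {"min_component_size": 0},
        {"connectivity": 10},
    ],
)
def test_config_invariants(kwargs):
    with pytest.raises(ValueError):
        PipelineConfig(**kwargs)


def test_config_yaml_roundtrip(tmp_path):
    import yaml

    cfg = PipelineConfig(hysteresis_low=30, vesselness_scale_min=4, vesselness_scale_max=8)
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    assert PipelineConfig.from_file(path) == cfg
    path.write_text(yaml.safe_dump({"no_such_key": 1}))
    with pytest.raises(ValueError, match="no_such_key"):
        PipelineConfig.from_file(path)


# ---------------------------------------------------------------------------
# CLAHE


def test_clahe_constant_volume_unchanged():
    vol = _vol(np.full((32, 32, 4), 97.0), VolumeMeta(32, 32, 4, extent_mm=(1, 1, 1)))
    out = apply_clahe(vol)
    np.testing.assert_array_equal(out.voxels, vol.voxels)


def test_clahe_checkerboard_maps_to_two_levels():
    """A two-level slice stays two-level after equalisation (5-bin quantisation)."""
    cb = np.indices((64, 64)).sum(axis=0) % 2
    arr = np.zeros((64, 64, 3))
    arr[:, :, 1] = np.where(cb, 200.0, 50.0)
    out = apply_clahe(_vol(arr, UNIT_META3)).voxels[:, :, 1]
    assert np.unique(np.round(out, 6)).size == 2
    assert out.min() >= 0 and out.max() <= 255


def test_clahe_flattens_speckle_histogram():
    rng = np.random.default_rng(0)
    arr = rng.normal(100, 20, (64, 64, 3)).clip(0, 255)
    out = apply_clahe(_vol(arr, UNIT_META3)).voxels
    assert out.min() >= 0 and out.max() <= 255

    def chi2_vs_uniform(x, bins=5):
        h, _ = np.histogram(x, bins=bins, range=(0, 255))
        e = x.size / bins
        return ((h - e) ** 2 / e).sum()

    for k in range(3):
        assert chi2_vs_uniform(out[:, :, k]) < chi2_vs_uniform(arr[:, :, k])


# ---------------------------------------------------------------------------
# unsharp


def test_unsharp_constant_and_zero_amount_identity():
    vol = _vol(np.full((16, 16, 2), 50.0), VolumeMeta(16, 16, 2, extent_mm=(1, 1, 1)))
    np.testing.assert_allclose(unsharp_mask(vol).voxels, 50.0)
    rng = np.random.default_rng(3)
    arr = rng.uniform(0, 255, (16, 16, 2))
    vol = _vol(arr, VolumeMeta(16, 16, 2, extent_mm=(1, 1, 1)))
    out = unsharp_mask(vol, PipelineConfig(unsharp_amount=0.0))
    np.testing.assert_allclose(out.voxels, arr)


def test_unsharp_matches_direct_convolution_oracle():
    """Single bright voxel: result equals an explicitly constructed kernel convolution."""
    cfg = PipelineConfig()
    arr = np.zeros((15, 15, 2))
    arr[7, 7, :] = 100.0
    out = unsharp_mask(_vol(arr, VolumeMeta(15, 15, 2, extent_mm=(1, 1, 1))), cfg).voxels[:, :, 0]
    ax = np.arange(-7, 8)
    k1 = np.exp(-(ax**2) / (2 * cfg.unsharp_radius**2))
    k1 /= k1.sum()
    blur = ndimage.convolve(arr[:, :, 0], np.outer(k1, k1), mode="reflect")
    expected = np.clip(arr[:, :, 0] + cfg.unsharp_amount * (arr[:, :, 0] - blur), 0, 255)
    np.testing.assert_allclose(out, expected, atol=1e-3)
    assert out[7, 7] > 100.0  # centre boosted
    ring = np.ones((15, 15), dtype=bool)
    ring[7, 7] = False
    assert np.all(out[ring] <= blur[ring] + 1e-9)  # halo darkened relative to plain blur


# ---------------------------------------------------------------------------
# vesselness


def test_vesselness_zero_volume_zero_response():
    vol = _vol(np.zeros((24, 24, 24)), VolumeMeta(24, 24, 24, extent_mm=(1, 1, 1)))
    assert vesselness_filter(vol, PipelineConfig(vesselness_scale_min=2, vesselness_scale_max=3)).voxels.max() == 0


def test_vesselness_empty_scale_range_rejected():
    cfg = PipelineConfig(vesselness_scale_min=5, vesselness_scale_max=5, vesselness_scale_step=1)
    assert len(cfg.scales) == 1  # single scale is fine
    with pytest.raises(ValueError):
        PipelineConfig(vesselness_scale_min=6, vesselness_scale_max=5)


@pytest.fixture(scope="module")
def tube_volume():
    """Noiseless bright tube (radius 4 voxels, axis in-plane) on dark background."""
    ph = make_cylinder_phantom(
        radius_vox=4, length_vox=40, margin_vox=14,
        background_level=0.0, vessel_level=255.0, speckle_sigma=0.0,
    )
    return ph


def test_vesselness_peaks_on_tube_axis(tube_volume):
    cfg = PipelineConfig(vesselness_scale_min=3, vesselness_scale_max=5)
    v = vesselness_filter(tube_volume["volume"], cfg).voxels
    truth = tube_volume["truth_mask"].voxels
    far = ~ndimage.binary_dilation(truth, iterations=12)  # >= 3 radii away
    far[[0, -1], :, :] = far[:, [0, -1], :] = far[:, :, [0, -1]] = False  # border artifacts exempt
    assert v[truth].max() > v[far].max()


def test_vesselness_prefers_tube_over_sheet():
    """The plate discriminator suppresses a sheet of equal contrast.

    Tube and sheet share one volume so they also share the per-volume
    response normalisation.
    """
    n = 96
    meta = VolumeMeta(n, n, 48, extent_mm=(n, n, 48))
    arr = np.zeros((n, n, 48))
    jj, kk = np.meshgrid(np.arange(n), np.arange(48), indexing="ij")
    tube_cs = ((jj - 24) ** 2 + (kk - 24) ** 2) <= 16  # radius-4 tube along x
    arr[:, tube_cs] = 255.0
    sheet = np.zeros((n, n, 48), dtype=bool)
    sheet[:, 64:96, 20:28] = True  # 8-voxel-thick slab, same contrast
    arr[sheet] = 255.0
    cfg = PipelineConfig(vesselness_scale_min=3, vesselness_scale_max=4)
    v = vesselness_filter(_vol(arr, meta), cfg).voxels
    tube_mask = np.zeros_like(sheet)
    tube_mask[:, tube_cs] = True
    interior = sheet.copy()
    interior[[0, -1]] = False
    assert v[tube_mask].max() > 2 * v[interior].max()


def test_vesselness_agrees_with_reference_frangi(tube_volume):
    """Independent cross-check: skimage's Frangi filter ranks the same structure."""
    from skimage.filters import frangi

    vol = tube_volume["volume"].voxels.astype(float)
    ref = frangi(vol, sigmas=range(3, 6), black_ridges=False)
    cfg = PipelineConfig(vesselness_scale_min=3, vesselness_scale_max=5)
    ours = vesselness_filter(tube_volume["volume"], cfg).voxels
    truth = tube_volume["truth_mask"].voxels
    assert ref[truth].mean() > 10 * ref[~truth].mean()
    assert ours[truth].mean() > 10 * ours[~truth].mean()


# ---------------------------------------------------------------------------
# hysteresis + components


def _hysteresis_oracle(values, low, high, structure):
    """Flood-fill reference: label the >= low set, keep labels with a >= high voxel."""
    lowmask = values >= low
    labels, n = ndimage.label(lowmask, structure=structure)
    keep = np.zeros_like(lowmask)
    for lab in range(1, n + 1):
        comp = labels == lab
        if (values[comp] >= high).any():
            keep |= comp
    return keep


def test_hysteresis_chain_kept_and_isolated_dropped():
    meta = VolumeMeta(4, 3, 3, extent_mm=(4, 3, 3))
    arr = np.zeros((4, 3, 3))
    arr[:, 1, 1] = [44, 44, 46, 44]  # weak chain through one strong voxel
    mask = hysteresis_threshold(_vol(arr, meta))
    assert mask.voxels[:, 1, 1].all()
    assert mask.n_vessel_voxels == 4

    arr2 = np.zeros((4, 3, 3))
    arr2[1, 1, 1] = 44  # weak, no strong voxel in its component
    assert hysteresis_threshold(_vol(arr2, meta)).n_vessel_voxels == 0

    assert hysteresis_threshold(_vol(np.full((4, 3, 3), 39.0), meta)).n_vessel_voxels == 0


@pytest.mark.parametrize("connectivity", [6, 26])
def test_hysteresis_matches_flood_fill_oracle(connectivity):
    cfg = PipelineConfig(connectivity=connectivity)
    rng = np.random.default_rng(11)
    meta = VolumeMeta(20, 20, 20, extent_mm=(1, 1, 1))
    for _ in range(50):
        arr = rng.uniform(0, 60, (20, 20, 20))
        got = hysteresis_threshold(_vol(arr, meta), cfg).voxels
        want = _hysteresis_oracle(arr, cfg.hysteresis_low, cfg.hysteresis_high, cfg.structure)
        np.testing.assert_array_equal(got, want)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    hnp.arrays(np.uint8, (9, 9, 9), elements=st.integers(0, 60)),
    st.integers(20, 40),
)
def test_hysteresis_monotone_in_low_threshold(arr, low):
    """Lowering the weak threshold (strong fixed) never removes a kept voxel."""
    meta = VolumeMeta(9, 9, 9, extent_mm=(1, 1, 1))
    kept_hi = hysteresis_threshold(_vol(arr, meta), PipelineConfig(hysteresis_low=low)).voxels
    kept_lo = hysteresis_threshold(
        _vol(arr, meta), PipelineConfig(hysteresis_low=low - 10)
    ).voxels
    assert np.all(kept_lo | ~kept_hi)


def test_remove_small_components_boundary():
    meta = VolumeMeta(10, 10, 10, extent_mm=(1, 1, 1))
    blob29 = np.zeros((10, 10, 10), dtype=bool)
    blob29.flat[:0] = False
    blob29[:3, :3, :3] = True  # 27 voxels
    blob29[3, 0, 0] = blob29[3, 1, 0] = True  # 29
    assert remove_small_components(VesselMask(blob29, meta)).n_vessel_voxels == 0
    blob30 = blob29.copy()
    blob30[3, 2, 0] = True  # 30
    out = remove_small_components(VesselMask(blob30, meta))
    np.testing.assert_array_equal(out.voxels, blob30)


def test_remove_small_components_keeps_large_drops_small():
    meta = VolumeMeta(20, 10, 10, extent_mm=(2, 1, 1))
    m = np.zeros((20, 10, 10), dtype=bool)
    m[:5, :5, :4] = True  # 100 voxels
    m[15, 8, 8] = m[15, 8, 9] = m[15, 9, 8] = m[15, 9, 9] = m[16, 8, 8] = True  # 5 voxels
    out = remove_small_components(VesselMask(m, meta))
    labels, n = ndimage.label(out.voxels, structure=np.ones((3, 3, 3)))
    assert n == 1
    assert out.n_vessel_voxels == 100


# ---------------------------------------------------------------------------
# full chain


def test_segment_zero_volume_empty_mask():
    meta = VolumeMeta(24, 24, 24, extent_mm=(1, 1, 1))
    cfg = PipelineConfig(vesselness_scale_min=2, vesselness_scale_max=3)
    mask = segment_vessels(_vol(np.zeros((24, 24, 24)), meta), cfg)
    assert mask.n_vessel_voxels == 0


def test_segment_recovers_phantom_tube(standard_phantom, standard_segmentation):
    """Default parameters recover a scale-matched tube on a speckle background."""
    truth = standard_phantom["truth_mask"].voxels
    mask = standard_segmentation.voxels
    overlap = (mask & truth).sum() / truth.sum()
    dilated = ndimage.binary_dilation(truth, iterations=2)
    outside = (mask & ~dilated).sum() / mask.sum()
    assert overlap >= 0.8
    assert outside <= 0.2
    # every surviving component respects the minimum size
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    sizes = np.bincount(labels.ravel())[1:]
    assert n >= 1 and (sizes >= 30).all()


def test_segment_deterministic(standard_phantom, standard_segmentation):
    again = segment_vessels(standard_phantom["volume"])
    np.testing.assert_array_equal(again.voxels, standard_segmentation.voxels)


def test_segment_translation_equivariance_along_depth():
    """Shifting the input by whole depth slices shifts the mask identically (interior)."""
    ph = make_cylinder_phantom(
        radius_vox=6, length_vox=36, margin_vox=30, speckle_sigma=0.0,
        background_level=40.0, vessel_level=255.0,
    )
    # margins exceed the Gaussian kernel reach (4 sigma), so the shifted tube
    # never interacts differently with the volume borders
    cfg = PipelineConfig(vesselness_scale_min=4, vesselness_scale_max=6,
                         min_component_size=10)
    vol = ph["volume"].voxels
    shift = 4
    shifted = np.zeros_like(vol)
    shifted[:, :, shift:] = vol[:, :, :-shift]
    shifted[:, :, :shift] = vol[:, :, :1]  # replicate the (background) first slice
    meta = ph["volume"].meta
    m0 = segment_vessels(OCTAVolume(vol, meta), cfg).voxels
    m1 = segment_vessels(OCTAVolume(shifted, meta), cfg).voxels
    expected = np.zeros_like(m0)
    expected[:, :, shift:] = m0[:, :, :-shift]
    np.testing.assert_array_equal(m1, expected)
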