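"""Gradient map, watershed basins and candidate extraction."""

import numpy as np
import pytest

from nodulecad.core_io import BinaryMask, CTVolume, LabelMap, VolumeError
from nodulecad.structure_seg import (
    GradientVolume,
    extract_candidates,
    gradient_magnitude,
    watershed_labels,
)


def _all_mask(shape):
    return BinaryMask(np.ones(shape, dtype=np.uint8))


def test_gradient_of_constant_is_zero():
    vol = CTVolume(np.full((10, 10, 10), -500.0, dtype=np.float32), spacing=(1.5, 0.7, 0.7))
    grad = gradient_magnitude(vol, sigma_mm=1.0)
    assert np.allclose(grad.magnitude, 0.0, atol=1e-9)


def test_gradient_of_linear_ramp_equals_slope():
    # 3 HU/mm along x, spacing 0.7 mm: interior magnitude must be ~3
    shape = (12, 12, 40)
    x_mm = np.arange(shape[2]) * 0.7
    vox = np.broadcast_to(3.0 * x_mm, shape).astype(np.float32).copy()
    vol = CTVolume(vox, spacing=(1.5, 0.7, 0.7))
    grad = gradient_magnitude(vol, sigma_mm=1.0)
    interior = grad.magnitude[4:-4, 4:-4, 8:-8]
    assert np.allclose(interior, 3.0, atol=1e-3)


def test_gradient_peaks_on_sphere_shell():
    shape, spacing = (24, 40, 40), (1.5, 1.0, 1.0)
    zz, yy, xx = np.ogrid[0:24, 0:40, 0:40]
    r_mm = np.sqrt(((zz - 12) * 1.5) ** 2 + (yy - 20.0) ** 2 + (xx - 20.0) ** 2)
    vox = np.where(r_mm <= 8.0, 0.0, -800.0).astype(np.float32)
    grad = gradient_magnitude(CTVolume(vox, spacing=spacing), sigma_mm=1.0)
    peak_r = r_mm[np.unravel_index(np.argmax(grad.magnitude), shape)]
    assert abs(peak_r - 8.0) < 2.0


def test_gradient_requires_positive_sigma():
    vol = CTVolume(np.zeros((4, 4, 4), dtype=np.float32), spacing=(1, 1, 1))
    with pytest.raises(VolumeError):
        gradient_magnitude(vol, sigma_mm=0.0)


def test_gradient_volume_rejects_negative_magnitude():
    with pytest.raises(VolumeError):
        GradientVolume(np.full((2, 2, 2), -1.0), sigma_mm=1.0, spacing=(1, 1, 1))


def test_watershed_flat_field_is_one_region():
    grad = GradientVolume(np.zeros((8, 8, 8)), sigma_mm=1.0, spacing=(1, 1, 1))
    labels = watershed_labels(grad, _all_mask((8, 8, 8)), level=0.15)
    assert labels.labels().size == 1
    assert (labels.data > 0).all()


def test_watershed_separates_two_blobs():
    shape, spacing = (16, 40, 40), (1.5, 1.0, 1.0)
    vox = np.zeros(shape, dtype=np.float32)
    zz, yy, xx = np.ogrid[0:16, 0:40, 0:40]
    b1 = ((zz - 8) * 1.5) ** 2 + (yy - 12.0) ** 2 + (xx - 12.0) ** 2 <= 36
    b2 = ((zz - 8) * 1.5) ** 2 + (yy - 28.0) ** 2 + (xx - 28.0) ** 2 <= 36
    vox[b1 | b2] = -600.0  # two dark blobs in a bright field
    vol = CTVolume(vox, spacing=spacing)
    labels = watershed_labels(gradient_magnitude(vol, 1.0), _all_mask(shape), level=0.06)
    l1 = labels.data[8, 12, 12]
    l2 = labels.data[8, 28, 28]
    assert l1 > 0 and l2 > 0 and l1 != l2


def test_watershed_label_count_monotone_in_level(mixed_case, processed_mixed, phantom_cfg):
    from nodulecad.structure_seg import gradient_magnitude as gm

    _, vol, _ = mixed_case
    grad = gm(vol, phantom_cfg.watershed.sigma_mm)
    lung = processed_mixed.lung.mask
    counts = [
        watershed_labels(grad, lung, level=lvl).labels().size
        for lvl in (0.02, 0.06, 0.15, 0.4)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_watershed_empty_mask_errors():
    grad = GradientVolume(np.zeros((4, 4, 4)), sigma_mm=1.0, spacing=(1, 1, 1))
    with pytest.raises(VolumeError, match="empty"):
        watershed_labels(grad, BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8)))


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

def test_extract_candidates_drops_outside_mask_and_small_objects():
    shape = (20, 20, 20)
    vol = CTVolume(np.zeros(shape, dtype=np.float32), spacing=(1.0, 1.0, 1.0))
    labels = np.zeros(shape, dtype=np.int32)
    lung = np.zeros(shape, dtype=np.uint8)
    lung[:, :, :10] = 1
    # label 1: 6 mm ball inside the mask, spanning slices 4..10 -> kept, ns = 7
    zz, yy, xx = np.ogrid[0:20, 0:20, 0:20]
    ball6 = (zz - 7) ** 2 + (yy - 8) ** 2 + (xx - 5) ** 2 <= 9
    labels[ball6] = 1
    # label 2: wholly outside the lung mask -> not emitted
    labels[10:14, 10:14, 14:18] = 2
    # label 3: 2 mm equivalent diameter -> dropped below the 3 mm floor
    labels[15, 15, 0:4] = 3
    cands = extract_candidates(LabelMap(labels), BinaryMask(lung), vol)
    assert [c.label for c in cands] == [1]
    c = cands[0]
    assert c.slice_range == (4, 10) and c.ns == 7
    assert 3.0 <= c.equivalent_diameter_mm <= 30.0


def test_extract_candidates_partition_reconciles(mixed_case, processed_mixed, phantom_cfg):
    """Every lung voxel belongs to exactly one watershed label; kept + dropped counts add up."""
    from nodulecad.structure_seg import gradient_magnitude, watershed_labels

    _, vol, _ = mixed_case
    lung = processed_mixed.lung.mask
    grad = gradient_magnitude(vol, phantom_cfg.watershed.sigma_mm)
    labels = watershed_labels(grad, lung, phantom_cfg.watershed.level, phantom_cfg.watershed.threshold)
    inside = lung.as_bool()
    assert (labels.data[inside] > 0).all()  # partition covers the mask
    cands = extract_candidates(labels, lung, vol)
    kept = sum(c.n_voxels for c in cands)
    assert kept <= int(inside.sum())
    # kept voxels are exactly those of size-eligible components
    voxel_vol = vol.voxel_volume_mm3
    total_eligible = 0
    masked = np.where(inside, labels.data, 0)
    for lab in np.unique(masked):
        if lab == 0:
            continue
        from scipy import ndimage as ndi

        comps, n = ndi.label(masked == lab, structure=ndi.generate_binary_structure(3, 1))
        for k in range(1, n + 1):
            nvox = int((comps == k).sum())
            eq_d = (6 * nvox * voxel_vol / np.pi) ** (1 / 3)
            if 3.0 <= eq_d <= 30.0:
                total_eligible += nvox
    assert kept == total_eligible


def test_candidates_contain_every_nodule_centroid_without_vessels(template):
    """On a vessel-free phantom the extractor emits >= k objects covering all k centers."""
    from dataclasses import replace

    from nodulecad import phantom
    from nodulecad.structure_seg import gradient_magnitude, watershed_labels
    from nodulecad import lung_seg

    spec = phantom.sample_case(template, case_seed=424, nodules_per_case=(3, 5))
    spec = replace(spec, vessels=())
    vol, gt = phantom.generate_phantom(spec)
    cfg = lung_seg.LungSegConfig.for_phantom(template)
    seg = lung_seg.segment_lungs(vol, gt.seeds, cfg)
    grad = gradient_magnitude(vol, 1.0)
    labels = watershed_labels(grad, seg.mask, level=0.06)
    cands = extract_candidates(labels, seg.mask, vol)
    assert len(cands) >= len(gt.nodules)
    for nod in gt.nodules:
        cvox = np.round(np.array(nod.center_mm) / np.array(vol.spacing)).astype(int)
        assert any((np.abs(c.voxels - cvox).sum(axis=1) == 0).any() for c in cands), nod.type
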