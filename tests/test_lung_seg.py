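"""Lung segmentation: flood-fill and morphology oracles, volume gate, retry loop."""

from collections import deque

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import ball

from nodulecad import lung_seg
from nodulecad.core_io import BinaryMask, CTVolume, VoxelIndex
from nodulecad.lung_seg import (
    LungSegConfig,
    SeedError,
    close_3d,
    region_grow,
    segment_lungs,
    smooth_curvature_flow,
    volume_check,
)


def bfs_flood_fill(window: np.ndarray, seeds) -> np.ndarray:
    """Independent breadth-first 6-connected flood fill inside a boolean window."""
    out = np.zeros_like(window, dtype=bool)
    q = deque()
    for s in seeds:
        if window[s] and not out[s]:
            out[s] = True
            q.append(s)
    shape = window.shape
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if window[nz, ny, nx] and not out[nz, ny, nx]:
                    out[nz, ny, nx] = True
                    q.append((nz, ny, nx))
    return out


def _cfg(**kw):
    return LungSegConfig(**kw)


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def test_region_grow_single_block_exact():
    vox = np.zeros((20, 20, 20), dtype=np.float32)
    vox[5:12, 4:10, 6:15] = -500.0
    vol = CTVolume(vox, spacing=(1, 1, 1))
    mask = region_grow(vol, [VoxelIndex(8, 6, 10)], _cfg())
    expected = vox == -500.0
    assert np.array_equal(mask.as_bool(), expected)


def test_region_grow_reaches_only_seeded_component():
    vox = np.zeros((20, 20, 20), dtype=np.float32)
    vox[2:6, 2:6, 2:6] = -500.0
    vox[10:15, 10:15, 10:15] = -500.0
    vol = CTVolume(vox, spacing=(1, 1, 1))
    mask = region_grow(vol, [VoxelIndex(3, 3, 3)], _cfg()).as_bool()
    assert mask[2:6, 2:6, 2:6].all()
    assert not mask[10:15, 10:15, 10:15].any()


def test_region_grow_seed_outside_window_errors():
    vol = CTVolume(np.zeros((5, 5, 5), dtype=np.float32), spacing=(1, 1, 1))
    with pytest.raises(SeedError, match=r"\(2, 2, 2\)"):
        region_grow(vol, [VoxelIndex(2, 2, 2)], _cfg())


def test_region_grow_equals_bfs_oracle_on_random_volumes():
    rng = np.random.default_rng(12)
    for _ in range(10):
        shape = tuple(rng.integers(8, 28, size=3))
        vox = rng.uniform(-1200, 100, size=shape).astype(np.float32)
        window = (vox >= -1000) & (vox <= -200)
        if not window.any():
            continue
        seed_idx = tuple(int(v) for v in rng.choice(np.argwhere(window)))
        vol = CTVolume(vox, spacing=(1, 1, 1))
        mask = region_grow(vol, [VoxelIndex(*seed_idx)], _cfg())
        assert np.array_equal(mask.as_bool(), bfs_flood_fill(window, [seed_idx]))


# ---------------------------------------------------------------------------
# morphological closing
# ---------------------------------------------------------------------------

def brute_force_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation then erosion with an explicit Euclidean ball, with safe padding."""
    pad = radius + 1
    mp = np.pad(mask, pad)
    selem = ball(radius)
    dil = ndi.binary_dilation(mp, structure=selem)
    ero = ndi.binary_erosion(dil, structure=selem)
    return ero[pad:-pad, pad:-pad, pad:-pad]


def test_close_3d_radius_zero_is_identity():
    rng = np.random.default_rng(1)
    m = BinaryMask((rng.random((10, 10, 10)) > 0.5).astype(np.uint8))
    assert np.array_equal(close_3d(m, 0).data, m.data)


def test_close_3d_convex_cube_unchanged():
    m = np.zeros((20, 20, 20), dtype=np.uint8)
    m[5:15, 5:15, 5:15] = 1
    closed = close_3d(BinaryMask(m), 5)
    assert np.array_equal(closed.data, m)


def test_close_3d_fills_hemispherical_indentation():
    # a solid block with a radius-5 hemispherical bite taken out of one face
    m = np.zeros((24, 24, 24), dtype=bool)
    m[4:20, 4:20, 4:12] = True
    zz, yy, xx = np.ogrid[0:24, 0:24, 0:24]
    bite = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 11) ** 2 <= 25
    m &= ~bite
    closed = close_3d(BinaryMask(m.astype(np.uint8)), 12).as_bool()
    assert np.array_equal(closed, brute_force_closing(m, 12))
    # the bite's interior (below the rolling-ball reach at the rim) is filled
    assert closed[12, 12, 6] and closed[12, 12, 9]


@pytest.mark.parametrize("radius", [2, 3])
def test_close_3d_matches_brute_force_on_random_masks(radius):
    rng = np.random.default_rng(7)
    for _ in range(5):
        m = ndi.binary_dilation(rng.random((16, 16, 16)) > 0.97, iterations=2)
        closed = close_3d(BinaryMask(m.astype(np.uint8)), radius).as_bool()
        assert np.array_equal(closed, brute_force_closing(m, radius))


def test_close_3d_idempotent():
    rng = np.random.default_rng(5)
    m = BinaryMask(ndi.binary_dilation(rng.random((18, 18, 18)) > 0.96, iterations=2).astype(np.uint8))
    once = close_3d(m, 4)
    twice = close_3d(once, 4)
    assert np.array_equal(once.data, twice.data)


# ---------------------------------------------------------------------------
# volume gate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "measured,expected",
    [(3_545_668, "accepted"), (0, "retry"), (1_400_000, "retry"), (2_000_000, "accepted")],
)
def test_volume_check_examples(measured, expected):
    assert volume_check(measured, _cfg()) == expected


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_smoothing_identity_and_fixed_point():
    rng = np.random.default_rng(0)
    vol = CTVolume(rng.normal(-800, 30, (8, 10, 12)).astype(np.float32), spacing=(1.5, 0.7, 0.7))
    out = smooth_curvature_flow(vol, iterations=0)
    assert np.array_equal(out.voxels, vol.voxels)
    const = CTVolume(np.full((8, 8, 8), -500.0, dtype=np.float32), spacing=(1, 1, 1))
    smoothed = smooth_curvature_flow(const, iterations=5)
    assert np.allclose(smoothed.voxels, -500.0, atol=1e-3)


def test_smoothing_reduces_variance(clean_phantom):
    _, vol, _ = clean_phantom
    out = smooth_curvature_flow(vol, iterations=10)
    assert out.voxels.var() < vol.voxels.var()


# ---------------------------------------------------------------------------
# the full stage
# ---------------------------------------------------------------------------

def test_segment_lungs_requires_two_seeds(clean_phantom):
    _, vol, gt = clean_phantom
    with pytest.raises(Exception, match="two seeds"):
        segment_lungs(vol, gt.seeds[:1])


def test_segment_lungs_covers_ground_truth(mixed_case, processed_mixed, phantom_cfg):
    _, _, gt = mixed_case
    seg = processed_mixed.lung
    assert seg.status == "accepted"
    assert seg.measured_volume == seg.mask.count
    mask = seg.mask.as_bool()
    covered = mask[gt.lung_mask].mean()
    assert covered >= 0.99
    for nod in gt.nodules:
        v = nod.voxels
        assert mask[v[:, 0], v[:, 1], v[:, 2]].mean() >= 0.99


def test_seeds_in_one_lung_drive_retry_then_needs_new_seeds(clean_phantom, template):
    spec, vol, gt = clean_phantom
    cfg = LungSegConfig.for_phantom(template)
    left_seed = gt.seeds[1]  # the smaller cavity
    neighbour = VoxelIndex(left_seed.slice, left_seed.row + 1, left_seed.col)
    seg = segment_lungs(vol, [left_seed, neighbour], cfg)
    assert seg.status == "needs_new_seeds"
    assert seg.attempts == cfg.max_attempts


def test_failing_gate_with_single_attempt(clean_phantom, template):
    spec, vol, gt = clean_phantom
    cfg = LungSegConfig.for_phantom(template, max_attempts=1)
    seg = segment_lungs(vol, [gt.seeds[1], VoxelIndex(gt.seeds[1].slice, gt.seeds[1].row + 1, gt.seeds[1].col)], cfg)
    assert seg.attempts == 1
    assert seg.status != "accepted"


def test_config_validation():
    with pytest.raises(Exception):
        LungSegConfig(hu_low=-100, hu_high=-200)
    with pytest.raises(Exception):
        LungSegConfig(volume_tolerance=1.5)
    with pytest.raises(Exception):
        LungSegConfig(closing_radius_voxels=-1)
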