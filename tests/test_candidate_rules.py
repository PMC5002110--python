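"""Rule descriptors: mesh roundness, moment elongation, GLCM energy, decisions."""

import numpy as np
import pytest

from conftest import make_candidate
from nodulecad.candidate_rules import (
    GLCMConfig,
    Rule,
    RuleFeatures,
    RuleThresholds,
    apply_rules,
    compute_features,
    elongation,
    glcm_energy,
    roundness,
)
from nodulecad.core_io import CTVolume


def sphere_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    zz, yy, xx = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    return (
        ((zz - center[0]) * spacing[0]) ** 2
        + ((yy - center[1]) * spacing[1]) ** 2
        + ((xx - center[2]) * spacing[2]) ** 2
        <= radius**2
    )


def ellipsoid_mask(shape, center, semis):
    zz, yy, xx = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    return (
        ((zz - center[0]) / semis[0]) ** 2
        + ((yy - center[1]) / semis[1]) ** 2
        + ((xx - center[2]) / semis[2]) ** 2
        <= 1.0
    )


def eig_oracle(voxels, spacing):
    """Brute-force 3x3 second-central-moment eigenvalue ratio."""
    pts = voxels * np.asarray(spacing)
    mu = pts.mean(axis=0)
    M = np.zeros((3, 3))
    for p in pts:
        d = p - mu
        M += np.outer(d, d)
    M /= len(pts)
    eig = np.sort(np.linalg.eigvalsh(M))
    return eig[-1] / eig[0]


# ---------------------------------------------------------------------------
# roundness
# ---------------------------------------------------------------------------

def test_roundness_of_digitized_sphere_near_one():
    m = sphere_mask((26, 26, 26), (12.5, 12.5, 12.5), 10.0)
    c = make_candidate(m)
    val = roundness(c, (1.0, 1.0, 1.0))
    assert 0.95 <= val <= 1.05


def test_roundness_sphere_beats_prolate_ellipsoid():
    sph = make_candidate(sphere_mask((26, 26, 26), (12.5, 12.5, 12.5), 10.0))
    ell = make_candidate(ellipsoid_mask((64, 16, 16), (31.5, 7.5, 7.5), (30.0, 6.0, 6.0)))
    r_sph = roundness(sph, (1.0, 1.0, 1.0))
    r_ell = roundness(ell, (1.0, 1.0, 1.0))
    assert r_ell < 1.0
    assert r_ell < r_sph
    # closed-form check: a 5:1 prolate spheroid has area ratio ~0.58
    assert r_ell < 0.75


def test_roundness_rotation_invariance_within_mesh_tolerance():
    # the same 2:1 ellipsoid, axis-aligned vs rotated 45 degrees in-plane
    n = 48
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float) - (n - 1) / 2
    axis_aligned = (yy / 16.0) ** 2 + (xx / 8.0) ** 2 + (zz / 8.0) ** 2 <= 1.0
    u = (yy + xx) / np.sqrt(2)
    v = (yy - xx) / np.sqrt(2)
    rotated = (u / 16.0) ** 2 + (v / 8.0) ** 2 + (zz / 8.0) ** 2 <= 1.0
    r1 = roundness(make_candidate(axis_aligned), (1.0, 1.0, 1.0))
    r2 = roundness(make_candidate(rotated), (1.0, 1.0, 1.0))
    assert abs(r1 - r2) / r1 < 0.02


def test_roundness_requires_meshable_candidate():
    m = np.zeros((4, 4, 4), dtype=bool)
    m[1, 1, 1] = True
    with pytest.raises(ValueError, match="required to mesh"):
        roundness(make_candidate(m), (1, 1, 1))


# ---------------------------------------------------------------------------
# elongation
# ---------------------------------------------------------------------------

def test_elongation_sphere_near_one():
    c = make_candidate(sphere_mask((22, 22, 22), (10.5, 10.5, 10.5), 8.0))
    assert elongation(c, (1.0, 1.0, 1.0)) == pytest.approx(1.0, abs=0.05)


def test_elongation_tube_matches_eig_oracle():
    m = np.zeros((40, 9, 9), dtype=bool)
    m[2:38, 3:6, 3:6] = True  # straight tube, ~12:1
    for spacing in [(1.0, 1.0, 1.0), (1.5, 0.7, 0.7)]:
        c = make_candidate(m)
        assert elongation(c, spacing) == pytest.approx(eig_oracle(c.voxels, spacing), rel=1e-9)


def test_elongation_oracle_on_random_blobs():
    rng = np.random.default_rng(4)
    for _ in range(10):
        m = np.zeros((12, 12, 12), dtype=bool)
        pts = rng.integers(0, 12, size=(30, 3))
        m[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        c = make_candidate(m)
        want = eig_oracle(c.voxels, (1.5, 0.7, 0.7))
        assert elongation(c, (1.5, 0.7, 0.7)) == pytest.approx(want, rel=1e-9)


def test_elongation_degenerate_cases():
    single = np.zeros((3, 3, 3), dtype=bool)
    single[1, 1, 1] = True
    assert elongation(make_candidate(single), (1, 1, 1)) == 1.0
    line = np.zeros((9, 3, 3), dtype=bool)
    line[1:8, 1, 1] = True
    assert elongation(make_candidate(line), (1, 1, 1)) == float("inf")


# ---------------------------------------------------------------------------
# GLCM energy
# ---------------------------------------------------------------------------

def _uniform_volume(shape=(10, 12, 12), value=100.0):
    return CTVolume(np.full(shape, value, dtype=np.float32), spacing=(1, 1, 1))


def test_glcm_energy_uniform_candidate_is_sqrt_ns():
    vol = _uniform_volume()
    m = np.zeros((10, 12, 12), dtype=bool)
    m[2:7, 3:9, 3:9] = True  # ns = 5
    c = make_candidate(m)
    assert glcm_energy(c, vol) == pytest.approx(np.sqrt(5), abs=1e-12)
    m1 = np.zeros((10, 12, 12), dtype=bool)
    m1[4, 3:9, 3:9] = True  # single slice
    assert glcm_energy(make_candidate(m1), vol) == pytest.approx(1.0, abs=1e-12)


def glcm_oracle(plane, levels):
    """Brute-force enumeration of horizontal neighbour pairs (symmetric, normalized)."""
    mat = np.zeros((levels, levels))
    h, w = plane.shape
    for y in range(h):
        for x in range(w - 1):
            a, b = plane[y, x], plane[y, x + 1]
            if a >= 0 and b >= 0:
                mat[a, b] += 1
                mat[b, a] += 1
    return (mat / mat.sum()) ** 2


def test_glcm_energy_checkerboard_matches_pair_counting():
    shape = (3, 8, 8)
    vox = np.zeros(shape, dtype=np.float32)
    yy, xx = np.mgrid[0:8, 0:8]
    checker = ((yy + xx) % 2).astype(np.float32) * 200.0
    vox[1] = checker
    vol = CTVolume(vox, spacing=(1, 1, 1))
    m = np.zeros(shape, dtype=bool)
    m[1, :, :] = True
    c = make_candidate(m)
    cfg = GLCMConfig(levels=64)
    # quantization of {0, 200} over the candidate range gives codes {0, 63}
    codes = np.where(checker > 0, 63, 0)
    want = np.sqrt(glcm_oracle(codes, 64).sum())
    assert glcm_energy(c, vol, cfg) == pytest.approx(want, abs=1e-12)


def test_glcm_energy_invariant_under_bin_preserving_remap():
    rng = np.random.default_rng(9)
    base = rng.integers(0, 64, size=(4, 10, 10)).astype(np.float32)
    m = np.zeros((4, 10, 10), dtype=bool)
    m[:, 2:9, 2:9] = True
    c = make_candidate(m)
    v1 = CTVolume(base * 10.0, spacing=(1, 1, 1))
    v2 = CTVolume(base * 25.0 + 100.0, spacing=(1, 1, 1))  # affine, bins preserved
    assert glcm_energy(c, v1) == pytest.approx(glcm_energy(c, v2), abs=1e-12)


def test_glcm_energy_thin_slices_contribute_zero(caplog):
    vol = _uniform_volume()
    m = np.zeros((10, 12, 12), dtype=bool)
    m[3, 4:8, 4:8] = True
    m[4, 5, 5] = True  # single pixel on slice 4
    c = make_candidate(m)
    with caplog.at_level("WARNING", logger="nodulecad"):
        val = glcm_energy(c, vol)
    assert val == pytest.approx(1.0, abs=1e-12)  # only slice 3 contributes
    assert any("pixels" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# rule decisions
# ---------------------------------------------------------------------------

def test_apply_rules_order_and_strictness():
    t = RuleThresholds(
        roundness=Rule(0.5, "discard_if_below"),
        elongation=Rule(5.0, "discard_if_above"),
        energy=Rule(0.1, "discard_if_below"),
    )
    assert apply_rules(RuleFeatures(0.9, 2.0, 1.0), t).keep
    d = apply_rules(RuleFeatures(0.2, 40.0, 1.0), t)
    assert not d.keep and d.reason == "roundness"  # first violated rule wins
    d = apply_rules(RuleFeatures(0.9, 40.0, 1.0), t)
    assert not d.keep and d.reason == "elongation"
    # equality with a threshold never discards
    assert apply_rules(RuleFeatures(0.5, 5.0, 0.1), t).keep
    # disabled rules are skipped
    t_off = RuleThresholds(elongation=Rule(5.0, "discard_if_above", enabled=False))
    assert apply_rules(RuleFeatures(0.9, 40.0, 1.0), t_off).keep


def test_rules_discard_vessels_and_keep_nodules(mixed_case, phantom_cfg):
    """Calibrated defaults: >= 90 % of pure vessel tubes discarded, all nodules kept."""
    from nodulecad.phantom import _cavity_mask, _tube_mask

    spec, vol, gt = mixed_case
    cavity = np.zeros(spec.shape, dtype=bool)
    for cav in spec.cavities:
        cavity |= _cavity_mask(cav, spec.shape, spec.spacing)

    voxvol = vol.voxel_volume_mm3
    vessel_decisions = []
    for tube in spec.vessels:
        m = _tube_mask(tube, spec.shape, spec.spacing) & cavity
        if m.sum() < 8:
            continue
        c = make_candidate(m, voxel_volume=voxvol)
        vessel_decisions.append(apply_rules(compute_features(c, vol, phantom_cfg.glcm), phantom_cfg.rules))
    assert vessel_decisions
    discarded = sum(not d.keep for d in vessel_decisions)
    assert discarded / len(vessel_decisions) >= 0.9

    for nod in gt.nodules:
        m = np.zeros(spec.shape, dtype=bool)
        m[nod.voxels[:, 0], nod.voxels[:, 1], nod.voxels[:, 2]] = True
        c = make_candidate(m, voxel_volume=voxvol)
        d = apply_rules(compute_features(c, vol, phantom_cfg.glcm), phantom_cfg.rules)
        assert d.keep, (nod.type, nod.diameter_mm, d.reason, d.features)
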