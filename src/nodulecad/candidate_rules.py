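"""Rule-based screening of candidate objects.

Three cheap descriptors knock out structures that are obviously not nodules
(vessels, airway fragments) before the expensive classifier stage:

* **Roundness** -- ratio of the surface area of the sphere with the
  candidate's volume to the candidate's own (marching-cubes) surface area.
  A sphere scores 1; since the sphere minimises area at fixed volume every
  other shape scores below 1, and tubular or ragged shapes score low.
* **Elongation** -- ratio of the largest to the smallest eigenvalue of the
  candidate's second central moment matrix in physical coordinates; ~1 for
  spheres, large for cylinders.
* **Energy** -- texture uniformity from a per-slice gray-level
  co-occurrence matrix (GLCM): sqrt over the candidate's ``ns`` slices of
  the sum of squared normalized co-occurrence frequencies.  A perfectly
  uniform candidate spanning ``ns`` slices scores exactly ``sqrt(ns)``.

Each rule carries an explicit comparison direction and enable flag;
comparisons are strict, so a value exactly at its threshold is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import marching_cubes, mesh_surface_area

from .core_io import CTVolume
from .structure_seg import CandidateObject

logger = logging.getLogger("nodulecad")


@dataclass(frozen=True)
class RuleFeatures:
    roundness: float
    elongation: float
    energy: float


@dataclass(frozen=True)
class Rule:
    threshold: float
    direction: str  # "discard_if_below" | "discard_if_above"
    enabled: bool = True

    def violated(self, value: float) -> bool:
        if not self.enabled:
            return False
        if self.direction == "discard_if_below":
            return value < self.threshold
        if self.direction == "discard_if_above":
            return value > self.threshold
        raise ValueError(f"unknown rule direction {self.direction!r}")


@dataclass(frozen=True)
class RuleThresholds:
    """Thresholds and directions for the three rules, applied in order R1-R3.

    The defaults operate on the natural dimensionless scales of the
    descriptors and were calibrated once on the phantom suite: discard when
    roundness drops below 0.35 (ragged/tubular surface), when elongation
    exceeds 4 (cylindrical), or when GLCM energy drops below 0.02 (texture
    so fragmented that no coherent structure is present).  Threshold
    magnitudes of 8.3e4 / 6.8e4 / 3.3 are sometimes quoted for these rules
    in the CAD literature; on the dimensionless scales used here the first
    two are unreachable, so they are not the defaults, but any combination
    can be configured.
    """

    roundness: Rule = field(default_factory=lambda: Rule(0.35, "discard_if_below"))
    elongation: Rule = field(default_factory=lambda: Rule(4.0, "discard_if_above"))
    energy: Rule = field(default_factory=lambda: Rule(0.02, "discard_if_below"))


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization and offset of the co-occurrence matrix.

    Intensities are quantized to ``levels`` bins over the candidate's own HU
    range; pairs are taken at a 1-pixel horizontal offset within each axial
    slice; the matrix is symmetrized and normalized.
    """

    levels: int = 64
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("GLCM levels must be >= 2")


@dataclass(frozen=True)
class RuleDecision:
    keep: bool
    reason: str  # "" when kept, else the violated rule's name
    features: RuleFeatures


def _candidate_mask(c: CandidateObject, pad: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Dense padded {0,1} grid of the candidate plus its index offset."""
    lo = c.voxels.min(axis=0) - pad
    hi = c.voxels.max(axis=0) + pad + 1
    grid = np.zeros(tuple(hi - lo), dtype=np.uint8)
    rel = c.voxels - lo
    grid[rel[:, 0], rel[:, 1], rel[:, 2]] = 1
    return grid, lo


def roundness(c: CandidateObject, spacing: tuple[float, float, float]) -> float:
    """Equal-volume-sphere area over marching-cubes surface area; in (0, 1] for solids.

    Degenerate voxel sets that cannot be meshed return 0 with a warning.
    """
    if c.n_voxels < 8:
        raise ValueError(f"candidate {c.label} has {c.n_voxels} voxels; at least 8 are required to mesh")
    grid, _ = _candidate_mask(c, pad=2)
    # mesh a lightly smoothed field: the raw binary staircase overestimates
    # surface area by ~8 %; fall back to the binary mesh for tiny candidates
    # that the smoothing would erase
    from scipy import ndimage as ndi

    mesh = None
    smoothed = ndi.gaussian_filter(grid.astype(np.float64), sigma=1.0)
    if smoothed.max() > 0.55:
        try:
            verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=spacing)
            mesh = (verts, faces)
        except (ValueError, RuntimeError):
            mesh = None
    if mesh is None:
        try:
            verts, faces, _, _ = marching_cubes(grid.astype(np.float64), level=0.5, spacing=spacing)
            mesh = (verts, faces)
        except (ValueError, RuntimeError):
            logger.warning("candidate %d: degenerate voxel set, roundness set to 0", c.label)
            return 0.0
    verts, faces = mesh
    area = float(mesh_surface_area(verts, faces))
    if area <= 0:
        logger.warning("candidate %d: zero mesh area, roundness set to 0", c.label)
        return 0.0
    # enclosed volume by the divergence theorem, so A_n and a describe the
    # same surface regardless of the smoothing
    tri = verts[faces]
    volume = abs(float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])))) / 6.0
    if volume <= 0:
        logger.warning("candidate %d: zero mesh volume, roundness set to 0", c.label)
        return 0.0
    r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    area_sphere = 4.0 * np.pi * r * r
    return float(area_sphere / area)


def elongation(c: CandidateObject, spacing: tuple[float, float, float]) -> float:
    """Largest over smallest principal second moment of the voxel set (>= 1).

    A single voxel is defined as 1; collinear voxel sets (zero minimal
    moment) return ``inf``.
    """
    if c.n_voxels < 1:
        raise ValueError("empty candidate")
    if c.n_voxels == 1:
        return 1.0
    pts = c.voxels * np.asarray(spacing)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / c.n_voxels
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 1e-12:
        return float("inf")
    return float(eig[-1] / eig[0])


def glcm_energy(c: CandidateObject, vol: CTVolume, cfg: GLCMConfig | None = None) -> float:
    """Per-slice GLCM energy, accumulated as sqrt of the sum over slices.

    Quantizes the candidate's HU values to ``cfg.levels`` bins over its own
    range, builds the normalized symmetric co-occurrence histogram of
    1-pixel horizontal neighbours per axial slice, and returns
    ``sqrt(sum_slices sum_ij P_ij^2)``.  Slices with fewer than two
    candidate pixels (no pairs) contribute 0 with a warning.
    """
    cfg = cfg or GLCMConfig()
    hu = vol.voxels[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]].astype(np.float64)
    lo, hi = float(hu.min()), float(hu.max())
    if hi > lo:
        codes = np.minimum(
            ((hu - lo) / (hi - lo) * cfg.levels).astype(np.int64), cfg.levels - 1
        )
    else:
        codes = np.zeros(hu.shape, dtype=np.int64)

    (z0, z1), (y0, y1), (x0, x1) = c.bbox
    total = 0.0
    for z in range(z0, z1):
        in_slice = c.voxels[:, 0] == z
        n_pix = int(in_slice.sum())
        if n_pix < 2:
            logger.warning("candidate %d slice %d has %d pixels; energy contribution 0", c.label, z, n_pix)
            continue
        plane = np.full((y1 - y0, x1 - x0), -1, dtype=np.int64)
        vox = c.voxels[in_slice]
        plane[vox[:, 1] - y0, vox[:, 2] - x0] = codes[in_slice]
        a = plane[:, :-1].ravel()
        b = plane[:, 1:].ravel()
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            logger.warning("candidate %d slice %d has no horizontal pixel pairs", c.label, z)
            continue
        mat = np.zeros((cfg.levels, cfg.levels), dtype=np.float64)
        np.add.at(mat, (a[valid], b[valid]), 1.0)
        if cfg.symmetric:
            mat = mat + mat.T
        if cfg.normalized:
            mat = mat / mat.sum()
        total += float((mat**2).sum())
    return float(np.sqrt(total))


def compute_features(
    c: CandidateObject,
    vol: CTVolume,
    glcm: GLCMConfig | None = None,
) -> RuleFeatures:
    return RuleFeatures(
        roundness=roundness(c, vol.spacing),
        elongation=elongation(c, vol.spacing),
        energy=glcm_energy(c, vol, glcm),
    )


def apply_rules(f: RuleFeatures, t: RuleThresholds | None = None) -> RuleDecision:
    """Apply R1 (roundness), R2 (elongation), R3 (energy) in order.

    The first violated rule names the discard reason; comparisons are
    strict, so equality with a threshold keeps the candidate.
    """
    t = t or RuleThresholds()
    for name in ("roundness", "elongation", "energy"):
        rule: Rule = getattr(t, name)
        if rule.violated(getattr(f, name)):
            return RuleDecision(keep=False, reason=name, features=f)
    return RuleDecision(keep=True, reason="", features=f)
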