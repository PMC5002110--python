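"""Semi-automatic 3D lung segmentation.

The stage chain is: curvature-flow smoothing, seeded connected-threshold
region growing inside a Hounsfield window, 3D morphological closing with a
ball element (to pull juxtapleural nodules and vessel tunnels back into the
mask), and a lung-volume plausibility gate with a retry loop.  The caller
supplies exactly two seed voxels, one inside each lung.

The closing is computed through exact Euclidean distance transforms, which
is equivalent to dilation-then-erosion with the discrete ball
``{v : ||v|| <= r}`` but linear-time in the voxel count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi

from .core_io import BinaryMask, CTVolume, VoxelIndex, VolumeError

logger = logging.getLogger("nodulecad")

Status = Literal["accepted", "retry", "needs_new_seeds"]

#: 6-connected 3D structuring element (faces only).
STRUCTURE_6 = ndi.generate_binary_structure(3, 1)


class SeedError(VolumeError):
    """A seed voxel falls outside the intensity window."""


@dataclass(frozen=True)
class LungSegConfig:
    """Knobs of the lung-segmentation stage.

    ``hu_low``/``hu_high`` bound the region-growing window (air through lung
    parenchyma and vessels); ``closing_radius_voxels`` is the ball radius of
    the 3D closing; ``reference_volume`` is the expected lung volume in
    voxels against which the grown mask is gated, with relative deviations
    beyond ``volume_tolerance`` triggering a retry.  Each retry widens
    ``hu_high`` by ``retry_hu_step``; after ``max_attempts`` the caller is
    asked for new seeds.
    """

    hu_low: float = -1000.0
    hu_high: float = -200.0
    closing_radius_voxels: int = 12
    reference_volume: float = 3_545_668.0
    volume_tolerance: float = 0.60
    smoothing_iterations: int = 10
    smoothing_time_step: float = 0.0625
    max_attempts: int = 3
    retry_hu_step: float = 50.0

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise VolumeError("hu_low must be strictly below hu_high")
        if not (0.0 < self.volume_tolerance < 1.0):
            raise VolumeError("volume_tolerance must lie in (0, 1)")
        if self.closing_radius_voxels < 0:
            raise VolumeError("closing_radius_voxels must be >= 0")

    @classmethod
    def for_phantom(cls, spec, **overrides) -> "LungSegConfig":
        """A config whose reference volume is the phantom's analytic cavity volume."""
        return cls(reference_volume=spec.lung_volume_voxels(), **overrides)


@dataclass
class LungSegmentation:
    """Result of :func:`segment_lungs`: the mask plus gate bookkeeping."""

    mask: BinaryMask
    measured_volume: int
    status: Status
    attempts: int


def smooth_curvature_flow(vol: CTVolume, iterations: int = 10, time_step: float = 0.0625) -> CTVolume:
    """Edge-preserving curvature-flow denoising (finite-difference level-set flow).

    ``iterations=0`` returns the input unchanged; a constant volume is a
    fixed point for any iteration count.
    """
    import SimpleITK as sitk

    if iterations < 0:
        raise VolumeError("iterations must be >= 0")
    if not np.isfinite(vol.voxels).all():
        raise VolumeError("volume contains non-finite voxels")
    if iterations == 0:
        return CTVolume(vol.voxels.copy(), vol.spacing, vol.origin)
    img = sitk.GetImageFromArray(vol.voxels.astype(np.float64))
    img.SetSpacing(tuple(vol.spacing[::-1]))
    out = sitk.CurvatureFlow(img, timeStep=float(time_step), numberOfIterations=int(iterations))
    return CTVolume(sitk.GetArrayFromImage(out).astype(np.float32), vol.spacing, vol.origin)


def region_grow(vol: CTVolume, seeds: Sequence[VoxelIndex], cfg: LungSegConfig) -> BinaryMask:
    """Seeded connected-threshold growing.

    The result is the union, over the seeds, of the 6-connected components
    of ``{voxel : hu_low <= HU <= hu_high}`` containing each seed.

    Raises
    ------
    SeedError
        If a seed voxel's HU lies outside the window (the error names the
        seed and its value).
    """
    window = (vol.voxels >= cfg.hu_low) & (vol.voxels <= cfg.hu_high)
    for seed in seeds:
        seed.validate_within(vol.shape)
        hu = float(vol.voxels[seed.as_tuple()])
        if not window[seed.as_tuple()]:
            raise SeedError(
                f"seed {seed.as_tuple()} has HU {hu:.1f}, outside the window "
                f"[{cfg.hu_low:g}, {cfg.hu_high:g}]"
            )
    labels, _ = ndi.label(window, structure=STRUCTURE_6)
    wanted = {int(labels[s.as_tuple()]) for s in seeds}
    mask = np.isin(labels, sorted(wanted))
    return BinaryMask(mask.astype(np.uint8), provenance="region_grow")


def close_3d(mask: BinaryMask, radius_voxels: int) -> BinaryMask:
    """Morphological closing with a ball of ``radius_voxels`` (index space).

    Implemented as two exact Euclidean distance transforms; identical to
    dilation followed by erosion with the ball ``{v : ||v|| <= r}``.
    Radius 0 is the identity.
    """
    if radius_voxels < 0:
        raise VolumeError("radius_voxels must be >= 0")
    m = mask.as_bool()
    if radius_voxels == 0 or not m.any():
        return BinaryMask(m.astype(np.uint8), provenance=f"close_3d(r={radius_voxels})")
    r = float(radius_voxels)
    # pad so dilation cannot wrap the image border into the erosion
    pad = int(np.ceil(r)) + 1
    mp = np.pad(m, pad)
    dist_to_mask = ndi.distance_transform_edt(~mp)
    dilated = mp | (dist_to_mask <= r)
    dist_to_bg = ndi.distance_transform_edt(dilated)
    closed = dist_to_bg > r
    closed = closed[pad:-pad, pad:-pad, pad:-pad]
    return BinaryMask(closed.astype(np.uint8), provenance=f"close_3d(r={radius_voxels})")


def volume_check(measured: int, cfg: LungSegConfig) -> Status:
    """Gate a measured lung volume against the reference.

    Returns ``"retry"`` iff the relative deviation ``|1 - measured/reference|``
    exceeds ``volume_tolerance`` (two-sided), else ``"accepted"``.
    """
    if measured < 0:
        raise VolumeError("measured volume must be >= 0")
    deviation = abs(1.0 - measured / cfg.reference_volume)
    return "retry" if deviation > cfg.volume_tolerance else "accepted"


def segment_lungs(vol: CTVolume, seeds: Sequence[VoxelIndex], cfg: LungSegConfig | None = None) -> LungSegmentation:
    """Run the full semi-automatic lung segmentation.

    Smooth once, then grow/close/gate up to ``cfg.max_attempts`` times.  A
    failing volume gate widens the upper HU bound by ``retry_hu_step`` per
    attempt (re-growing an unchanged window would be a no-op).  If every
    attempt fails the status is ``"needs_new_seeds"`` and the caller must
    supply different seed points.
    """
    cfg = cfg or LungSegConfig()
    if len(seeds) != 2:
        raise VolumeError(f"exactly two seeds are required (one per lung), got {len(seeds)}")
    smoothed = smooth_curvature_flow(vol, cfg.smoothing_iterations, cfg.smoothing_time_step)

    mask = BinaryMask(np.zeros(vol.shape, dtype=np.uint8))
    measured = 0
    status: Status = "retry"
    attempts = 0
    for attempt in range(cfg.max_attempts):
        attempts = attempt + 1
        cfg_a = replace(cfg, hu_high=cfg.hu_high + cfg.retry_hu_step * attempt)
        grown = region_grow(smoothed, seeds, cfg_a)
        mask = close_3d(grown, cfg.closing_radius_voxels)
        measured = mask.count
        status = volume_check(measured, cfg)
        logger.info(
            "lung segmentation attempt %d: window [%g, %g] HU, volume %d voxels -> %s",
            attempts, cfg_a.hu_low, cfg_a.hu_high, measured, status,
        )
        if status == "accepted":
            break
    if status != "accepted":
        status = "needs_new_seeds"
    mask.provenance = "segment_lungs"
    return LungSegmentation(mask=mask, measured_volume=measured, status=status, attempts=attempts)
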