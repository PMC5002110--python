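"""Watershed separation of internal lung structures.

A Gaussian gradient-magnitude map is built in physical coordinates (the
per-axis derivative of a Gaussian-smoothed volume, divided by the voxel
spacing, combined as the Euclidean norm), then flooded by the watershed
transform restricted to the lung mask.  Regional minima deeper than a
fraction ``level`` of the magnitude range seed the catchment basins;
magnitudes below ``threshold`` of the range are floored first so that
near-flat noise does not spawn basins.  Basin fragments inside the lung mask
whose equivalent diameter lies in the nodule size range become candidate
objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_minima, local_minima
from skimage.segmentation import watershed

from .core_io import BinaryMask, CTVolume, LabelMap, VolumeError
from .lung_seg import STRUCTURE_6


@dataclass
class GradientVolume:
    """Gradient-magnitude map (HU/mm) congruent with its source volume."""

    magnitude: np.ndarray
    sigma_mm: float
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if (self.magnitude < 0).any():
            raise VolumeError("gradient magnitude must be non-negative")


@dataclass
class CandidateObject:
    """A labeled 6-connected voxel set inside the lung mask.

    ``ns`` is the number of axial slices the object spans
    (``last - first + 1``); ``equivalent_diameter_mm`` is the diameter of
    the sphere with the object's volume.
    """

    label: int
    voxels: np.ndarray  # (n, 3) int indices (z, y, x)
    slice_range: tuple[int, int]
    volume_mm3: float
    equivalent_diameter_mm: float
    mean_hu: float
    centroid_mm: np.ndarray
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open per axis

    @property
    def ns(self) -> int:
        return self.slice_range[1] - self.slice_range[0] + 1

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


def gradient_magnitude(vol: CTVolume, sigma_mm: float = 1.0) -> GradientVolume:
    """Gaussian gradient magnitude in HU/mm, respecting anisotropic spacing."""
    if sigma_mm <= 0:
        raise VolumeError("sigma_mm must be > 0")
    data = vol.voxels.astype(np.float64)
    acc = np.zeros_like(data)
    for axis in range(3):
        sigma_vox = [sigma_mm / s for s in vol.spacing]
        order = [0, 0, 0]
        order[axis] = 1
        d = ndi.gaussian_filter(data, sigma=sigma_vox, order=order) / vol.spacing[axis]
        acc += d * d
    return GradientVolume(np.sqrt(acc), sigma_mm=sigma_mm, spacing=vol.spacing)


def watershed_labels(
    grad: GradientVolume,
    lung: BinaryMask,
    level: float = 0.15,
    threshold: float = 0.01,
) -> LabelMap:
    """Flood the gradient map inside the lung mask.

    ``level`` and ``threshold`` are fractions of the in-mask magnitude
    range.  Minima shallower than ``level`` are merged into their
    neighbours (via h-minima marker extraction); magnitudes below
    ``threshold`` are floored.  Deterministic for fixed input.
    """
    if not (0.0 <= level <= 1.0 and 0.0 <= threshold <= 1.0):
        raise VolumeError("level and threshold must lie in [0, 1]")
    mask = lung.as_bool()
    if not mask.any():
        raise VolumeError("empty lung mask")
    g = grad.magnitude.astype(np.float64)
    gmin = float(g[mask].min())
    grange = float(g[mask].max()) - gmin
    if grange > 0:
        gn = (g - gmin) / grange
    else:
        gn = np.zeros_like(g)
    gn = np.clip(gn, threshold, None)
    gn[~mask] = 2.0  # keep minima (and flooding) inside the mask

    if level > 0 and grange > 0:
        minima = h_minima(gn, level) & mask
    else:
        minima = local_minima(gn, connectivity=1) & mask
    if not minima.any():  # pathologically high level: one basin from the global minimum
        flat = np.zeros_like(mask)
        inside = np.argwhere(mask)
        flat[tuple(inside[np.argmin(gn[mask])])] = True
        minima = flat
    markers, _ = ndi.label(minima, structure=STRUCTURE_6)
    labels = watershed(gn, markers=markers, mask=mask, connectivity=STRUCTURE_6)
    return LabelMap(labels.astype(np.int32), provenance="watershed").relabeled()


def extract_candidates(
    labels: LabelMap,
    lung: BinaryMask,
    vol: CTVolume,
    min_diameter_mm: float = 3.0,
    max_diameter_mm: float = 30.0,
) -> list[CandidateObject]:
    """Turn watershed basins into candidate objects.

    Each positive label is intersected with the lung mask and split into
    6-connected components; components whose equivalent diameter falls
    outside ``[min_diameter_mm, max_diameter_mm]`` are dropped (the system
    does not look for nodules below 3 mm or above 30 mm).
    """
    if labels.shape != vol.shape or lung.shape != vol.shape:
        raise VolumeError("labels, lung mask and volume must be congruent")
    voxel_vol = vol.voxel_volume_mm3
    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    masked = np.where(lung.as_bool(), labels.data, 0)

    candidates: list[CandidateObject] = []
    next_id = 1
    slices = ndi.find_objects(masked)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        region = masked[sl] == lab
        comps, n_comp = ndi.label(region, structure=STRUCTURE_6)
        offset = np.array([s.start for s in sl])
        for comp in range(1, n_comp + 1):
            idx = np.argwhere(comps == comp) + offset
            volume = idx.shape[0] * voxel_vol
            eq_d = (6.0 * volume / np.pi) ** (1.0 / 3.0)
            if not (min_diameter_mm <= eq_d <= max_diameter_mm):
                continue
            zmin, zmax = int(idx[:, 0].min()), int(idx[:, 0].max())
            hu = vol.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
            bbox = tuple(
                (int(idx[:, k].min()), int(idx[:, k].max()) + 1) for k in range(3)
            )
            candidates.append(
                CandidateObject(
                    label=next_id,
                    voxels=idx,
                    slice_range=(zmin, zmax),
                    volume_mm3=float(volume),
                    equivalent_diameter_mm=float(eq_d),
                    mean_hu=float(hu.mean()),
                    centroid_mm=origin + idx.mean(axis=0) * spacing,
                    bbox=bbox,  # type: ignore[arg-type]
                )
            )
            next_id += 1
    return candidates
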