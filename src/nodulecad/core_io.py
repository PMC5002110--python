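"""Volume and mask containers plus readers/writers for the formats the pipeline touches.

Conventions
-----------
* Index order is ``(slice, row, col)`` == ``(z, y, x)``, 0-based.
* Physical quantities (spacing, origin, coordinates, diameters) are in
  millimetres unless a name is suffixed ``_voxels``.
* Hounsfield values are stored as ``float32`` and clipped to the CT range
  ``[-1024, 3071]``; any clipping is logged, never silent.
* Anisotropic spacing is carried through every stage, not resampled away;
  stages that need isotropy say so in their own contracts.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("nodulecad")

HU_MIN = -1024.0
HU_MAX = 3071.0


class VolumeError(ValueError):
    """Raised for malformed volumes, masks or on-disk inputs."""


@dataclass
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels : ndarray
        3D array in ``(z, y, x)`` order, interpreted as Hounsfield units.
        Cast to ``float32``; values outside ``[-1024, 3071]`` are clipped
        (the clip is logged).
    spacing : tuple of float
        Voxel size in mm per axis, ``(z, y, x)``; strictly positive.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm, ``(z, y, x)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeError(
                f"CTVolume requires a 3D grid, got {self.voxels.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.isfinite(self.voxels).all():
            raise VolumeError("CTVolume contains non-finite voxels")
        voxels = self.voxels.astype(np.float32, copy=False)
        n_clip = int(np.count_nonzero((voxels < HU_MIN) | (voxels > HU_MAX)))
        if n_clip:
            logger.warning("clipping %d voxels outside the HU range [%g, %g]", n_clip, HU_MIN, HU_MAX)
            voxels = np.clip(voxels, HU_MIN, HU_MAX)
        self.voxels = voxels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_mm(self, index: Sequence[float]) -> np.ndarray:
        """Physical (z, y, x) mm coordinate of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def mm_to_index(self, point_mm: Sequence[float]) -> np.ndarray:
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass(frozen=True)
class VoxelIndex:
    """A 0-based (slice, row, col) voxel address, e.g. a user seed point."""

    slice: int
    row: int
    col: int

    def __post_init__(self) -> None:
        for name, v in (("slice", self.slice), ("row", self.row), ("col", self.col)):
            if int(v) != v or v < 0:
                raise VolumeError(f"VoxelIndex.{name} must be a non-negative integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (int(self.slice), int(self.row), int(self.col))

    def validate_within(self, shape: Sequence[int]) -> None:
        for name, v, n in zip(("slice", "row", "col"), self.as_tuple(), shape):
            if v >= n:
                raise VolumeError(f"VoxelIndex.{name}={v} outside extent {n}")


@dataclass
class BinaryMask:
    """A {0,1} grid congruent with a CTVolume.

    ``provenance`` records which stage produced the mask (e.g.
    ``"region_grow"``, ``"close_3d(r=12)"``).
    """

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"BinaryMask requires a 3D grid, got {data.ndim}D")
        if data.dtype == bool:
            data = data.astype(np.uint8)
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise VolumeError(f"BinaryMask values must be 0/1, found {uniq[:10]}")
        self.data = data.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass
class LabelMap:
    """A non-negative integer label grid; 0 is background."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"LabelMap requires a 3D grid, got {data.ndim}D")
        if data.min() < 0:
            raise VolumeError("LabelMap labels must be non-negative")
        self.data = data.astype(np.int32, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the map."""
        u = np.unique(self.data)
        return u[u > 0]

    def relabeled(self) -> "LabelMap":
        """Return a copy whose label set is {0} plus contiguous 1..n."""
        u = self.labels()
        lut = np.zeros(int(self.data.max()) + 1, dtype=np.int32)
        lut[u] = np.arange(1, u.size + 1, dtype=np.int32)
        return LabelMap(lut[self.data], provenance=self.provenance)


# ---------------------------------------------------------------------------
# DICOM series reading
# ---------------------------------------------------------------------------

def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Read one CT DICOM series from a directory into a CTVolume.

    Slices are sorted by spatial position along the scan axis; raw stored
    values are mapped to HU through the per-slice rescale slope/intercept;
    z spacing is derived from the slice positions.

    Raises
    ------
    VolumeError
        If the directory holds more than one series, slice positions are
        missing/duplicated, or the slice pitch is non-uniform (the error
        names the offending gap).
    """
    import pydicom

    directory = Path(directory)
    datasets = []
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise VolumeError(f"no DICOM image files found in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise VolumeError(f"directory mixes {len(uids)} series UIDs: {sorted(uids)}")

    def z_of(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            raise VolumeError("slice without ImagePositionPatient; cannot sort series")
        return float(ipp[2])

    datasets.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in datasets], dtype=float)

    if len(datasets) > 1:
        dz = np.diff(zs)
        if np.any(dz < 1e-6):
            i = int(np.argmin(dz))
            raise VolumeError(f"duplicate slice position at z={zs[i]:g} mm")
        if dz.max() - dz.min() > 1e-3 * dz.mean():
            i = int(np.argmax(dz))
            raise VolumeError(
                "non-uniform slice spacing: gap of "
                f"{dz[i]:g} mm between z={zs[i]:g} and z={zs[i + 1]:g} "
                f"(expected {np.median(dz):g} mm)"
            )
        spacing_z = float(np.mean(dz))
    else:
        spacing_z = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    voxels = np.stack(slices, axis=0)

    ps = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    ipp0 = getattr(datasets[0], "ImagePositionPatient", [0.0, 0.0, 0.0])
    return CTVolume(
        voxels=voxels,
        spacing=(spacing_z, float(ps[0]), float(ps[1])),
        origin=(float(ipp0[2]), float(ipp0[1]), float(ipp0[0])),
    )


# ---------------------------------------------------------------------------
# Single-file volumes and masks (NIfTI / NRRD via SimpleITK)
# ---------------------------------------------------------------------------

def _sitk():
    import SimpleITK as sitk

    return sitk


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a scalar NIfTI/NRRD volume; HU interpretation is assumed."""
    sitk = _sitk()
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise VolumeError(f"expected a 3D volume, got {img.GetDimension()}D in {path}")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeError(f"expected scalar voxels, got {img.GetNumberOfComponentsPerPixel()} components")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return CTVolume(
        voxels=arr.astype(np.float32),
        spacing=tuple(img.GetSpacing()[::-1]),
        origin=tuple(img.GetOrigin()[::-1]),
    )


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    sitk = _sitk()
    img = sitk.GetImageFromArray(vol.voxels.astype(np.float32))
    img.SetSpacing(tuple(vol.spacing[::-1]))
    img.SetOrigin(tuple(vol.origin[::-1]))
    sitk.WriteImage(img, str(path))


def write_mask(mask: BinaryMask | LabelMap, path: str | os.PathLike, like: CTVolume | None = None) -> None:
    """Write a mask/label grid with integer voxel type, carrying ``like``'s geometry."""
    sitk = _sitk()
    if isinstance(mask, BinaryMask):
        arr = mask.data.astype(np.uint8)
    elif isinstance(mask, LabelMap):
        arr = mask.data.astype(np.int32)
    else:
        raise VolumeError(f"write_mask expects BinaryMask or LabelMap, got {type(mask).__name__}")
    img = sitk.GetImageFromArray(arr)
    if like is not None:
        if tuple(like.shape) != tuple(arr.shape):
            raise VolumeError(f"mask shape {arr.shape} incongruent with volume shape {like.shape}")
        img.SetSpacing(tuple(like.spacing[::-1]))
        img.SetOrigin(tuple(like.origin[::-1]))
    parent = Path(path).parent
    if parent and not parent.exists():
        raise VolumeError(f"output directory does not exist: {parent}")
    sitk.WriteImage(img, str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask | LabelMap:
    """Read a mask written by :func:`write_mask`; returns a BinaryMask when values are {0,1}."""
    sitk = _sitk()
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if np.isin(np.unique(arr), (0, 1)).all():
        return BinaryMask(arr.astype(np.uint8), provenance=f"read:{path}")
    return LabelMap(arr.astype(np.int32), provenance=f"read:{path}")
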