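"""Synthetic chest-CT phantoms with ground truth.

The phantom emulates the gross attenuation structure a nodule-detection
pipeline depends on: a soft-tissue thorax (~40 HU) enclosing two air-filled
lung cavities (~-880 HU) modelled as ellipsoids (the right cavity larger than
the left, as in real anatomy), tubular vessels crossing each cavity at
soft-tissue attenuation, and spherical nodules of 3-30 mm diameter of four
types -- isolated, juxtapleural, juxtavascular and ground-glass.  Additive
Gaussian noise (default sigma 20 HU) stands in for acquisition noise.

Every nodule carries a ground-truth voxel set (exactly the voxels whose
centers fall inside its analytic sphere), its type, diameter, and a 5-degree
malignancy label assigned from a fixed (type, size) table so the diagnosis
stage has learnable structure.  A companion generator maps those degrees to
the seven categorical radiologist descriptors the diagnosis SVM consumes.

Geometry is analytic, so voxel counts, surface areas and placement
constraints all have closed-form oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_io import CTVolume, VoxelIndex

NODULE_TYPES = ("isolated", "juxtapleural", "juxtavascular", "ground-glass")


class PhantomError(ValueError):
    """Raised for invalid phantom specifications (overlaps, out-of-cavity nodules...)."""


@dataclass(frozen=True)
class Cavity:
    """An ellipsoidal lung cavity: center and semi-axes in mm, (z, y, x)."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def contains(self, point_mm: Sequence[float]) -> bool:
        q = (np.asarray(point_mm, float) - np.asarray(self.center)) / np.asarray(self.semiaxes)
        return float(np.dot(q, q)) <= 1.0

    def volume_mm3(self) -> float:
        a, b, c = self.semiaxes
        return 4.0 / 3.0 * math.pi * a * b * c

    def nearest_surface_point(self, point_mm: Sequence[float]) -> np.ndarray:
        """Nearest ellipsoid-surface point to an interior point.

        Uses the standard Lagrange parametrisation of the nearest surface
        point: x_i = a_i^2 q_i / (t + a_i^2), with t the root of
        sum((a_i q_i / (t + a_i^2))^2) = 1 in (-min(a_i^2), 0].
        """
        a = np.asarray(self.semiaxes, float)
        q = np.asarray(point_mm, float) - np.asarray(self.center, float)
        # avoid the exactly-on-axis singularity of the parametrisation
        q = np.where(np.abs(q) < 1e-9, 1e-9, q)
        norm = float(np.sum((q / a) ** 2))
        if norm > 1.0:
            raise PhantomError(f"point {tuple(point_mm)} is outside the cavity")

        def f(t: float) -> float:
            return float(np.sum((a * q / (t + a**2)) ** 2) - 1.0)

        lo = -float(np.min(a**2)) + 1e-9
        hi = 0.0
        if f(hi) >= 0.0:  # point numerically on the surface
            return np.asarray(point_mm, float)
        t = brentq(f, lo, hi, xtol=1e-10)
        x = a**2 * q / (t + a**2)
        return x + np.asarray(self.center, float)

    def wall_distance(self, point_mm: Sequence[float]) -> float:
        """Euclidean distance from an interior point to the ellipsoid surface."""
        return float(np.linalg.norm(self.nearest_surface_point(point_mm) - np.asarray(point_mm, float)))


@dataclass(frozen=True)
class VesselTube:
    """A straight vessel segment: endpoints in mm (z, y, x) and a radius in mm."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_mm: float

    def distance_to_axis(self, point_mm: Sequence[float]) -> float:
        p = np.asarray(point_mm, float)
        a = np.asarray(self.start, float)
        d = np.asarray(self.end, float) - a
        t = float(np.clip(np.dot(p - a, d) / np.dot(d, d), 0.0, 1.0))
        return float(np.linalg.norm(p - (a + t * d)))


@dataclass(frozen=True)
class NoduleSpec:
    """One synthetic nodule: analytic sphere + intensity + malignancy label."""

    center: tuple[float, float, float]  # mm, (z, y, x)
    diameter_mm: float
    type: str
    intensity_hu: float
    malignancy_degree: int

    def __post_init__(self) -> None:
        if not (3.0 <= self.diameter_mm <= 30.0):
            raise PhantomError(f"nodule diameter {self.diameter_mm} mm outside [3, 30] mm")
        if self.type not in NODULE_TYPES:
            raise PhantomError(f"unknown nodule type {self.type!r}; expected one of {NODULE_TYPES}")
        if self.malignancy_degree not in (1, 2, 3, 4, 5):
            raise PhantomError(f"malignancy degree must be 1..5, got {self.malignancy_degree}")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


def _default_cavities() -> tuple[Cavity, Cavity]:
    # physical field of view of the default spec is 60 x 72 x 96 mm
    right = Cavity(center=(30.0, 36.0, 26.0), semiaxes=(24.0, 27.0, 22.0))
    left = Cavity(center=(30.0, 36.0, 74.0), semiaxes=(20.0, 22.0, 18.0))
    return (right, left)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom volume.

    Intensities are HU.  The lung interior must sit inside the segmentation
    window [-1000, -200] and the wall outside it; ground-glass attenuation is
    strictly below solid attenuation.
    """

    shape: tuple[int, int, int] = (40, 104, 138)
    spacing: tuple[float, float, float] = (1.5, 0.7, 0.7)
    body_hu: float = 40.0
    lung_hu: float = -880.0
    vessel_hu: float = 30.0
    solid_nodule_hu: float = 20.0
    ground_glass_hu: float = -430.0
    noise_sigma_hu: float = 20.0
    seed: int = 0
    cavities: tuple[Cavity, Cavity] = field(default_factory=_default_cavities)
    vessels: tuple[VesselTube, ...] = ()
    nodules: tuple[NoduleSpec, ...] = ()

    def __post_init__(self) -> None:
        if not (-1000.0 <= self.lung_hu <= -200.0):
            raise PhantomError(f"lung interior HU {self.lung_hu} outside the segmentation window [-1000, -200]")
        if -1000.0 <= self.body_hu <= -200.0:
            raise PhantomError(f"wall HU {self.body_hu} must lie outside the segmentation window")
        if self.ground_glass_hu >= self.solid_nodule_hu:
            raise PhantomError("ground-glass HU must be strictly below solid-nodule HU")

    def nodule_intensity(self, ntype: str) -> float:
        return self.ground_glass_hu if ntype == "ground-glass" else self.solid_nodule_hu

    def lung_volume_voxels(self) -> float:
        """Analytic cavity volume expressed in voxels (the reference lung volume)."""
        return sum(c.volume_mm3() for c in self.cavities) / float(np.prod(self.spacing))


@dataclass
class NoduleAnnotation:
    """Ground truth for one nodule: analytic parameters plus its exact voxel set."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    type: str
    malignancy_degree: int
    voxels: np.ndarray  # (n, 3) int indices (z, y, x)

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class GroundTruth:
    """Per-case annotation: nodules, the true lung mask and suggested seeds."""

    nodules: list[NoduleAnnotation]
    lung_mask: np.ndarray  # bool, cavity union nodule voxels
    seeds: list[VoxelIndex]  # one per cavity, at the cavity centers
    case_seed: int = 0

    @property
    def lung_volume_voxels(self) -> int:
        return int(np.count_nonzero(self.lung_mask))

    def to_table(self, case_id: int | str = 0) -> pd.DataFrame:
        rows = [
            {
                "case_id": case_id,
                "nodule_id": i,
                "center_z_mm": n.center_mm[0],
                "center_y_mm": n.center_mm[1],
                "center_x_mm": n.center_mm[2],
                "diameter_mm": n.diameter_mm,
                "type": n.type,
                "malignancy_degree": n.malignancy_degree,
                "n_voxels": int(n.voxels.shape[0]),
            }
            for i, n in enumerate(self.nodules)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "case_id", "nodule_id", "center_z_mm", "center_y_mm", "center_x_mm",
                "diameter_mm", "type", "malignancy_degree", "n_voxels",
            ],
        )

    def to_json(self, path: str | Path, case_id: int | str = 0) -> None:
        doc = {
            "case_id": case_id,
            "case_seed": int(self.case_seed),
            "seeds": [s.as_tuple() for s in self.seeds],
            "lung_volume_voxels": self.lung_volume_voxels,
            "nodules": [
                {
                    "center_mm": list(n.center_mm),
                    "diameter_mm": n.diameter_mm,
                    "type": n.type,
                    "malignancy_degree": n.malignancy_degree,
                    "n_voxels": int(n.voxels.shape[0]),
                }
                for n in self.nodules
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def _mm_grids(shape, spacing):
    zz, yy, xx = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    return zz * spacing[0], yy * spacing[1], xx * spacing[2]


def _sphere_mask(shape, spacing, center, radius):
    zz, yy, xx = _mm_grids(shape, spacing)
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


def _cavity_mask(cav: Cavity, shape, spacing):
    zz, yy, xx = _mm_grids(shape, spacing)
    a = cav.semiaxes
    c = cav.center
    return ((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2 + ((xx - c[2]) / a[2]) ** 2 <= 1.0


def _tube_mask(tube: VesselTube, shape, spacing):
    z = np.arange(shape[0], dtype=float)[:, None, None] * spacing[0]
    y = np.arange(shape[1], dtype=float)[None, :, None] * spacing[1]
    x = np.arange(shape[2], dtype=float)[None, None, :] * spacing[2]
    a = np.asarray(tube.start, float)
    d = np.asarray(tube.end, float) - a
    L2 = float(np.dot(d, d))
    t = ((z - a[0]) * d[0] + (y - a[1]) * d[1] + (x - a[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dz = z - (a[0] + t * d[0])
    dy = y - (a[1] + t * d[1])
    dx = x - (a[2] + t * d[2])
    return dz**2 + dy**2 + dx**2 <= tube.radius_mm**2


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Voxelize a PhantomSpec into a CT volume and its ground truth.

    Deterministic for a fixed ``spec.seed``.  Ground-truth voxel sets are
    exactly the voxels whose centers fall inside each analytic sphere (for
    juxtapleural nodules that includes the sliver protruding into the wall).

    Raises
    ------
    PhantomError
        If two nodules overlap or a nodule center lies outside both cavities.
    """
    shape, spacing = spec.shape, spec.spacing

    for i, n in enumerate(spec.nodules):
        if not any(c.contains(n.center) for c in spec.cavities):
            raise PhantomError(f"nodule {i} center {n.center} lies outside both lung cavities")
        for j in range(i + 1, len(spec.nodules)):
            m = spec.nodules[j]
            gap = float(np.linalg.norm(np.subtract(n.center, m.center)))
            if gap < n.radius_mm + m.radius_mm:
                raise PhantomError(f"nodules {i} and {j} overlap (center gap {gap:.2f} mm)")

    vol = np.full(shape, spec.body_hu, dtype=np.float32)
    cavity_union = np.zeros(shape, dtype=bool)
    for cav in spec.cavities:
        cavity_union |= _cavity_mask(cav, shape, spacing)
    vol[cavity_union] = spec.lung_hu

    for tube in spec.vessels:
        vol[_tube_mask(tube, shape, spacing) & cavity_union] = spec.vessel_hu

    annotations: list[NoduleAnnotation] = []
    lung_mask = cavity_union.copy()
    # Juxtapleural nodules deform the pleura: lung air wraps their flanks down
    # to a narrow attachment base, so paint an air collar around each one
    # (except the base cap facing the wall) before painting the spheres.
    for n in spec.nodules:
        if n.type != "juxtapleural":
            continue
        cav = next((c for c in spec.cavities if c.contains(n.center)), None)
        if cav is None:
            continue
        u = cav.nearest_surface_point(n.center) - np.asarray(n.center, float)
        if np.linalg.norm(u) < 1e-9:
            continue
        u = u / np.linalg.norm(u)
        r = n.radius_mm
        base_radius = max(1.0, 0.25 * r)
        base_cos = math.sqrt(max(0.0, 1.0 - (base_radius / r) ** 2))
        zz, yy, xx = _mm_grids(shape, spacing)
        dz, dy, dx = zz - n.center[0], yy - n.center[1], xx - n.center[2]
        dist = np.sqrt(dz**2 + dy**2 + dx**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_angle = (dz * u[0] + dy * u[1] + dx * u[2]) / np.where(dist > 0, dist, 1.0)
        collar = (dist > r) & (dist <= r + _JP_COLLAR_MM) & (cos_angle < base_cos)
        vol[collar] = spec.lung_hu
        lung_mask |= collar

    for n in spec.nodules:
        sph = _sphere_mask(shape, spacing, n.center, n.radius_mm)
        vol[sph] = n.intensity_hu
        lung_mask |= sph
        annotations.append(
            NoduleAnnotation(
                center_mm=tuple(n.center),
                diameter_mm=n.diameter_mm,
                type=n.type,
                malignancy_degree=n.malignancy_degree,
                voxels=np.argwhere(sph),
            )
        )

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma_hu > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma_hu, size=shape).astype(np.float32)

    # suggested seeds: the free-air voxel nearest each cavity center (a nodule
    # or vessel may sit exactly at the center)
    free = cavity_union & (np.abs(vol - spec.lung_hu) < 6 * max(spec.noise_sigma_hu, 1.0))
    seeds = []
    for c in spec.cavities:
        target = np.asarray(c.center) / np.asarray(spacing)
        idx = np.argwhere(_cavity_mask(Cavity(c.center, tuple(s * 0.5 for s in c.semiaxes)), shape, spacing) & free)
        if idx.size == 0:
            idx = np.argwhere(free)
        best = idx[np.argmin(np.sum((idx - target) ** 2, axis=1))]
        seeds.append(VoxelIndex(*(int(v) for v in best)))
    return (
        CTVolume(vol, spacing=spacing),
        GroundTruth(nodules=annotations, lung_mask=lung_mask, seeds=seeds, case_seed=spec.seed),
    )


# ---------------------------------------------------------------------------
# Malignancy-degree assignment and diagnosis-feature synthesis
# ---------------------------------------------------------------------------

#: Fixed (type, diameter) -> degree table.  Diameter cut-offs in mm.  The
#: ordering follows the usual radiological priors: ground-glass attenuation
#: and vascular attachment raise suspicion, small sharply-bounded solid
#: nodules lower it.
def assign_malignancy_degree(ntype: str, diameter_mm: float) -> int:
    if ntype == "isolated":
        return 1 if diameter_mm < 6 else (2 if diameter_mm < 10 else 3)
    if ntype == "juxtapleural":
        return 2 if diameter_mm < 13 else 3
    if ntype == "juxtavascular":
        return 3 if diameter_mm < 8 else 4
    if ntype == "ground-glass":
        return 4 if diameter_mm < 9 else 5
    raise PhantomError(f"unknown nodule type {ntype!r}")


#: Prototype Table-1 descriptor (as value indices per field) for each degree.
#: Field order matches nodulecad.malignancy.FEATURE_VALUES.
DEGREE_PROTOTYPES: dict[int, dict[str, int]] = {
    1: {"calcification": 4, "internal_structure": 0, "lobulation": 2, "margin": 2,
        "sphericity": 2, "spiculation": 2, "texture": 2},
    2: {"calcification": 1, "internal_structure": 0, "lobulation": 2, "margin": 2,
        "sphericity": 2, "spiculation": 1, "texture": 2},
    3: {"calcification": 5, "internal_structure": 0, "lobulation": 1, "margin": 1,
        "sphericity": 1, "spiculation": 1, "texture": 1},
    4: {"calcification": 5, "internal_structure": 0, "lobulation": 0, "margin": 0,
        "sphericity": 1, "spiculation": 1, "texture": 1},
    5: {"calcification": 5, "internal_structure": 0, "lobulation": 0, "margin": 0,
        "sphericity": 0, "spiculation": 0, "texture": 0},
}


def generate_diagnosis_features(
    degrees: Sequence[int],
    seed: int = 0,
    flip_prob: float = 0.08,
) -> pd.DataFrame:
    """Synthesize radiologist descriptor records for given malignancy degrees.

    Each record starts at its degree's prototype; independently per field,
    with probability ``flip_prob`` the value is nudged one ordinal step
    (clipped to the field's range).  ``flip_prob=0`` yields noiseless tables.

    Returns a DataFrame with the seven descriptor columns (category strings)
    plus a ``degree`` column.
    """
    from .malignancy import FEATURE_VALUES

    rng = np.random.default_rng(seed)
    rows = []
    for deg in degrees:
        proto = DEGREE_PROTOTYPES[int(deg)]
        rec: dict[str, object] = {}
        for fname, values in FEATURE_VALUES.items():
            code = proto[fname]
            if flip_prob > 0 and rng.random() < flip_prob:
                code = int(np.clip(code + rng.choice((-1, 1)), 0, len(values) - 1))
            rec[fname] = values[code]
        rec["degree"] = int(deg)
        rows.append(rec)
    cols = list(FEATURE_VALUES.keys()) + ["degree"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Randomized case sampling
# ---------------------------------------------------------------------------

_TYPE_PROBS = {"isolated": 0.30, "juxtapleural": 0.25, "juxtavascular": 0.25, "ground-glass": 0.20}
_DIAMETER_RANGES = {
    "isolated": (4.0, 14.0),
    "juxtapleural": (9.0, 15.0),
    "juxtavascular": (4.0, 10.0),
    "ground-glass": (5.0, 14.0),
}
#: Target analytic protrusion of a juxtapleural sphere past the cavity wall, mm.
_JP_PROTRUSION_MM = 0.3
#: Thickness of the air collar wrapping a juxtapleural nodule's flanks, mm.
_JP_COLLAR_MM = 1.6
#: Ceiling on the fraction of a juxtapleural nodule's voxels inside the wall.
_JP_MAX_OUTSIDE_FRACTION = 0.007


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _point_in_cavity(cav: Cavity, rng: np.random.Generator, margin: float) -> np.ndarray | None:
    for _ in range(200):
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(u, u) > 1.0:
            continue
        p = np.asarray(cav.center) + u * np.asarray(cav.semiaxes)
        if not cav.contains(p):
            continue
        if cav.wall_distance(p) >= margin:
            return p
    return None


def _clear_of(p: np.ndarray, r: float, placed: list[NoduleSpec], vessels: Sequence[VesselTube],
              skip_vessel: VesselTube | None = None, vessel_gap: float = 2.0) -> bool:
    for n in placed:
        if np.linalg.norm(p - np.asarray(n.center)) < r + n.radius_mm + 2.0:
            return False
    for t in vessels:
        if t is skip_vessel:
            continue
        if t.distance_to_axis(p) < r + t.radius_mm + vessel_gap:
            return False
    return True


def _sample_vessels(spec: PhantomSpec, rng: np.random.Generator) -> tuple[VesselTube, ...]:
    """Two tubes per cavity, from the hilum side toward the far wall."""
    tubes = []
    for cav in spec.cavities:
        c = np.asarray(cav.center)
        a = np.asarray(cav.semiaxes)
        toward_mid = 1.0 if c[2] < 48.0 else -1.0  # hilum faces the mediastinum
        for _ in range(2):
            start = c + np.array([rng.uniform(-0.2, 0.2) * a[0],
                                  rng.uniform(-0.3, 0.3) * a[1],
                                  toward_mid * 0.80 * a[2]])
            u = rng.uniform(-1.0, 1.0, size=3)
            u[2] = -toward_mid * abs(u[2]) - 0.3 * toward_mid
            u /= np.linalg.norm(u)
            end = c + 0.80 * a * u
            tubes.append(VesselTube(start=tuple(start), end=tuple(end), radius_mm=float(rng.uniform(1.2, 2.2))))
    return tuple(tubes)


def _sphere_voxel_stats(spec: PhantomSpec, cavity_union: np.ndarray, center: np.ndarray, r: float):
    """(fraction of sphere voxels outside the cavities, wall face-adjacency flag)."""
    shape, spacing = spec.shape, spec.spacing
    lo = np.maximum(np.floor((center - r) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((center + r) / spacing).astype(int) + 2, shape)
    sub = tuple(slice(int(lo[k]), int(hi[k])) for k in range(3))
    zz = np.arange(lo[0], hi[0])[:, None, None] * spacing[0]
    yy = np.arange(lo[1], hi[1])[None, :, None] * spacing[1]
    xx = np.arange(lo[2], hi[2])[None, None, :] * spacing[2]
    sph = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= r**2
    if not sph.any():
        return 1.0, False
    cav = cavity_union[sub]
    frac_out = 1.0 - float(np.count_nonzero(sph & cav)) / float(np.count_nonzero(sph))
    # face-adjacency between the sphere and non-cavity, non-sphere voxels
    outside = ~cav & ~sph
    adj = False
    for axis in range(3):
        a = np.swapaxes(sph, 0, axis)
        b = np.swapaxes(outside, 0, axis)
        if (a[:-1] & b[1:]).any() or (a[1:] & b[:-1]).any():
            adj = True
            break
    if (sph & ~cav).any():
        adj = True
    return frac_out, adj


def _place_juxtapleural(spec: PhantomSpec, cavity_union: np.ndarray, cav: Cavity,
                        r: float, rng: np.random.Generator,
                        placed: list[NoduleSpec], vessels: Sequence[VesselTube]) -> np.ndarray | None:
    c0 = np.asarray(cav.center)
    for _ in range(60):
        # contact is placed on the lateral pleura: an in-plane direction, so the
        # contact geometry is resolved at the finer in-plane pixel size
        ang = rng.uniform(0.0, 2.0 * math.pi)
        u = np.array([0.0, math.sin(ang), math.cos(ang)])
        r_dir = 1.0 / math.sqrt(float(np.sum((u / np.asarray(cav.semiaxes)) ** 2)))
        if r_dir < r + 2.0:
            continue
        for protrusion in (_JP_PROTRUSION_MM, _JP_PROTRUSION_MM + 0.15, _JP_PROTRUSION_MM + 0.30):
            target_gap = r - protrusion

            def gap_minus_target(s: float) -> float:
                return cav.wall_distance(c0 + s * u) - target_gap

            lo, hi = 0.0, r_dir * (1.0 - 1e-6)
            if gap_minus_target(lo) < 0.0 or gap_minus_target(hi) > 0.0:
                continue
            s = brentq(gap_minus_target, lo, hi, xtol=1e-6)
            p = c0 + s * u
            frac_out, adj = _sphere_voxel_stats(spec, cavity_union, p, r)
            if adj and frac_out <= _JP_MAX_OUTSIDE_FRACTION and _clear_of(p, r, placed, vessels):
                return p
    return None


def sample_case(
    template: PhantomSpec,
    case_seed: int,
    nodules_per_case: tuple[int, int] = (1, 8),
) -> PhantomSpec:
    """Draw one randomized case spec (vessels + nodules) from a template.

    The nodule count is uniform on ``nodules_per_case`` (default 1-8 per
    case); types follow a fixed mix covering all four classes; diameters are
    uniform within per-type ranges chosen so every nodule fits its placement
    constraint inside the cavities.
    """
    rng = np.random.default_rng(case_seed)
    vessels = _sample_vessels(template, rng)
    spec = replace(template, vessels=vessels, nodules=(), seed=case_seed)

    cavity_union = np.zeros(spec.shape, dtype=bool)
    for cav in spec.cavities:
        cavity_union |= _cavity_mask(cav, spec.shape, spec.spacing)

    n_nodules = int(rng.integers(nodules_per_case[0], nodules_per_case[1] + 1))
    type_names = list(_TYPE_PROBS)
    type_p = np.array([_TYPE_PROBS[t] for t in type_names])
    cav_p = np.array([c.volume_mm3() for c in spec.cavities])
    cav_p = cav_p / cav_p.sum()

    placed: list[NoduleSpec] = []
    attempts = 0
    while len(placed) < n_nodules and attempts < 40 * n_nodules:
        attempts += 1
        ntype = str(rng.choice(type_names, p=type_p))
        lo, hi = _DIAMETER_RANGES[ntype]
        d = float(rng.uniform(lo, hi))
        r = d / 2.0
        cav = spec.cavities[int(rng.choice(len(spec.cavities), p=cav_p))]
        center: np.ndarray | None = None

        if ntype == "juxtapleural":
            center = _place_juxtapleural(spec, cavity_union, cav, r, rng, placed, vessels)
        elif ntype == "juxtavascular":
            for _ in range(40):
                tube = vessels[int(rng.integers(len(vessels)))]
                a = np.asarray(tube.start)
                dvec = np.asarray(tube.end) - a
                point = a + rng.uniform(0.25, 0.75) * dvec
                axis = dvec / np.linalg.norm(dvec)
                perp = np.cross(axis, _random_unit(rng))
                if np.linalg.norm(perp) < 1e-6:
                    continue
                perp /= np.linalg.norm(perp)
                p = point + (r + tube.radius_mm) * perp  # tangent to the vessel
                inside = next((cv for cv in spec.cavities if cv.contains(p)), None)
                if inside is None or inside.wall_distance(p) < r + 1.5:
                    continue
                if _clear_of(p, r, placed, vessels, skip_vessel=tube, vessel_gap=1.0):
                    center = p
                    break
        else:  # isolated / ground-glass: well inside the cavity, clear of vessels
            for _ in range(40):
                p = _point_in_cavity(cav, rng, margin=r + 3.0)
                if p is not None and _clear_of(p, r, placed, vessels):
                    center = p
                    break

        if center is None:
            continue
        placed.append(
            NoduleSpec(
                center=tuple(float(v) for v in center),
                diameter_mm=d,
                type=ntype,
                intensity_hu=spec.nodule_intensity(ntype),
                malignancy_degree=assign_malignancy_degree(ntype, d),
            )
        )

    if not placed:
        raise PhantomError(f"could not place any nodule for case seed {case_seed}")
    return replace(spec, nodules=tuple(placed))


def generate_dataset(
    n_cases: int,
    template: PhantomSpec | None = None,
    seed: int = 0,
    nodules_per_case: tuple[int, int] = (1, 8),
) -> list[tuple[CTVolume, GroundTruth]]:
    """Generate ``n_cases`` phantom cases with per-case seeds derived from ``seed``."""
    if n_cases < 1:
        raise PhantomError("n_cases must be >= 1")
    template = template or PhantomSpec()
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n_cases)
    dataset = []
    for cs in case_seeds:
        spec = sample_case(template, int(cs), nodules_per_case)
        dataset.append(generate_phantom(spec))
    return dataset


def write_dataset(dataset: Iterable[tuple[CTVolume, GroundTruth]], out_dir: str | Path) -> pd.DataFrame:
    """Write volumes (NIfTI), per-case ground-truth JSON and a combined nodule CSV."""
    from . import core_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = []
    for i, (vol, gt) in enumerate(dataset):
        core_io.write_volume(vol, out_dir / f"case_{i:03d}.nii.gz")
        gt.to_json(out_dir / f"case_{i:03d}_truth.json", case_id=i)
        tables.append(gt.to_table(case_id=i))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out_dir / "nodules.csv", index=False)
    return table
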