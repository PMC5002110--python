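"""False-positive elimination: per-slice HOG descriptors, PCA, RBF SVM.

Each surviving candidate is described by histogram-of-oriented-gradients
features computed slice by slice on its bounding-box patch; the slice
descriptors are concatenated in slice order and resampled by linear
interpolation to a fixed length so that candidates spanning different
numbers of slices become comparable vectors.  PCA then keeps the smallest
number of components reaching 80 % of the training variance, and a binary
RBF support-vector machine (C = 5, gamma = 1/n with n the reduced feature
count) separates nodules from non-nodules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.feature import hog
from skimage.transform import resize
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .core_io import CTVolume
from .structure_seg import CandidateObject


class DescriptorError(ValueError):
    """Raised for empty patches or descriptor-length mismatches."""


@dataclass(frozen=True)
class HOGConfig:
    """HOG parameters plus the fixed post-resampling descriptor length.

    Cell/block/orientation values follow common HOG practice (9
    orientations, 8x8-pixel cells, 2x2-cell blocks, L2-Hys block norm).
    Patches are the candidate's in-plane bounding box with ``margin_voxels``
    of context, intensity-windowed to ``hu_window`` and min-max scaled per
    slice patch; patches narrower than 16 px are upscaled so at least one
    2x2 block fits.
    """

    orientations: int = 9
    pixels_per_cell: tuple[int, int] = (8, 8)
    cells_per_block: tuple[int, int] = (2, 2)
    block_norm: str = "L2-Hys"
    length: int = 4096
    margin_voxels: int = 2
    hu_window: tuple[float, float] = (-1000.0, 400.0)

    def __post_init__(self) -> None:
        if self.length < self.orientations:
            raise ValueError("descriptor length must be >= orientations")
        if min(self.pixels_per_cell) < 1 or min(self.cells_per_block) < 1:
            raise ValueError("cell/block sizes must be positive")


@dataclass
class PCAModel:
    """Principal components retaining a target fraction of training variance."""

    mean: np.ndarray
    components: np.ndarray  # (k, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray  # per kept component
    retained_target: float
    retained_variance: float

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) @ self.components.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=np.float64) @ self.components + self.mean


@dataclass(frozen=True)
class SVMConfig:
    """RBF SVM settings shared by detection and diagnosis.

    ``gamma`` is resolved at fit time as ``1/n`` with ``n`` the feature
    count; the multiclass scheme (when more than two classes are present)
    is one-vs-one.
    """

    C: float = 5.0
    kernel: str = "rbf"
    gamma_mode: str = "reciprocal_n"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")

    def resolve_gamma(self, n_features: int) -> float:
        if self.gamma_mode == "reciprocal_n":
            return 1.0 / n_features
        return float(self.gamma_mode)


@dataclass
class DetectionModel:
    """Fitted PCA + binary SVM + the HOG configuration that produced the training data."""

    hog_config: HOGConfig
    pca: PCAModel
    svm: SVC
    gamma: float
    seed: int
    n_train: int
    class_counts: dict[str, int]


def extract_patch(c: CandidateObject, vol: CTVolume, cfg: HOGConfig, z: int) -> np.ndarray:
    """One axial patch: bounding box + margin, HU-windowed, min-max scaled."""
    (_, _), (y0, y1), (x0, x1) = c.bbox
    m = cfg.margin_voxels
    y0, y1 = max(0, y0 - m), min(vol.shape[1], y1 + m)
    x0, x1 = max(0, x0 - m), min(vol.shape[2], x1 + m)
    patch = vol.voxels[z, y0:y1, x0:x1].astype(np.float64)
    if patch.size == 0:
        raise DescriptorError(f"candidate {c.label}: empty patch at slice {z}")
    lo, hi = cfg.hu_window
    patch = np.clip(patch, lo, hi)
    pmin, pmax = patch.min(), patch.max()
    patch = (patch - pmin) / (pmax - pmin) if pmax > pmin else np.zeros_like(patch)
    min_px = 8 * max(cfg.cells_per_block)  # at least one block must fit
    if patch.shape[0] < min_px or patch.shape[1] < min_px:
        patch = resize(
            patch,
            (max(patch.shape[0], min_px), max(patch.shape[1], min_px)),
            order=1, mode="edge", anti_aliasing=False, preserve_range=True,
        )
    return patch


def hog_descriptor(c: CandidateObject, vol: CTVolume, cfg: HOGConfig | None = None) -> np.ndarray:
    """Fixed-length HOG descriptor of a candidate.

    Per-slice HOGs are concatenated in slice order; the variable-length
    concatenation is resampled by linear interpolation to exactly
    ``cfg.length`` values.  All outputs are >= 0; a constant patch yields an
    all-zero contribution.
    """
    cfg = cfg or HOGConfig()
    if c.ns < 1:
        raise DescriptorError("candidate spans no slices")
    parts = []
    for z in range(c.slice_range[0], c.slice_range[1] + 1):
        patch = extract_patch(c, vol, cfg, z)
        parts.append(
            hog(
                patch,
                orientations=cfg.orientations,
                pixels_per_cell=cfg.pixels_per_cell,
                cells_per_block=cfg.cells_per_block,
                block_norm=cfg.block_norm,
                feature_vector=True,
            )
        )
    concat = np.concatenate(parts)
    if concat.size == 0:
        raise DescriptorError(f"candidate {c.label}: empty HOG concatenation")
    if concat.size == 1:
        return np.full(cfg.length, float(concat[0]))
    xp = np.linspace(0.0, 1.0, concat.size)
    xq = np.linspace(0.0, 1.0, cfg.length)
    return np.interp(xq, xp, concat)


def fit_pca(descriptors: np.ndarray, retained: float = 0.80) -> PCAModel:
    """Fit PCA keeping the smallest component count reaching ``retained`` variance.

    The component count is chosen without being fixed in advance: the full
    spectrum is computed and truncated at the first cumulative
    explained-variance ratio >= ``retained`` (up to fp rounding).
    """
    if not (0.0 < retained <= 1.0):
        raise ValueError(f"retained variance fraction must lie in (0, 1], got {retained}")
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2D matrix with at least 2 training rows")
    p = PCA(n_components=None, svd_solver="full").fit(X)
    cum = np.cumsum(p.explained_variance_ratio_)
    k = int(np.argmax(cum >= retained - 1e-12)) + 1
    return PCAModel(
        mean=p.mean_,
        components=p.components_[:k],
        explained_variance_ratio=p.explained_variance_ratio_[:k],
        retained_target=retained,
        retained_variance=float(cum[k - 1]),
    )


def train_detector(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: SVMConfig | None = None,
    seed: int = 0,
) -> SVC:
    """Fit the binary nodule/non-nodule SVM on PCA-reduced features.

    ``gamma`` is set to ``1/n`` with ``n = features.shape[1]``.
    Deterministic for fixed inputs and seed.
    """
    cfg = cfg or SVMConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    svm = SVC(
        C=cfg.C,
        kernel=cfg.kernel,
        gamma=cfg.resolve_gamma(X.shape[1]),
        random_state=seed,
    )
    svm.fit(X, y)
    return svm


def fit_detection_model(
    descriptors: np.ndarray,
    labels: np.ndarray,
    hog_cfg: HOGConfig | None = None,
    svm_cfg: SVMConfig | None = None,
    retained: float = 0.80,
    seed: int = 0,
) -> DetectionModel:
    """End-to-end detector fit: PCA on raw descriptors, then the SVM."""
    hog_cfg = hog_cfg or HOGConfig()
    svm_cfg = svm_cfg or SVMConfig()
    y = np.asarray(labels).astype(int)
    pca = fit_pca(descriptors, retained)
    Z = pca.transform(descriptors)
    svm = train_detector(Z, y, svm_cfg, seed)
    return DetectionModel(
        hog_config=hog_cfg,
        pca=pca,
        svm=svm,
        gamma=svm_cfg.resolve_gamma(pca.n_components),
        seed=seed,
        n_train=int(y.size),
        class_counts={"nodule": int((y == 1).sum()), "non-nodule": int((y == 0).sum())},
    )


def classify_candidates(model: DetectionModel, descriptors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label descriptors as nodule/non-nodule with a continuous decision score.

    Scores are the signed SVM decision values (positive = nodule), suitable
    for ROC sweeps.  Deterministic: the same input yields the same output.
    """
    X = np.atleast_2d(np.asarray(descriptors, dtype=np.float64))
    expected = model.pca.mean.shape[0]
    if X.shape[1] != expected:
        raise DescriptorError(
            f"descriptor length mismatch: expected {expected}, got {X.shape[1]}"
        )
    scores = model.svm.decision_function(model.pca.transform(X))
    labels = np.where(scores > 0, "nodule", "non-nodule")
    return labels, scores


def save_model(model: DetectionModel, path: str | Path) -> None:
    """Serialize a detector (PCA arrays, SVM, configs, seed) to one archive file."""
    import joblib

    joblib.dump(model, path)


def load_model(path: str | Path) -> DetectionModel:
    import joblib

    model = joblib.load(path)
    if not isinstance(model, DetectionModel):
        raise DescriptorError(f"{path} does not contain a DetectionModel")
    return model
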