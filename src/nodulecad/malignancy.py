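"""Likelihood-of-malignancy scoring (the CADx stage).

A radiologist describes each detected nodule with seven categorical
features (calcification pattern, internal structure, lobulation, margin,
sphericity, spiculation, texture); a one-vs-one RBF SVM (C = 5, gamma = 1/7)
maps the encoded description to one of five malignancy degrees: highly
unlikely, moderately unlikely, indeterminate, moderately suspicious, highly
suspicious.

Features are encoded ordinally: each field's printed vocabulary order gives
integer codes 0..k-1, scaled to [0, 1].  The vocabularies are graded
(e.g. marked / intermediate / none), which is why ordinal rather than
one-hot encoding is the default.  Patient age and smoking status are cohort
framing, not model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

DEGREE_NAMES = {
    1: "highly unlikely",
    2: "moderately unlikely",
    3: "indeterminate",
    4: "moderately suspicious",
    5: "highly suspicious",
}

#: The seven descriptor vocabularies, in their canonical printed order
#: (first listed value encodes to 0).
FEATURE_VALUES: dict[str, tuple[str, ...]] = {
    "calcification": ("popcorn", "laminated", "solid", "non-central", "central", "absent"),
    "internal_structure": ("soft tissue", "fluid", "fat", "air"),
    "lobulation": ("marked", "intermediate", "none"),
    "margin": ("poorly defined", "intermediate", "sharp"),
    "sphericity": ("linear", "ovoid", "round"),
    "spiculation": ("marked", "intermediate", "none"),
    "texture": ("non-solid", "part solid/(mixed)", "solid"),
}

N_FEATURES = len(FEATURE_VALUES)


class VocabularyError(ValueError):
    """An unknown category string; the message lists the allowed values."""


@dataclass(frozen=True)
class NoduleDiagnosisFeatures:
    """One radiologist description; every field must use its printed vocabulary."""

    calcification: str
    internal_structure: str
    lobulation: str
    margin: str
    sphericity: str
    spiculation: str
    texture: str

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            allowed = FEATURE_VALUES[f.name]
            if value not in allowed:
                raise VocabularyError(
                    f"{f.name}={value!r} is not a valid value; allowed: {list(allowed)}"
                )


def encode_features(f: NoduleDiagnosisFeatures) -> np.ndarray:
    """Encode to a 7-vector of per-field ordinal codes scaled to [0, 1]."""
    vec = np.empty(N_FEATURES)
    for i, (name, values) in enumerate(FEATURE_VALUES.items()):
        code = values.index(getattr(f, name))
        vec[i] = code / (len(values) - 1)
    return vec


def decode_features(vec: np.ndarray) -> NoduleDiagnosisFeatures:
    """Invert :func:`encode_features` (the encoding is bijective)."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_FEATURES,):
        raise ValueError(f"expected a 7-vector, got shape {vec.shape}")
    kwargs = {}
    for i, (name, values) in enumerate(FEATURE_VALUES.items()):
        code = int(round(vec[i] * (len(values) - 1)))
        if not (0 <= code < len(values)) or abs(vec[i] * (len(values) - 1) - code) > 1e-6:
            raise ValueError(f"component {i} ({name}) = {vec[i]} is not a valid code")
        kwargs[name] = values[code]
    return NoduleDiagnosisFeatures(**kwargs)


@dataclass
class MalignancyModel:
    """Fitted 5-class one-vs-one SVM over the 7 encoded descriptors."""

    svm: SVC
    seed: int
    classes: np.ndarray
    _probe: np.ndarray  # one encoded training row, used to introspect the ovo machinery

    @property
    def gamma(self) -> float:
        return float(self.svm.gamma)

    @property
    def n_binary_classifiers(self) -> int:
        """Count of underlying pairwise machines, measured from the one-vs-one decision values."""
        prev = self.svm.decision_function_shape
        try:
            self.svm.decision_function_shape = "ovo"
            return int(np.atleast_2d(self.svm.decision_function(self._probe[None, :])).shape[1])
        finally:
            self.svm.decision_function_shape = prev


def train_malignancy(features: np.ndarray, degrees: np.ndarray, seed: int = 0) -> MalignancyModel:
    """Fit the diagnosis SVM (C = 5, gamma = 1/7, one-vs-one).

    With all five degrees present, 5*4/2 = 10 pairwise machines are
    constructed.  Raises on single-class input.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(degrees).astype(int)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (n, {N_FEATURES}), got {X.shape}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("at least two distinct malignancy degrees are required for training")
    svm = SVC(
        C=5.0,
        kernel="rbf",
        gamma=1.0 / N_FEATURES,
        decision_function_shape="ovr",  # 5 per-degree score columns; internally one-vs-one
        random_state=seed,
    )
    svm.fit(X, y)
    return MalignancyModel(svm=svm, seed=seed, classes=classes, _probe=X[0].copy())


def predict_malignancy(
    model: MalignancyModel,
    f: NoduleDiagnosisFeatures | np.ndarray,
) -> tuple[int, np.ndarray]:
    """Predict the degree plus a per-degree continuous score vector.

    The scores (one per trained degree) feed the per-degree ROC analysis.
    Deterministic for a fixed model.
    """
    from sklearn.exceptions import NotFittedError
    from sklearn.utils.validation import check_is_fitted

    try:
        check_is_fitted(model.svm)
    except NotFittedError as exc:
        raise ValueError("malignancy model is not fitted") from exc
    vec = encode_features(f) if isinstance(f, NoduleDiagnosisFeatures) else np.asarray(f, dtype=float)
    if vec.shape != (N_FEATURES,):
        raise ValueError(f"expected a 7-vector, got shape {vec.shape}")
    degree = int(model.svm.predict(vec[None, :])[0])
    scores = np.atleast_2d(model.svm.decision_function(vec[None, :]))[0]
    return degree, scores


def save_malignancy_model(model: MalignancyModel, path: str | Path) -> None:
    import joblib

    joblib.dump(model, path)


def load_malignancy_model(path: str | Path) -> MalignancyModel:
    import joblib

    model = joblib.load(path)
    if not isinstance(model, MalignancyModel):
        raise ValueError(f"{path} does not contain a MalignancyModel")
    return model
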