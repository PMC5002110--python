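"""Shared fixtures: phantom cases and the (expensive) end-to-end experiment."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from nodulecad import experiments, phantom
from nodulecad.phantom import NODULE_TYPES, PhantomSpec
from nodulecad.pipeline import process_case

logging.getLogger("nodulecad").setLevel(logging.ERROR)

#: Seed of the frozen test study; every stochastic fixture derives from it.
STUDY_SEED = 1001


@pytest.fixture(scope="session")
def template() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def mixed_case(template):
    """One deterministic phantom case containing all four nodule types."""
    for seed in range(STUDY_SEED, STUDY_SEED + 50):
        spec = phantom.sample_case(template, case_seed=seed, nodules_per_case=(5, 8))
        types = {n.type for n in spec.nodules}
        if types == set(NODULE_TYPES):
            vol, gt = phantom.generate_phantom(spec)
            return spec, vol, gt
    raise RuntimeError("no case with all four nodule types found in the seed range")


@pytest.fixture(scope="session")
def phantom_cfg(template):
    return experiments.phantom_pipeline_config(template)


@pytest.fixture(scope="session")
def processed_mixed(mixed_case, phantom_cfg):
    """The CADe stages (through the rules) run on the mixed-type case."""
    _, vol, gt = mixed_case
    return process_case(vol, gt.seeds, phantom_cfg)


@pytest.fixture(scope="session")
def detection_experiment():
    """The full 40-case train/test phantom detection study (shared: it is slow)."""
    return experiments.run_detection_experiment(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def clean_phantom(template):
    """A nodule- and vessel-free phantom volume."""
    spec = PhantomSpec(seed=STUDY_SEED)
    return spec, *phantom.generate_phantom(spec)


def make_candidate(mask: np.ndarray, label: int = 1, voxel_volume: float = 1.0):
    """Build a CandidateObject straight from a boolean voxel mask (unit spacing)."""
    from nodulecad.structure_seg import CandidateObject

    idx = np.argwhere(mask)
    volume = idx.shape[0] * voxel_volume
    return CandidateObject(
        label=label,
        voxels=idx,
        slice_range=(int(idx[:, 0].min()), int(idx[:, 0].max())),
        volume_mm3=float(volume),
        equivalent_diameter_mm=float((6 * volume / np.pi) ** (1 / 3)),
        mean_hu=0.0,
        centroid_mm=idx.mean(axis=0).astype(float),
        bbox=tuple((int(idx[:, k].min()), int(idx[:, k].max()) + 1) for k in range(3)),
    )
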