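"""Shared fixtures: phantoms and derived objects are built once per session
(everything downstream treats them as read-only)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from bacumorph import align, extract_semilandmarks
from bacumorph.config import PipelineConfig
from bacumorph.synthetic import BonePhantomParams, generate_bone


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def phantom_params() -> BonePhantomParams:
    return BonePhantomParams(seed=42)


@pytest.fixture(scope="session")
def phantom(phantom_params):
    return generate_bone(phantom_params, specimen_id="phantom42")


@pytest.fixture(scope="session")
def aligned_phantom(phantom, default_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return align(phantom, default_config)


@pytest.fixture(scope="session")
def phantom_landmarks(aligned_phantom, default_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_semilandmarks(aligned_phantom, default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
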