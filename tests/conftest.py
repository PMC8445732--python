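"""Shared fixtures: small synthetic eyes and datasets.

Everything is generated at test time from fixed seeds; no stored fixtures.
"""

from __future__ import annotations

import os

# pin BLAS threading before numpy loads: float32 reductions must not depend
# on the host's core count for seeded runs to be reproducible
for _var in (
    "OMP_NUM_THREADS",
    "OPENBLAS_NUM_THREADS",
    "MKL_NUM_THREADS",
    "NUMEXPR_NUM_THREADS",
    "VECLIB_MAXIMUM_THREADS",
):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from angiograde.frames import Grade
from angiograde.synth import generate_dataset, generate_eye, params_for_grade


@pytest.fixture(scope="session")
def pdr_eye():
    """One PDR eye at full resolution with heavy planted burden."""
    return generate_eye(params_for_grade(Grade.PDR, image_size=128, seed=42))


@pytest.fixture(scope="session")
def npdr_eye():
    return generate_eye(params_for_grade(Grade.NPDR, image_size=128, seed=7))


@pytest.fixture(scope="session")
def normal_eye():
    return generate_eye(params_for_grade(Grade.NORMAL, image_size=128, seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 15-eye dataset at GAN scale (64 px)."""
    return generate_dataset(5, 5, 5, seed=33, image_size=64)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
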