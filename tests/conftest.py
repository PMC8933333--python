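"""Shared fixtures: small designs and a calibrated two-region model."""

import numpy as np
import pytest

from bdcm.design import generate_task_design
from bdcm.network import BDCMParams, default_posner_structure


@pytest.fixture(scope="session")
def small_design():
    """Two blocks of 20 trials - the scaled-down cueing run used in tests."""
    return generate_task_design(n_blocks=2, trials_per_block=20, seed=42)


@pytest.fixture(scope="session")
def default_design():
    """The full 5 x 40 cueing run."""
    return generate_task_design(seed=7)


@pytest.fixture(scope="session")
def two_region():
    """A bilateral one-area network with known, identifiable parameters."""
    structure = default_posner_structure(
        region_labels=("A-L", "A-R"), output_regions=("A-L",)
    )
    truth = BDCMParams.zeros(structure)
    truth.A[:] = [[-0.5, 0.2], [0.4, -0.5]]
    truth.C[:, 0] = [0.7, 0.5]
    truth.B[1, 0, 1] = 2.0
    truth.B[1, 1, 0] = 3.0
    truth.ar[0] = -0.03
    truth.decay = 0.3
    truth.rho = -0.0161
    return structure, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
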