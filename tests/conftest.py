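"""Shared fixtures: all data is generated in-process, nothing on disk."""

from __future__ import annotations

import numpy as np
import pytest

from prfpipe import (
    CohortSimConfig,
    ExposureSimConfig,
    ExpressionMatrix,
    generate_cohort,
    generate_exposure_study,
)


@pytest.fixture(scope="session")
def exposure_default():
    """Default exposure study at the package's default seed."""
    config = ExposureSimConfig(seed=0)
    matrix, annotations, truth = generate_exposure_study(config)
    return config, matrix, annotations, truth


@pytest.fixture(scope="session")
def cohort_default():
    """Default three-group cohort (68/88/48) at the default seed."""
    config = CohortSimConfig(seed=0)
    matrix, annotations, truth = generate_cohort(config)
    return config, matrix, annotations, truth


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples with easily hand-checked values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 5.0, 5.0, 5.0],
            [2.5, 1.5, 4.25, 3.0],
        ]
    )
    return ExpressionMatrix(["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], values)
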