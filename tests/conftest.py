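import dataclasses

import numpy as np
import pandas as pd
import pytest

from crcith.io import ExpressionMatrix
from crcith.simulate import SimulationConfig, simulate_cohort
from crcith.signatures import derive_templates


@pytest.fixture(scope="session")
def default_cohort():
    """Default multiregional cohort (100 tumors, 2-4 samples each)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def training_cohort():
    """Homogeneous single-sample cohort used to derive subtype templates."""
    cfg = dataclasses.replace(
        SimulationConfig(seed=11), het_fraction=0.0,
        samples_per_tumor={1: 1.0}, n_tumors=200,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def templates(training_cohort):
    expr, sheet, _ = training_cohort
    return derive_templates(expr, sheet.set_index("sample_id")["subtype"])


@pytest.fixture
def tiny_expr():
    """3-gene x 4-sample deterministic matrix."""
    values = np.array(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [2.5, 2.5, 2.5, 2.5]]
    )
    return ExpressionMatrix(("g1", "g2", "g3"), ("s1", "s2", "s3", "s4"), values)


@pytest.fixture
def tiny_sheet():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "tumor_id": ["t1", "t1", "t2", "t2"],
            "patient_id": ["p1", "p1", "p2", "p2"],
        }
    )
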