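import numpy as np
import pandas as pd
import pytest

from meheg import (
    BetaMatrix,
    SampleAnnotation,
    SignatureMatrix,
    simulate_cohort,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_reference():
    """200-probe, 3-region unstructured reference with 60 planted DMPs."""
    sig, truth = simulate_reference(
        200, 60, separation=0.3, seed=11, mode="independent"
    )
    return sig, truth


@pytest.fixture(scope="session")
def progression_reference():
    """Progression-gradient reference used for cohort scoring tests."""
    sig, truth = simulate_reference(400, 60, separation=0.1, seed=7)
    return sig, truth


@pytest.fixture(scope="session")
def small_cohort(progression_reference):
    sig, truth_ref = progression_reference
    beta, annot, truth = simulate_cohort(sig, n_patients=10, seed=13)
    return beta, annot, truth, truth_ref


@pytest.fixture
def tiny_beta():
    """3 probes x 6 samples, two patients x three regions, hand-set values."""
    values = pd.DataFrame(
        {
            "P1_DTS": [0.10, 0.50, 0.30, 0.70],
            "P2_DTS": [0.20, 0.60, 0.31, 0.72],
            "P1_CB": [0.50, 0.52, 0.29, 0.55],
            "P2_CB": [0.60, 0.58, 0.33, 0.57],
            "P1_IF": [0.80, 0.48, 0.30, 0.40],
            "P2_IF": [0.90, 0.55, 0.32, 0.42],
        },
        index=["cgA", "cgB", "cgC", "cgD"],
    )
    return BetaMatrix(values)


@pytest.fixture
def tiny_annot():
    table = pd.DataFrame(
        {
            "sample": ["P1_DTS", "P2_DTS", "P1_CB", "P2_CB", "P1_IF", "P2_IF"],
            "patient": ["P1", "P2", "P1", "P2", "P1", "P2"],
            "region": ["DTS", "DTS", "CB", "CB", "IF", "IF"],
        }
    ).set_index("sample")
    return SampleAnnotation(table)
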