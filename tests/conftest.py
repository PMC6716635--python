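"""Shared fixtures: small hand-built matrices and the multi-seed recovery run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from samgepc.io_model import ClinicalTable, ExpressionMatrix, Platform


@pytest.fixture
def tiny_array_matrix() -> ExpressionMatrix:
    """3 genes × 4 samples (2 patients × baseline/m12), log2 intensities."""
    df = pd.DataFrame(
        {
            "P1_baseline": [5.0, 7.0, 6.0],
            "P1_m12": [6.0, 7.0, 5.5],
            "P2_baseline": [5.2, 7.1, 6.1],
            "P2_m12": [6.1, 7.0, 5.4],
        },
        index=pd.Index(["A", "B", "C"], name="gene_id"),
    )
    return ExpressionMatrix(Platform.MICROARRAY, df)


@pytest.fixture
def tiny_clinical() -> ClinicalTable:
    return ClinicalTable(
        pd.DataFrame(
            {
                "lvef_baseline": [25.0, 30.0, 20.0, 35.0],
                "lvef_m3": [31.0, 32.0, np.nan, 36.0],
                "lvef_m12": [45.0, 31.0, 26.0, np.nan],
                "rvef_baseline": [np.nan] * 4,
                "rvef_locf": [np.nan] * 4,
                "cohort_tags": [{"A-S"}] * 4,
            },
            index=pd.Index(["P1", "P2", "P3", "P4"], name="patient_id"),
        )
    )


@pytest.fixture(scope="session")
def recovery_replicates():
    """Per-seed recovery metrics at the generator's default study conditions.

    Shared across the acceptance tests that characterise sensitivity and the
    concordance ordering; 200 independent seeds.
    """
    from samgepc.experiments import run_replicates

    return run_replicates(200, seed0=1)
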