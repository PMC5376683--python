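"""Shared fixtures: one seed-0 synthetic reference run reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scfib import (
    GeneratorConfig,
    ExpressionMatrix,
    autoscale_by_cell,
    cq_to_rq,
    generate_patient_cohort,
    generate_reference,
    load_default_panel,
    qc_gapdh_gate,
    to_log2,
)

SEED = 0


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def reference():
    """(plate, truth) for the default cell-line experiment at the test seed."""
    return generate_reference(seed=SEED)


@pytest.fixture(scope="session")
def gated(reference):
    plate, _ = reference
    matrix, report = qc_gapdh_gate(cq_to_rq(plate))
    return matrix, report


@pytest.fixture(scope="session")
def log2_unimputed(gated):
    return to_log2(gated[0], impute=False)


@pytest.fixture(scope="session")
def log2_imputed(gated):
    return to_log2(gated[0], impute=True)


@pytest.fixture(scope="session")
def by_cell(log2_imputed):
    return autoscale_by_cell(log2_imputed)


@pytest.fixture(scope="session")
def patient():
    return generate_patient_cohort(seed=SEED + 1)


def make_matrix(values, genes=None, scale="log2_rq_imputed", detected=None, classes=None):
    """Build a small ExpressionMatrix from a 2-D array for unit tests."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    genes = genes or [f"G{j}" for j in range(g)]
    cell_ids = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    vdf = pd.DataFrame(values, index=cell_ids, columns=genes)
    ddf = pd.DataFrame(
        np.asarray(detected, dtype=bool) if detected is not None else True,
        index=cell_ids,
        columns=genes,
    )
    cells = pd.DataFrame(
        {
            "sample_id": "s",
            "cell_class": classes if classes is not None else "control",
        },
        index=cell_ids,
    )
    return ExpressionMatrix(values=vdf, detected=ddf, cells=cells, scale=scale)
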