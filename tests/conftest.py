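"""Shared fixtures: small simulated studies, generated at test time."""

import numpy as np
import pandas as pd
import pytest

from coxenpipe import (
    ExpressionPanel,
    SimulationConfig,
    generate_cell_line_panel,
    generate_patient_cohort,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study: fast enough for unit tests, still structured."""
    return SimulationConfig(
        n_cell_lines=40,
        n_patients=80,
        n_genes=300,
        n_signature_genes_per_drug=10,
        n_drugs=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    panel, profiles, tissue, truth = generate_cell_line_panel(small_config)
    reference = generate_patient_cohort(small_config, truth, cohort_id=0, tag="ref")
    return panel, profiles, tissue, truth, reference


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def gaussian_panel(rng) -> ExpressionPanel:
    """Independent-Gaussian panel: no coexpression structure at all."""
    n_genes, n_samples = 40, 50
    data = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{i:03d}" for i in range(n_samples)],
    )
    return ExpressionPanel(data, name="gauss")
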