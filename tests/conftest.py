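import numpy as np
import pandas as pd
import pytest

import polyen as pe
from polyen.model import SearchSpace


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort with a clear linear mean signal (10 donors)."""
    spec = pe.CohortSpec(
        n_donors=10,
        n_genes=12,
        cell_types={"TypeA": 30, "TypeB": 20},
        signal={"TypeA": [pe.GeneSignal(gene=0, b0=2.5, b1=0.02, c0=0.4)]},
        scenario="tiny",
        seed=11,
    )
    dataset, truth = pe.generate_cohort(spec)
    return dataset, truth


@pytest.fixture(scope="session")
def strong_cohort():
    dataset, truth = pe.generate_cohort(pe.preset_scenarios(1)["strong_mean"])
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    dataset, _ = tiny_cohort
    return pe.gene_space_features(dataset, "TypeA", min_cells=2)


@pytest.fixture
def fast_space():
    """A reduced search budget for tests where tuning quality is irrelevant."""
    return SearchSpace(budget=6, cv_folds=3)


@pytest.fixture
def manual_dataset():
    """A hand-built 4-cell, 2-gene, 2-donor dataset with known statistics."""
    values = np.array([[1.0, 2.0], [2.0, 0.0], [3.0, 1.0], [5.0, 4.0]])
    cells = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3", "c4"],
            "donor_id": ["d1", "d1", "d1", "d2"],
            "cell_type": ["T", "T", "T", "T"],
        }
    )
    donors = pd.DataFrame({"donor_id": ["d1", "d2"], "age": [30.0, 60.0]})
    return pe.CellExpressionDataset(
        values=values,
        cell_annotations=cells,
        donor_annotations=donors,
        gene_ids=["gA", "gB"],
        normalized=True,
    )
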