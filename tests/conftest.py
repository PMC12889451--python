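from __future__ import annotations

import numpy as np
import pytest

from drugsig import InteractionMatrix, all_rankings, make_fixture


@pytest.fixture(scope="session")
def fixture_study():
    return make_fixture()


@pytest.fixture(scope="session")
def fixture_rankings(fixture_study):
    return all_rankings(fixture_study.matrix)


def random_grid_matrix(rng: np.random.Generator, n_compounds: int, n_proteins: int) -> InteractionMatrix:
    """A random interaction matrix with scores on a coarse grid, so that
    distance and score ties actually occur."""
    grid = np.arange(0.0, 1.2, 0.2).round(1)
    scores = rng.choice(grid, size=(n_compounds, n_proteins))
    return InteractionMatrix(
        compound_ids=[f"D{i:02d}" for i in range(n_compounds)],
        protein_ids=[f"P{j:02d}" for j in range(n_proteins)],
        scores=scores,
    )
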