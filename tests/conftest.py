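import numpy as np
import pandas as pd
import pytest

from braindeconv import (
    ProportionMatrix,
    generate_population,
    standard_scenario,
)


@pytest.fixture(scope="session")
def scenario():
    """The standard five-type, 70-sample seeded benchmark scenario."""
    return standard_scenario(seed=1)


@pytest.fixture(scope="session")
def small_population():
    """A small planted population for fast unit tests."""
    return generate_population(
        n_genes=300,
        cell_types=["A", "B", "C"],
        markers_per_type=20,
        fold_change=8.0,
        seed=7,
        n_cells=300,
    )


@pytest.fixture()
def simplex_frame():
    """A 4-type x 6-sample exact-simplex proportion table."""
    rng = np.random.default_rng(3)
    values = rng.dirichlet(np.ones(4), size=6).T
    return ProportionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(["w", "x", "y", "z"], name="cell_type"),
            columns=[f"s{i}" for i in range(6)],
        ),
        kind="true",
    )
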