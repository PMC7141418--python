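import numpy as np
import pandas as pd
import pytest

from gsweave import (
    GenotypeMatrix,
    MarkerMap,
    PhenotypeVector,
    SimConfig,
    simulate_population,
)


@pytest.fixture
def toy_geno():
    """6 lines x 5 markers with hand-set dosages and two missing calls."""
    dosage = np.array([
        [0, 2, 1, 0, 2],
        [1, 2, 0, 0, 2],
        [2, 2, 1, 0, 0],
        [0, 2, np.nan, 1, 0],
        [1, 2, 2, 0, np.nan],
        [2, 2, 0, 0, 2],
    ], dtype=float)
    return GenotypeMatrix(
        [f"L{i}" for i in range(1, 7)],
        [f"M{j}" for j in range(1, 6)],
        dosage,
    )


@pytest.fixture
def toy_map():
    return MarkerMap(pd.DataFrame({
        "marker_id": [f"M{j}" for j in range(1, 6)],
        "chromosome": ["1A", "1A", "1A", "2B", "2B"],
        "position": [10.0, 20.0, 30.0, 5.0, 15.0],
    }))


@pytest.fixture
def toy_pheno():
    rng = np.random.default_rng(11)
    return PhenotypeVector(pd.Series(
        rng.normal(size=6), index=[f"L{i}" for i in range(1, 7)]
    ))


@pytest.fixture(scope="session")
def small_population():
    """Session-scoped simulated population for model-level tests."""
    cfg = SimConfig(n_lines=120, n_markers=300, n_chromosomes=5,
                    n_qtl=40, h2_target=0.6, seed=42)
    return simulate_population(cfg)
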