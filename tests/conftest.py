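import numpy as np
import pandas as pd
import pytest

from phenonoise import CarrierLabels, GenotypeMatrix, SimulationConfig, simulate_population


def make_matrix(values, positions=None, chromosome="19"):
    """GenotypeMatrix from a plain array, synthesising the locus map."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    locus_table = pd.DataFrame({
        "id": [f"snp{j + 1:03d}" for j in range(m)],
        "chromosome": [chromosome] * m,
        "position": np.asarray(positions, dtype=np.int64),
    })
    ids = np.array([f"ind{i + 1:03d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(values, locus_table, ids)


@pytest.fixture(scope="session")
def small_panel():
    """120 x 40 simulated panel with a fixed copy probability (no calibration)."""
    cfg = SimulationConfig(n_individuals=120, n_snps=40, seed=17,
                           copy_prob=0.98)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def labels200():
    rng = np.random.default_rng(0)
    y = np.zeros(200, dtype=np.int8)
    y[rng.choice(200, 8, replace=False)] = 1
    return CarrierLabels(y)
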