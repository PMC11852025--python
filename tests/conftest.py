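import numpy as np
import pytest

from spermsurf import ingest
from spermsurf.simulate import SimulationConfig, simulate_dataset, write_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared read-only."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def dataset_paths(default_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("synthdata")
    return write_dataset(default_dataset, out)


@pytest.fixture()
def small_matrix():
    """Hand-built 4-protein × (BU,BX,BY ×3) matrix with known masks."""
    values = np.array([
        [10.0, 11.0, 12.0, 20.0, 21.0, 22.0, 15.0, 15.5, 16.0],
        [np.nan, 11.0, 12.0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan],
        [10.0, np.nan, np.nan, 10.5, np.nan, np.nan, 11.0, np.nan, np.nan],
        [np.nan] * 9,
    ])
    observed = np.isfinite(values)
    samples = [f"{c}_{r}" for c in ("BU", "BX", "BY") for r in (1, 2, 3)]
    return ingest.IntensityMatrix(
        protein_ids=["P1", "P2", "P3", "P4"],
        sample_ids=samples,
        condition_of={s: s.split("_")[0] for s in samples},
        values=values,
        observed_mask=observed,
        imputed_mask=np.zeros_like(observed),
    )
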