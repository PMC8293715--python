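import numpy as np
import pandas as pd
import pytest

from elevrange import OccurrenceData


def make_occurrences(elevations, matrix, species=None) -> OccurrenceData:
    """Build a validated OccurrenceData from raw arrays."""
    matrix = np.asarray(matrix, dtype=int)
    n_plots, n_species = matrix.shape
    plot_ids = [f"p{i + 1}" for i in range(n_plots)]
    if species is None:
        species = [f"s{j + 1}" for j in range(n_species)]
    plots = pd.DataFrame({"plot_id": plot_ids, "elevation_m": np.asarray(elevations, float)})
    mat = pd.DataFrame(matrix, index=pd.Index(plot_ids, name="plot_id"), columns=species)
    return OccurrenceData(plots=plots, matrix=mat)


def random_occurrences(rng: np.random.Generator, n_plots: int, n_species: int,
                       p_occupied: float = 0.4) -> OccurrenceData:
    """Random presence/absence fixture; every species occurs at least once."""
    elevs = np.sort(rng.uniform(1000.0, 6000.0, size=n_plots))
    mat = (rng.random((n_plots, n_species)) < p_occupied).astype(int)
    for j in range(n_species):
        if mat[:, j].sum() == 0:
            mat[rng.integers(n_plots), j] = 1
    return make_occurrences(elevs, mat)


@pytest.fixture
def rng():
    return np.random.default_rng(20214)
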