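import numpy as np
import pytest

from ascbias import (GeneticMap, GenotypeMatrix, PopulationModel,
                     simulate_dataset)


def make_genotypes(dosages, populations, gmap=None):
    """GenotypeMatrix from a plain (sites x individuals) array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    populations = np.asarray(populations, dtype=object)
    samples = np.array([f"{p}_{i}" for i, p in enumerate(populations)],
                       dtype=object)
    if gmap is None:
        gmap = GeneticMap.uniform(dosages.shape[0], span_cm=10.0)
    return GenotypeMatrix(dosages, samples, populations, gmap)


@pytest.fixture(scope="session")
def small_dataset():
    """4 populations x 12 individuals x 600 sites with moderate drift."""
    model = PopulationModel(n_populations=4, drift_F=[0.05, 0.1, 0.2, 0.3],
                            n_sites=600, seed=7)
    return simulate_dataset(model, 12, span_cm=50.0)
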