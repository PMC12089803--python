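import numpy as np
import pandas as pd
import pytest

from intgen.config import SimulationConfig
from intgen.simulate import generate_dataset


def small_config(seed: int = 7, **kwargs) -> SimulationConfig:
    defaults = dict(
        n_individuals=1_500,
        n_variants=250,
        n_reference=500,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared small synthetic biobank for read-only tests."""
    return generate_dataset(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def make_gm(dosages, maf=None, info=1.0, samples=None):
    """Build a GenotypeMatrix around a raw dosage array for unit tests."""
    from intgen.genotypes import GenotypeMatrix

    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "info_score": np.full(m, info, dtype=float),
        }
    )
    if samples is None:
        samples = np.array([f"S{i}" for i in range(n)])
    return GenotypeMatrix(dosages=dosages, samples=np.asarray(samples), variants=variants)
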