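import numpy as np
import pandas as pd
import pytest

from copdsubtype import simulate as sim


@pytest.fixture(scope="session")
def high_sep_config():
    """Strongly separated planted subtypes: 5 SD shifts, all candidates informative."""
    return sim.SynthConfig(
        n_genes=300,
        n_candidate_genes=60,
        n_samples=60,
        k_subtypes=3,
        subtype_proportions=(1 / 3, 1 / 3, 1 / 3),
        effect_size=5.0,
        frac_informative=1.0,
        n_pathways=20,
        pathway_size_range=(5, 25),
        clinical_shift=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def high_sep_cohort(high_sep_config):
    return sim.generate_cohort(high_sep_config)


@pytest.fixture(scope="session")
def null_config():
    """No subtype signal anywhere: effect_size = 0, clinical_shift = 0."""
    return sim.SynthConfig(
        n_genes=500,
        n_candidate_genes=400,
        n_samples=90,
        k_subtypes=3,
        subtype_proportions=(1 / 3, 1 / 3, 1 / 3),
        effect_size=0.0,
        frac_informative=0.5,
        clinical_shift=0.0,
        n_pathways=30,
        pathway_size_range=(5, 40),
        seed=7,
    )


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return sim.generate_cohort(null_config)


@pytest.fixture
def small_expression():
    rng = np.random.default_rng(3)
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{i}" for i in range(6)]
    return pd.DataFrame(rng.normal(size=(10, 6)), index=genes, columns=samples)
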