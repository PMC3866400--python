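import numpy as np
import pandas as pd
import pytest

from gfsbrain import encephalization as ence
from gfsbrain import synthetic as syn
from gfsbrain.datatypes import GeneFamilyMatrix


@pytest.fixture(scope="session")
def small_tree():
    return syn.simulate_tree(12, birth_rate=1.0, seed=42)


@pytest.fixture(scope="session")
def clade40():
    """A 40-species clade with traits, true Ei, and computed Ei."""
    tree = syn.simulate_tree(40, seed=7)
    traits, true_ei = syn.simulate_traits(tree, mlsp_ei_corr=0.79, seed=3)
    ence.compute_ei(traits)
    return tree, traits, true_ei


def make_matrix(counts, species=None, family_ids=None) -> GeneFamilyMatrix:
    counts = np.asarray(counts)
    n_fam, n_sp = counts.shape
    return GeneFamilyMatrix(
        family_ids=family_ids or [f"fam{i:03d}" for i in range(n_fam)],
        species_ids=species or [f"s{i:03d}" for i in range(n_sp)],
        counts=counts,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_traits():
    data = pd.DataFrame(
        {
            "brain_mass_g": [10.0, 56.2, 320.0, 1800.0, 9.0],
            "body_mass_g": [1e3, 1e4, 1e5, 1e6, 8e2],
            "mlsp_yr": [12.0, 20.0, 35.0, 60.0, 10.0],
        },
        index=pd.Index([f"s{i}" for i in range(5)], name="species"),
    )
    from gfsbrain.datatypes import SpeciesTraitTable

    return SpeciesTraitTable(data=data)
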