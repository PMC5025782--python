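import numpy as np
import pandas as pd
import pytest

from wingpwas import peptides, proteins
from wingpwas.simulate import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle shared across test modules."""
    return generate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def quantified(bundle):
    """Normalized, filtered and rolled-up levels for the shared bundle."""
    log2 = peptides.log2_median_center(bundle.intensities)
    filtered, _ = peptides.filter_missingness(log2)
    mapping = {p: (bundle.truth.peptide_protein[p],) for p in filtered.index}
    entries = proteins.classify_entries(mapping)
    levels, stats = proteins.quantify(filtered, bundle.design, entries)
    return levels, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def trait_index(phenotypes: pd.DataFrame) -> pd.Index:
    return pd.Index(phenotypes["line"].astype(str) + "_" + phenotypes["sex"].astype(str))
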