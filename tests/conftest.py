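import numpy as np
import pandas as pd
import pytest

import genomedrift as gd


@pytest.fixture
def uniform_phi():
    return np.full((3, 4), 0.25)


@pytest.fixture
def basic_model(uniform_phi):
    return gd.CodonModel(kappa=2.0, omega=0.5, phi=uniform_phi)


@pytest.fixture
def three_taxon_tree():
    return gd.read_newick("(A:0.2,(B:0.3,C:0.1):0.15);")


@pytest.fixture
def tiny_alignment():
    return gd.CodonAlignment("g1", {"A": "ATGAAA", "B": "ATGAAG",
                                    "C": "ATAAAA"})


@pytest.fixture
def trait_table():
    df = pd.DataFrame({
        "assembly_size": [1.0e9, 5.0e8, 2.0e9],
        "cvalue": [1.1, np.nan, 2.3],
        "contig_n50": [60_000.0, 49_999.0, 80_000.0],
        "busco_complete": [95.0, 90.0, 70.0],
        "busco_duplicated": [5.0, 35.0, 30.0],
    }, index=pd.Index(["sp1", "sp2", "sp3"], name="species"))
    return gd.SpeciesTraitTable(df)
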