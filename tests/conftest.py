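import dendropy
import numpy as np
import pandas as pd
import pytest

from phniche.diversification import LabeledPhylogeny, make_spec
from phniche.synthetic_data import GradientScenario, gen_soil_gradient, gen_yule_tree


@pytest.fixture(scope="session")
def three_tip_phylo():
    tree = dendropy.Tree.get(data="((A:1.0,B:1.0):0.5,C:1.5):0.0;", schema="newick")
    return LabeledPhylogeny(tree, {"A": "ES", "B": "EG", "C": "CG"})


@pytest.fixture(scope="session")
def four_tip_phylo():
    tree = dendropy.Tree.get(
        data="((A:1.0,B:1.0):0.5,(C:0.7,D:0.7):0.8):0.0;", schema="newick"
    )
    return LabeledPhylogeny(tree, {"A": "ES", "B": "EG", "C": "CG", "D": "CS"})


@pytest.fixture(scope="session")
def cr_m5_spec():
    return make_spec("CR", 5)


@pytest.fixture(scope="session")
def small_gradient():
    """Reduced-size gradient survey shared across tests."""
    scenario = GradientScenario(n_soils=30, n_phylotypes=120, seed=11)
    matrix, meta, truth = gen_soil_gradient(scenario)
    return matrix, meta, truth


@pytest.fixture(scope="session")
def yule50():
    return gen_yule_tree(1.0, 50, seed=3)
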