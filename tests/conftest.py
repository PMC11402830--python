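import numpy as np
import pytest

import padi6tools as pt


@pytest.fixture(scope="session")
def landscape():
    cfg = pt.GeneratorConfig(seed=7, n_residues=200)
    return cfg, pt.simulate_ddg_landscape(cfg)


@pytest.fixture(scope="session")
def rank_tables(landscape):
    _, land = landscape
    return pt.build_rank_table(land.dimer), pt.build_rank_table(land.monomer)


@pytest.fixture(scope="session")
def toy_dimer():
    from padi6tools.simulate import simulate_toy_dimer

    return simulate_toy_dimer()


@pytest.fixture(scope="session")
def helix():
    from padi6tools.simulate import simulate_helix_chain

    return simulate_helix_chain()
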