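import numpy as np
import pytest
from hypothesis import settings

import dimerslide as ds
from dimerslide import synth

settings.register_profile("default", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def wt_0n100():
    """0N100 substrate slid by the wild-type dimer (short run, 300 molecules)."""
    return ds.simulate("0N100", "WT", n_molecules=300, t_end=200.0, seed=2)


@pytest.fixture(scope="session")
def wt_0n140():
    """0N140 substrate, long run so essentially all molecules have settled."""
    return ds.simulate("0N140", "WT", n_molecules=500, t_end=3600.0, seed=3)


@pytest.fixture(scope="session")
def ctd_titration():
    """Synthetic CTD-DNA binding titration at the published assay design."""
    cfg = synth.GeneratorConfig(noise=0.02, replicates=20, seed=21)
    return synth.gen_binding_titration(cfg, "CTD_DNA")
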