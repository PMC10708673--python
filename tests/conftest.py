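import numpy as np
import pytest

from pearlnecklace import MarkovParams, NecklacePlan, generate_ensemble, make_necklace


@pytest.fixture(scope="session")
def uncorrelated_pe_ensemble():
    """2000 uncorrelated PE sequences at the canonical N=202, p=3."""
    return generate_ensemble(2000, 202, 3, "pe", MarkovParams(0.5), seed=101)


@pytest.fixture(scope="session")
def blocky_pe_ensemble():
    """2000 blocky (mean block length 4) PE sequences at N=202, p=3."""
    return generate_ensemble(2000, 202, 3, "pe", MarkovParams(0.75), seed=202)


@pytest.fixture(scope="session")
def two_pearl_necklace():
    """Planted 80/40 necklace with 30+26+26 string/tail monomers (N=202)."""
    plan = NecklacePlan(pearls=((80, 12), (40, 6)), strings=(30, 26, 26), seed=7)
    conf, truth = make_necklace(plan)
    return conf, truth
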