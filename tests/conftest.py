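import numpy as np
import pytest

from phenobench import simdata


@pytest.fixture(scope="session")
def small_map():
    return simdata.GenomeMap.regular(n_chromosomes=3, length=1.0, markers_per_chromosome=30)


@pytest.fixture(scope="session")
def cross(small_map):
    """400 segregants of a biparental cross, 90 markers on 3 chromosomes."""
    return simdata.simulate_cross(small_map, 400, seed=11)


@pytest.fixture(scope="session")
def additive_trait(cross):
    arch = simdata.TraitArchitecture(
        "additive", additive={5: 1.0, 40: 0.8, 70: 0.6}, h2=0.7
    )
    return simdata.simulate_trait(cross, arch, seed=12), arch
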