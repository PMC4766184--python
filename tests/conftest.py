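import numpy as np
import pytest

from fluctme import PhenotypeFitness


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def pf_experiment():
    """The illustrative phenotype fitness pair measured after evolution:
    anoxia-adapted phenotype fitness 2.63 in anoxia, 0.335 in normoxia."""
    return PhenotypeFitness.from_fitness_values(2.63, 0.335)
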