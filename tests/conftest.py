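import numpy as np
import pytest

from recurneo import synthetic
from recurneo.predictors import ToyBindingPredictor
from recurneo.variant_filtering import ProteinChange


@pytest.fixture(scope="session")
def scenario():
    """The packaged two-study example scenario (config, fasta, proteome)."""
    return synthetic.example_scenario(seed=11)


@pytest.fixture(scope="session")
def simulated_cohort(scenario):
    config, _, proteome = scenario
    return synthetic.simulate_cohort(config, proteome)


@pytest.fixture(scope="session")
def toy_predictor():
    return ToyBindingPredictor(seed=3, n_reference=5000)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_change(gene="KRAS", pos=12, ref="G", alt="D"):
    return ProteinChange(gene, pos, ref, alt)
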