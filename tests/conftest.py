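import numpy as np
import pytest

from srleseq import FractionSample, simulate_6mer_truth
from srleseq.simulate import simulate_fraction_counts


@pytest.fixture(scope="session")
def planted_truth():
    """The screen's planting scheme: 110 nuclear + 49 cytoplasmic 6-mers at effect 1."""
    return simulate_6mer_truth(110, 49, 1.0, seed=7)


@pytest.fixture(scope="session")
def triplicate_samples():
    return [
        FractionSample(fraction, rep, depth=2_000_000)
        for fraction in ("nuclear", "cytoplasmic")
        for rep in (1, 2, 3)
    ]


@pytest.fixture(scope="session")
def planted_counts(planted_truth, triplicate_samples):
    return simulate_fraction_counts(planted_truth, triplicate_samples, dispersion=0.02, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
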