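import numpy as np
import pytest

from cobel.pipeline import screen
from cobel.synthetic_data import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def signal_manifest():
    """One signal fixture shared across the suite (planted erosions)."""
    return generate_fixture(FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def signal_result(signal_manifest):
    m = signal_manifest
    return screen(
        m.pwms,
        m.genome,
        m.alignment,
        m.tree,
        m.variants,
        m.outgroup,
        m.genes,
        m.chrom_lengths,
        m.ontology,
        seed=m.config.seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pwm(rng, length, pseudocount=1e-3):
    from cobel.motif_model import Pwm

    freqs = rng.dirichlet(np.ones(4), size=length)
    return Pwm(id="RND", tf_name="RND", freqs=freqs, pseudocount=pseudocount)
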