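import numpy as np
import pytest

from codonpref.simulate import SimConfig, assemble_genome, simulate_genes
from codonpref.spectrum import MUT_CLASSES, MutationSpectrum


@pytest.fixture(scope="session")
def small_sim():
    """A small assembled synthetic genome shared across IO-level tests."""
    cfg = SimConfig(n_genes=120, n_chromosomes=2)
    rng = np.random.default_rng(42)
    sim = simulate_genes(cfg, rng)
    assemble_genome(sim, rng)
    return sim


@pytest.fixture
def uniform_spectrum():
    return MutationSpectrum(rates={c: 1 / 12 for c in MUT_CLASSES})


@pytest.fixture
def default_spectrum():
    cfg = SimConfig()
    return cfg.spectrum()


def random_spectrum(rng) -> MutationSpectrum:
    raw = {c: float(rng.gamma(2.0)) for c in MUT_CLASSES}
    return MutationSpectrum.from_rates(raw)
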