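import numpy as np
import pytest

from cytocycle.pipeline import prepare_profiles
from cytocycle.synth import PopulationConfig, generate_population


@pytest.fixture(scope="session")
def small_population():
    """200 cells with stain, default priors — shared across unit tests."""
    cfg = PopulationConfig(n_cells=200, seed=42)
    records, truth = generate_population(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_profiles(small_population):
    """Feature table + stain + QC of the 200-cell population."""
    _, records, truth = small_population
    features, stain, qc = prepare_profiles(records, seed=42)
    return features, stain, qc, truth


@pytest.fixture(scope="session")
def acceptance_population():
    """The default synthetic population used by the acceptance suite.

    3000 cells at the default study conditions (phase priors with ~5%
    mitotic mass, 5% stain CV, size-DNA coupling); generated once per
    session because profiling it is the expensive step.
    """
    cfg = PopulationConfig(n_cells=3000, seed=11)
    records, truth = generate_population(cfg)
    features, stain, qc = prepare_profiles(records, seed=11)
    return cfg, truth, features, stain, qc


def dna_mixture(n, f_g1, f_s, f_g2m, mu=100.0, cv=0.05, seed=0):
    """Stain-intensity mixture consistent with the generator's stain model.

    DNA content c is 2 for G1, uniform(2, 4) for S and 4 for G2/M; the
    measured intensity is c/2 * mu * (1 + eps) with eps ~ N(0, cv).
    """
    rng = np.random.default_rng(seed)
    ns = rng.multinomial(n, [f_g1, f_s, f_g2m])
    c = np.concatenate(
        [np.full(ns[0], 1.0), rng.uniform(1.0, 2.0, ns[1]), np.full(ns[2], 2.0)]
    )
    return c * mu * (1.0 + rng.normal(0.0, cv, len(c)))
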