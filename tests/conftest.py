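import numpy as np
import pytest

import crmclass as cc


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (one 5 Mb chromosome, six archetypes)."""
    return cc.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def analysis(dataset):
    """Full pipeline run on the default dataset with the data-driven preset."""
    return cc.run_analysis(dataset.ip, dataset.input_track, dataset.tracks,
                           dataset.histone_names, dataset.genes,
                           dataset.expression, dataset.domains, dataset.truth,
                           cc.synthetic_preset())


@pytest.fixture
def small_genome():
    return cc.GenomeModel(("chrA", "chrB"), {"chrA": 1000, "chrB": 600}, 50)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_track(genome, arrays, semantics="log2_enrichment"):
    return cc.SignalTrack(genome, {c: np.asarray(a, dtype=float)
                                   for c, a in arrays.items()}, semantics)
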