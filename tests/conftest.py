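"""Shared fixtures: calibrated synthetic hosts, donors and the default corpus."""

from __future__ import annotations

import numpy as np
import pytest

from islet import oup
from islet import simulate as sim


@pytest.fixture(scope="session")
def host_and_donors():
    """One host model plus three well-separated donor models."""
    rng = np.random.default_rng(11)
    host = sim.random_host_model("host", rng)
    donors = sim.donor_models(3, host, rng)
    return host, donors


@pytest.fixture(scope="session")
def host_genome(host_and_donors):
    host, _ = host_and_donors
    return sim.sample_genome(host, 200_000, seed=77)


@pytest.fixture(scope="session")
def default_corpus():
    """The default 30-genome / 10-donor / 300-island corpus."""
    return sim.make_corpus(seed=1)


@pytest.fixture(scope="session")
def corpus_patterns(default_corpus):
    """(patterns by island id, donor id by island id, host id by island id)."""
    islands = default_corpus.island_sequences()
    patterns = {i: oup.sequence_pattern(s) for i, (_g, _d, s) in islands.items()}
    donor_of = {i: d for i, (_g, d, _s) in islands.items()}
    host_of = {i: g for i, (g, _d, _s) in islands.items()}
    return patterns, donor_of, host_of


@pytest.fixture(scope="session")
def corpus_clustering(corpus_patterns):
    """Similarity graph + MCL clusters (with subclusters and representatives)."""
    from islet import network

    patterns, _donor_of, _host_of = corpus_patterns
    g = network.build_graph(patterns)
    clusters = network.mcl(g)
    network.subcluster(clusters, g)
    network.assign_representatives(clusters, g)
    return g, clusters
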