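import logging

import pytest
from hypothesis import HealthCheck, settings

from netprior import network_builder as nb
from netprior import prioritizer, synthetic_fixtures as sf, topology

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

logging.getLogger("netprior").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec() -> sf.FixtureSpec:
    """A fast, fully contaminated fixture spec for module-level tests."""
    return sf.FixtureSpec(
        n_genes=300,
        universe_extra=600,
        n_seed_genes=15,
        planted_module_size=20,
        module_hub_edges=15,
        n_candidates=120,
        n_candidates_mapped=80,
        candidate_planted_fraction=0.15,
        n_pathways=8,
        pathway_size_range=(5, 20),
        planted_pathway_size=12,
        coexpression_block_size=10,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_fixtures(small_spec) -> sf.Fixtures:
    return sf.generate_fixtures(small_spec)


@pytest.fixture(scope="session")
def study_fixtures() -> sf.Fixtures:
    """Default-size fixtures mirroring the study's data shapes."""
    return sf.generate_fixtures(sf.FixtureSpec(rng_seed=1))


@pytest.fixture(scope="session")
def study_pipeline(study_fixtures):
    """The default fixtures run through ingest → build → rank → map."""
    fx = study_fixtures
    human = nb.filter_taxon(fx.edge_records, 9606)
    pairs, _ = nb.collapse_to_symbols(human, fx.alias_map)
    net = nb.build_seed_network(pairs, fx.seed_records)
    table = topology.relative_betweenness(topology.betweenness(net))
    prioritized, unmapped = prioritizer.map_candidates(net, table, fx.candidate_records)
    return {
        "fixtures": fx,
        "net": net,
        "table": table,
        "prioritized": prioritized,
        "unmapped": unmapped,
    }
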