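import numpy as np
import pytest

from phenoconverge.ontology import OntologyDAG
from phenoconverge.synthdata import PlantedPathway, SimulationConfig, simulate


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down simulation for fast unit tests."""
    defaults = dict(
        n_terms=120,
        n_genes=400,
        n_chromosomes=5,
        n_patients=60,
        n_replication=40,
        n_go_terms=30,
        n_kegg_terms=15,
        n_mpo_terms=25,
        n_bg_modules=25,
        n_expr_samples=40,
        pathways=(PlantedPathway(n_genes=6, n_carriers=15, n_replication_carriers=8),),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate(small_config(), seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """Full study-scale bundle used for end-to-end checks."""
    return simulate(seed=7)


@pytest.fixture(scope="session")
def pipeline_result(default_bundle):
    from phenoconverge.pipeline import inputs_from_bundle, run_pipeline

    return run_pipeline(inputs_from_bundle(default_bundle))


def random_dag(n_terms: int, rng: np.random.Generator, frac_two_parents=0.2) -> OntologyDAG:
    """Random rooted DAG with edges pointing at lower indices (acyclic)."""
    ids = [f"T{i:03d}" for i in range(n_terms)]
    edges = set()
    for i in range(1, n_terms):
        edges.add((ids[i], ids[int(rng.integers(i))]))
        if rng.random() < frac_two_parents and i > 1:
            edges.add((ids[i], ids[int(rng.integers(i))]))
    edges = {(c, p) for c, p in edges if c != p}
    return OntologyDAG(term_ids=set(ids), labels={t: t for t in ids}, is_a_edges=edges)
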