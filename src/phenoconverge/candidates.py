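"""Multi-method candidate genes and their PPI validation.

A gene becomes a candidate for a patient-phenotype group when it is
identified independently by at least two of the four engines — GO-like
annotation, KEGG-like pathways, model-organism knockout phenotypes, and
co-expression clustering.  "Identified by" an annotation engine means
contributing to at least one significant enrichment from that engine;
for the co-expression engine it means contributing (having an induced
edge) in a significant cluster test.  Candidate sets are then validated
by asking whether they cluster in the protein-protein interaction
network more than degree-matched random sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment import EnrichmentResult
from .networks import ClusterTestResult, GeneNetwork, cluster_test

__all__ = ["CandidateSet", "multi_method_candidates", "validate_candidates_ppi"]

ANNOTATION_ENGINES = ("GO", "KEGG", "MGI")
NETWORK_ENGINE = "coexpression"


@dataclass
class CandidateSet:
    group_term: str
    genes: frozenset[str]
    provenance: dict[str, frozenset[str]]  # gene -> engines that identified it
    ppi_result: ClusterTestResult | None = None

    @property
    def ppi_significant(self) -> bool:
        return (
            self.ppi_result is not None
            and not self.ppi_result.untestable
            and self.ppi_result.p < 0.05
        )


def multi_method_candidates(
    group_term: str,
    enrichments: Sequence[EnrichmentResult],
    cluster_results: Mapping[str, ClusterTestResult],
    min_methods: int = 2,
) -> CandidateSet:
    """Genes identified by >= min_methods distinct engines for one group.

    ``enrichments`` are this group's results across annotation engines
    (their ``resource`` field names the engine); ``cluster_results`` maps
    network-engine names (e.g. "coexpression") to this group's cluster
    test.  Multiple significant terms within one engine still count as
    one method.
    """
    engines_by_gene: dict[str, set[str]] = {}
    for e in enrichments:
        if e.significant:
            for g in e.contributing_genes:
                engines_by_gene.setdefault(g, set()).add(e.resource)
    for engine, res in cluster_results.items():
        if res is not None and not res.untestable and res.p < 0.05:
            for g in res.contributing_genes:
                engines_by_gene.setdefault(g, set()).add(engine)
    genes = frozenset(
        g for g, engines in engines_by_gene.items() if len(engines) >= min_methods
    )
    return CandidateSet(
        group_term=group_term,
        genes=genes,
        provenance={g: frozenset(engines_by_gene[g]) for g in genes},
    )


def validate_candidates_ppi(
    candidates: CandidateSet,
    ppi: GeneNetwork,
    n_samples: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> CandidateSet:
    """Attach an edge-count degree-matched cluster test on the PPI network."""
    candidates.ppi_result = cluster_test(
        ppi, candidates.genes, statistic="edge-count", n_samples=n_samples, rng=rng
    )
    return candidates
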