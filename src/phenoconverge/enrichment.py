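"""Gene-set enrichment engines: hypergeometric tests with BH-FDR.

Each patient-phenotype group's pooled CNV gene set is tested against the
term→gene maps of an annotation resource (GO-like, KEGG-like pathway
collections, or model-organism knockout phenotypes).  Significance is the
upper tail of the hypergeometric distribution against the resource's gene
universe, corrected with Benjamini–Hochberg within one (group × resource)
family at FDR < 0.05.

The model-organism engine additionally maps test genes through a strict
1:1 ortholog table, restricts the tested terms to the overarching
category configured for the group's phenotype, and drops terms that
annotate less than a minimum fraction (default 1%) of the category's
gene pool before correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import PatientPhenotypeGroup
from .ontology import CategoryMap, hpo_to_mpo_category

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCollection",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_fdr",
    "enrich_group",
    "enrich_group_mgi",
    "read_gmt",
    "read_two_column_map",
]


@dataclass
class AnnotationCollection:
    """A named term→gene-set resource over a gene universe.

    For model-organism resources, ``orthologs`` maps human gene → model
    gene and must be one-to-one on its domain, and ``term_categories``
    assigns each annotation term to an overarching category.
    """

    name: str
    term_genes: dict[str, frozenset[str]]
    universe: frozenset[str]
    term_categories: dict[str, str] | None = None
    orthologs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        stray = set().union(*self.term_genes.values(), set()) - set(self.universe)
        if stray:
            raise ValueError(
                f"{self.name}: {len(stray)} annotated genes outside universe"
            )
        if self.orthologs is not None:
            vals = list(self.orthologs.values())
            if len(set(vals)) != len(vals):
                raise ValueError(f"{self.name}: ortholog map is not 1:1")

    def category_pool(self, category: str) -> frozenset[str]:
        """Union of gene sets of all terms in an overarching category."""
        if self.term_categories is None:
            raise ValueError("resource has no term categories")
        pool: set[str] = set()
        for term, cat in self.term_categories.items():
            if cat == category and term in self.term_genes:
                pool |= self.term_genes[term]
        return frozenset(pool)


@dataclass
class EnrichmentResult:
    group_term: str
    resource: str
    annotation_term: str
    k: int  # test ∩ annotated
    n: int  # test genes in universe
    K: int  # annotated genes in universe
    N: int  # universe size
    fold: float
    p: float
    q: float = float("nan")
    significant: bool = False
    contributing_genes: frozenset[str] = frozenset()


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N and n >= 0 and K >= 0):
        raise ValueError(f"invalid hypergeometric counts k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _test_terms(
    test: frozenset[str],
    universe: frozenset[str],
    term_genes: Mapping[str, frozenset[str]],
    group_term: str,
    resource: str,
    alpha: float,
) -> list[EnrichmentResult]:
    n = len(test)
    N = len(universe)
    results: list[EnrichmentResult] = []
    for term in sorted(term_genes):
        annotated = term_genes[term] & universe
        K = len(annotated)
        if K == 0:
            continue
        overlap = test & annotated
        k = len(overlap)
        p = hypergeom_upper_tail(k, n, K, N)
        fold = (k / n) / (K / N) if k > 0 else 0.0
        results.append(
            EnrichmentResult(
                group_term=group_term,
                resource=resource,
                annotation_term=term,
                k=k,
                n=n,
                K=K,
                N=N,
                fold=fold,
                p=p,
                contributing_genes=frozenset(overlap),
            )
        )
    if results:
        q = bh_fdr([r.p for r in results])
        for r, qv in zip(results, q):
            r.q = float(qv)
            r.significant = bool(qv < alpha)
    return results


def enrich_group(
    group: PatientPhenotypeGroup,
    annot: AnnotationCollection,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a group's pooled genes in one resource.

    One result per annotation term with at least one universe gene; FDR is
    computed within this (group × resource) family.
    """
    test = frozenset(group.gene_set) & annot.universe
    if not test:
        logger.warning(
            "group %s: no test genes in %s universe", group.term, annot.name
        )
        return []
    return _test_terms(test, annot.universe, annot.term_genes, group.term, annot.name, alpha)


def enrich_group_mgi(
    group: PatientPhenotypeGroup,
    annot: AnnotationCollection,
    hpo_category: str | None,
    alpha: float = 0.05,
    min_frac: float = 0.01,
) -> list[EnrichmentResult]:
    """Model-organism knockout-phenotype enrichment for one group.

    Test genes are mapped through the strict 1:1 ortholog table; only
    annotation terms within the group phenotype's overarching category
    are tested, and terms annotating fewer than ``min_frac`` of the
    category's gene pool are excluded before FDR.  The background is the
    resource universe (model genes reachable through a 1:1 ortholog).
    """
    if hpo_category is None:
        logger.info("group %s skipped: no overarching-category mapping", group.term)
        return []
    if annot.orthologs is None or annot.term_categories is None:
        raise ValueError("MGI-style engine needs orthologs and term categories")
    mapped = frozenset(
        annot.orthologs[g] for g in group.gene_set if g in annot.orthologs
    )
    test = mapped & annot.universe
    if not test:
        logger.warning("group %s: no orthologous test genes in %s", group.term, annot.name)
        return []
    pool = annot.category_pool(hpo_category)
    if not pool:
        logger.info("group %s: category %s has empty gene pool", group.term, hpo_category)
        return []
    min_genes = min_frac * len(pool)
    term_genes = {
        t: gs
        for t, gs in annot.term_genes.items()
        if annot.term_categories.get(t) == hpo_category
        and len(gs & pool) >= min_genes
    }
    return _test_terms(test, annot.universe, term_genes, group.term, annot.name, alpha)


# ---------------------------------------------------------------------------
# readers


def read_gmt(path, name: str, **kwargs) -> AnnotationCollection:
    """GMT format: term <tab> description <tab> gene1 <tab> gene2 ...

    The universe defaults to the union of all annotated genes.
    """
    term_genes: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term_genes[parts[0]] = frozenset(g for g in parts[2:] if g)
    universe = kwargs.pop("universe", None) or frozenset().union(*term_genes.values())
    return AnnotationCollection(
        name=name, term_genes=term_genes, universe=frozenset(universe), **kwargs
    )


def read_two_column_map(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            out[a] = b
    return out
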