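"""Phenotypic convergence: Goodall3 similarity and contributing-patient tests.

Because the cohort is phenotyped systematically, the absence of a recorded
phenotype is evidence of absence, and similarity between two patients can
use both shared presences and shared absences.  The Goodall3 measure
weights each phenotype i by its cohort frequency f_i:

    G_i = 1 - f_i^2          if i is present in both patients
    G_i = 1 - (1 - f_i)^2    if i is present in neither patient
    G_i = 0                  if i is present in only one

and the pairwise score is the sum of G_i over the phenotype universe
(every term annotated to any patient under comparison).  Sharing a rare
phenotype, or jointly lacking a common one, scores highly.

For each significant functional enrichment, the patients in the group are
split into "contributing" (their CNV genes intersect the enrichment's
gene set) and "non-contributing"; a two-sided Wilcoxon rank-sum test then
compares similarity among contributing pairs (intra) to similarity between
contributing and non-contributing patients (inter).  Comparisons need at
least 10 patients on each side to be testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import PatientPhenotypeGroup, PatientRecord
from .enrichment import AnnotationCollection, EnrichmentResult
from .networks import ClusterTestResult, GeneNetwork
from .ontology import OntologyDAG, proper_descendants

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyTable",
    "ConvergenceResult",
    "phenotype_frequencies",
    "goodall3",
    "contributing_split",
    "convergence_test",
    "subterm_convergence",
    "excess_binomial",
    "combine_by_annotation",
    "replication_grouping",
    "wilcoxon_rank_sum",
]

MIN_EACH = 10  # minimum contributing and non-contributing patients


@dataclass
class FrequencyTable:
    """Cohort frequencies of every phenotype carried by >= 1 patient."""

    terms: tuple[str, ...]  # the phenotype universe, sorted
    freqs: np.ndarray  # f_i in (0, 1]
    n_patients: int
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.freqs) and not ((self.freqs > 0) & (self.freqs <= 1)).all():
            raise ValueError("frequencies must lie in (0, 1]")

    def presence_vector(self, terms: Iterable[str]) -> np.ndarray:
        v = np.zeros(len(self.terms), dtype=bool)
        for t in terms:
            i = self.index.get(t)
            if i is not None:
                v[i] = True
        return v


def phenotype_frequencies(patients: Sequence[PatientRecord]) -> FrequencyTable:
    """f_i = carriers / cohort size over all terms carried by >= 1 patient."""
    if not patients:
        raise ValueError("empty cohort")
    counts: dict[str, int] = {}
    for p in patients:
        for t in p.propagated_terms:
            counts[t] = counts.get(t, 0) + 1
    terms = tuple(sorted(counts))
    freqs = np.array([counts[t] / len(patients) for t in terms])
    return FrequencyTable(terms=terms, freqs=freqs, n_patients=len(patients))


def goodall3(
    terms_a: Iterable[str], terms_b: Iterable[str], freqs: FrequencyTable
) -> float:
    """Goodall3 similarity of two patients' phenotype-term sets."""
    a = freqs.presence_vector(terms_a)
    b = freqs.presence_vector(terms_b)
    f = freqs.freqs
    both = a & b
    neither = ~a & ~b
    return float(np.sum((1 - f**2) * both) + np.sum((1 - (1 - f) ** 2) * neither))


def _similarity_matrix(
    patients: Sequence[PatientRecord], freqs: FrequencyTable,
    term_filter: frozenset[str] | None = None,
) -> np.ndarray:
    """All-pairs Goodall3 scores (vectorised over the phenotype universe)."""
    f = freqs.freqs
    P = np.zeros((len(patients), len(freqs.terms)), dtype=float)
    for i, p in enumerate(patients):
        terms = p.propagated_terms if term_filter is None else p.propagated_terms & term_filter
        P[i] = freqs.presence_vector(terms)
    w_both = 1 - f**2
    w_neither = 1 - (1 - f) ** 2
    Q = 1.0 - P
    return P @ (w_both[:, None] * P.T) + Q @ (w_neither[:, None] * Q.T)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) statistic and p-value.

    Exact null distribution for small tie-free inputs; normal approximation
    with tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) + len(y) <= 12
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ConvergenceResult:
    group_term: str
    reference: str  # resource + annotation term, or network id
    contributing: frozenset[str]
    non_contributing: frozenset[str]
    intra: np.ndarray  # similarity over contributing pairs
    inter: np.ndarray  # similarity contributing x non-contributing
    statistic: float = float("nan")
    p: float = float("nan")
    direction: int = 0  # sign(median(intra) - median(inter))
    untestable: bool = False
    n_groups: int = 1  # >1 for pooled-by-annotation results

    @property
    def significant(self) -> bool:
        return (not self.untestable) and self.p < 0.05


def contributing_split(
    group: PatientPhenotypeGroup,
    enrichment: EnrichmentResult | ClusterTestResult,
    patients: Mapping[str, PatientRecord],
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition group members by whether their CNV genes hit the
    enrichment's contributing gene set."""
    contrib_genes = set(enrichment.contributing_genes)
    contributing = frozenset(
        pid
        for pid in group.member_ids
        if patients[pid].de_novo_gene_set() & contrib_genes
    )
    return contributing, frozenset(group.member_ids) - contributing


def _test_partition(
    group_term: str,
    reference: str,
    contributing: frozenset[str],
    non_contributing: frozenset[str],
    patients: Mapping[str, PatientRecord],
    freqs: FrequencyTable,
    min_each: int = MIN_EACH,
    term_filter: frozenset[str] | None = None,
    n_groups: int = 1,
) -> ConvergenceResult:
    contrib = sorted(contributing)
    noncontrib = sorted(non_contributing)
    base = ConvergenceResult(
        group_term=group_term,
        reference=reference,
        contributing=frozenset(contrib),
        non_contributing=frozenset(noncontrib),
        intra=np.array([]),
        inter=np.array([]),
        untestable=True,
        n_groups=n_groups,
    )
    if len(contrib) < min_each or len(noncontrib) < min_each:
        return base
    if len(contrib) < 2:  # no intra pairs exist (only reachable when min_each < 2)
        return base
    if term_filter is not None and not term_filter:
        return base
    ordered = [patients[pid] for pid in contrib + noncontrib]
    sim = _similarity_matrix(ordered, freqs, term_filter)
    nc = len(contrib)
    iu, ju = np.triu_indices(nc, k=1)
    intra = sim[iu, ju]
    inter = sim[:nc, nc:].ravel()
    statistic, p = wilcoxon_rank_sum(intra, inter)
    direction = int(np.sign(np.median(intra) - np.median(inter)))
    return ConvergenceResult(
        group_term=group_term,
        reference=reference,
        contributing=frozenset(contrib),
        non_contributing=frozenset(noncontrib),
        intra=intra,
        inter=inter,
        statistic=statistic,
        p=p,
        direction=direction,
        untestable=False,
        n_groups=n_groups,
    )


def convergence_test(
    group: PatientPhenotypeGroup,
    split: tuple[frozenset[str], frozenset[str]],
    patients: Mapping[str, PatientRecord],
    freqs: FrequencyTable,
    reference: str = "",
    min_each: int = MIN_EACH,
) -> ConvergenceResult:
    """Intra- vs inter-similarity Wilcoxon test for one enrichment split.

    Intra = Goodall3 over all contributing pairs; inter = over all
    contributing × non-contributing pairs.  Untestable below ``min_each``
    on either side.
    """
    contributing, non_contributing = split
    return _test_partition(
        group.term, reference, contributing, non_contributing, patients, freqs,
        min_each=min_each,
    )


def subterm_convergence(
    group: PatientPhenotypeGroup,
    split: tuple[frozenset[str], frozenset[str]],
    patients: Mapping[str, PatientRecord],
    dag: OntologyDAG,
    reference: str = "",
    min_each: int = MIN_EACH,
) -> ConvergenceResult:
    """Convergence test restricted to subterms of the group phenotype.

    The phenotype universe and frequencies are recomputed over the group
    members and restricted to proper descendants of the group term; a
    significant result here means contributing patients share a more
    specific form of the group phenotype, rather than distinct co-morbid
    phenotypes.
    """
    subterms = proper_descendants(dag, group.term)
    members = [patients[pid] for pid in sorted(group.member_ids)]
    counts: dict[str, int] = {}
    for p in members:
        for t in p.propagated_terms & subterms:
            counts[t] = counts.get(t, 0) + 1
    terms = tuple(sorted(counts))
    if not terms:
        return _test_partition(
            group.term, reference, split[0], split[1], patients,
            FrequencyTable(terms=(), freqs=np.array([]), n_patients=len(members)),
            min_each=min_each, term_filter=frozenset(),
        )
    freqs = FrequencyTable(
        terms=terms,
        freqs=np.array([counts[t] / len(members) for t in terms]),
        n_patients=len(members),
    )
    return _test_partition(
        group.term, reference, split[0], split[1], patients, freqs,
        min_each=min_each, term_filter=frozenset(terms),
    )


def excess_binomial(results: Sequence[ConvergenceResult]) -> tuple[float, int, int]:
    """One-sided binomial test for an excess of intra > inter instances.

    Counts testable results whose contributing patients are more similar
    to each other (median intra > median inter) against p = 0.5; results
    with tied medians are dropped from the denominator.  Returns
    (p, n_intra_greater, n_considered).
    """
    testable = [r for r in results if not r.untestable]
    if not testable:
        raise ValueError("no testable convergence results")
    nonzero = [r for r in testable if r.direction != 0]
    k = sum(1 for r in nonzero if r.direction > 0)
    n = len(nonzero)
    if n == 0:
        logger.warning("all convergence results have tied medians; excess untestable")
        return float("nan"), 0, 0
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return float(p), k, n


def combine_by_annotation(
    enrichments: Sequence[EnrichmentResult],
    groups: Mapping[str, PatientPhenotypeGroup],
    patients: Mapping[str, PatientRecord],
    freqs: FrequencyTable,
    min_each: int = MIN_EACH,
) -> list[ConvergenceResult]:
    """Pool patients across phenotype groups sharing a significant annotation.

    For each annotation term significant in one or more groups, the
    contributing patients of those groups are pooled, non-contributing
    patients are the remaining pooled group members, and the convergence
    test is run on the pooled split.  The number of associated phenotype
    groups is reported on each result.
    """
    by_annot: dict[tuple[str, str], list[EnrichmentResult]] = {}
    for e in enrichments:
        if e.significant:
            by_annot.setdefault((e.resource, e.annotation_term), []).append(e)
    out: list[ConvergenceResult] = []
    for (resource, term), hits in sorted(by_annot.items()):
        contributing: set[str] = set()
        members: set[str] = set()
        for e in hits:
            group = groups[e.group_term]
            c, _nc = contributing_split(group, e, patients)
            contributing |= c
            members |= group.member_ids
        non_contributing = members - contributing
        if not non_contributing:
            logger.info("annotation %s/%s: every pooled patient contributes", resource, term)
            continue
        out.append(
            _test_partition(
                group_term="+".join(sorted({e.group_term for e in hits})),
                reference=f"{resource}:{term}",
                contributing=frozenset(contributing),
                non_contributing=frozenset(non_contributing),
                patients=patients,
                freqs=freqs,
                min_each=min_each,
                n_groups=len(hits),
            )
        )
    return out


def replication_grouping(
    pool_patients: Sequence[PatientRecord],
    phenotype_term: str,
    candidate_genes: frozenset[str],
    extended_genes: frozenset[str],
    reference: str = "",
    min_each: int = MIN_EACH,
) -> dict:
    """Three-way replication partition on patients without de novo CNVs.

    Patients holding ``phenotype_term`` are placed in mutually exclusive
    groups by their (inherited / unknown-inheritance) CNV genes:
    "candidate" when they hit a candidate-pathway gene, else "extended"
    when they hit a gene functionally linked to the pathway, else "none".
    Two convergence tests run: candidate vs (extended + none), and
    extended vs none, with frequencies over the comparison pool.
    """
    with_term = [p for p in pool_patients if phenotype_term in p.propagated_terms]
    candidate: set[str] = set()
    extended: set[str] = set()
    none: set[str] = set()
    for p in with_term:
        gene_set = p.all_cnv_gene_set()
        if gene_set & candidate_genes:
            candidate.add(p.patient_id)
        elif gene_set & extended_genes:
            extended.add(p.patient_id)
        else:
            none.add(p.patient_id)
    if not with_term:
        return {"candidate": set(), "extended": set(), "none": set(),
                "candidate_vs_rest": None, "extended_vs_none": None}
    freqs = phenotype_frequencies(with_term)
    by_id = {p.patient_id: p for p in with_term}
    cand_test = _test_partition(
        phenotype_term, f"{reference}|candidate_vs_rest",
        frozenset(candidate), frozenset(extended | none), by_id, freqs,
        min_each=min_each,
    )
    ext_test = _test_partition(
        phenotype_term, f"{reference}|extended_vs_none",
        frozenset(extended), frozenset(none), by_id, freqs,
        min_each=min_each,
    )
    return {
        "candidate": candidate,
        "extended": extended,
        "none": none,
        "candidate_vs_rest": cand_test,
        "extended_vs_none": ext_test,
    }
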