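"""Goodall3 similarity and the convergence test suite."""

from itertools import combinations

import numpy as np
import pytest

from phenoconverge.cohort import CnvCall, PatientPhenotypeGroup, PatientRecord
from phenoconverge.convergence import (
    FrequencyTable,
    combine_by_annotation,
    contributing_split,
    convergence_test,
    excess_binomial,
    goodall3,
    phenotype_frequencies,
    replication_grouping,
    subterm_convergence,
    wilcoxon_rank_sum,
    ConvergenceResult,
)
from phenoconverge.enrichment import EnrichmentResult

from .conftest import random_dag


def _patient(pid, terms, genes=()):
    p = PatientRecord(patient_id=pid, direct_terms=set(terms),
                      propagated_terms=set(terms), cnv_calls=[])
    if genes:
        cnv = CnvCall("chr1", 0, 100, "loss", "de_novo", pid, f"{pid}:c")
        p.cnv_calls = [cnv]
        p.affected_genes = {cnv.cnv_id: set(genes)}
    return p


def _freqs(term_freqs: dict):
    terms = tuple(sorted(term_freqs))
    return FrequencyTable(terms=terms, freqs=np.array([term_freqs[t] for t in terms]),
                          n_patients=100)


class TestFrequencies:
    def test_basic_fractions(self):
        patients = [_patient("P1", {"A"}), _patient("P2", {"A", "B"}),
                    _patient("P3", {"A"}), _patient("P4", {"A", "C"})]
        ft = phenotype_frequencies(patients)
        assert ft.freqs[ft.index["A"]] == pytest.approx(1.0)
        assert ft.freqs[ft.index["B"]] == pytest.approx(0.25)

    def test_counting_identity(self):
        rng = np.random.default_rng(0)
        terms = [f"T{i}" for i in range(30)]
        patients = [
            _patient(f"P{i}", set(rng.choice(terms, size=int(rng.integers(1, 10)),
                                             replace=False).tolist()))
            for i in range(25)
        ]
        ft = phenotype_frequencies(patients)
        assert sum(len(p.propagated_terms) for p in patients) == pytest.approx(
            ft.freqs.sum() * len(patients)
        )

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            phenotype_frequencies([])


def goodall3_oracle(a, b, term_freqs):
    """Straight transcription of the piecewise formula."""
    total = 0.0
    for term, f in term_freqs.items():
        if term in a and term in b:
            total += 1 - f**2
        elif term not in a and term not in b:
            total += 1 - (1 - f) ** 2
    return total


class TestGoodall3:
    def test_ubiquitous_shared_phenotype_scores_zero(self):
        ft = _freqs({"A": 1.0})
        assert goodall3({"A"}, {"A"}, ft) == pytest.approx(0.0)

    def test_hand_worked_example(self):
        ft = _freqs({"A": 0.5, "B": 0.25, "C": 0.75})
        score = goodall3({"A", "B"}, {"A"}, ft)
        assert score == pytest.approx((1 - 0.25) + 0 + (1 - 0.0625))

    def test_random_pairs_match_oracle_and_are_symmetric(self):
        rng = np.random.default_rng(1)
        terms = [f"T{i}" for i in range(40)]
        tf = {t: float(rng.uniform(0.01, 1.0)) for t in terms}
        ft = _freqs(tf)
        for _ in range(1000):
            a = set(rng.choice(terms, size=int(rng.integers(0, 20))).tolist())
            b = set(rng.choice(terms, size=int(rng.integers(0, 20))).tolist())
            s = goodall3(a, b, ft)
            assert s == pytest.approx(goodall3_oracle(a, b, tf), abs=1e-12)
            assert s == goodall3(b, a, ft)

    def test_self_similarity_dominates_and_bounds_hold(self):
        rng = np.random.default_rng(2)
        terms = [f"T{i}" for i in range(25)]
        tf = {t: float(rng.uniform(0.05, 0.95)) for t in terms}
        ft = _freqs(tf)
        upper = sum(max(1 - f**2, 1 - (1 - f) ** 2) for f in tf.values())
        for _ in range(100):
            a = set(rng.choice(terms, size=8).tolist())
            b = set(rng.choice(terms, size=8).tolist())
            s_ab = goodall3(a, b, ft)
            assert goodall3(a, a, ft) >= s_ab - 1e-12
            assert 0 <= s_ab <= upper + 1e-12

    def test_shared_presence_increases_discordance_never_does(self):
        ft = _freqs({"A": 0.5, "B": 0.3, "C": 0.4})
        base_terms = {"A"}
        base = goodall3(base_terms, base_terms, ft)
        with_shared = goodall3({"A", "B"}, {"A", "B"}, ft)
        assert with_shared > base  # new shared presence with f < 1 adds weight
        discordant = goodall3({"A", "B"}, {"A"}, ft)
        assert discordant <= base + 1e-12


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exact_rank_sum_enumeration(self, seed):
        """Two-sided p agrees with enumeration over all group assignments."""
        rng = np.random.default_rng(seed)
        nx_, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pool = rng.permutation(100)[: nx_ + ny].astype(float)  # distinct values
        x, y = pool[:nx_], pool[nx_:]
        _stat, p = wilcoxon_rank_sum(x, y)

        ranks = {v: r + 1 for r, v in enumerate(sorted(pool))}
        obs = sum(ranks[v] for v in x)
        mean = nx_ * (nx_ + ny + 1) / 2
        count = total = 0
        for idx in combinations(range(nx_ + ny), nx_):
            w = sum(ranks[pool[i]] for i in idx)
            total += 1
            if abs(w - mean) >= abs(obs - mean) - 1e-9:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-10)


class TestContributingSplit:
    def _group(self, members):
        return PatientPhenotypeGroup(term="T", member_ids=frozenset(members),
                                     gene_set=frozenset())

    def _enr(self, genes):
        return EnrichmentResult("T", "GO", "GO:x", 1, 1, 1, 2, 1.0, 0.5,
                                contributing_genes=frozenset(genes))

    def test_all_or_none(self):
        patients = {f"P{i}": _patient(f"P{i}", {"T"}, genes={"G1"}) for i in range(4)}
        group = self._group(patients)
        c, nc = contributing_split(group, self._enr({"G9"}), patients)
        assert c == frozenset() and nc == frozenset(patients)
        c, nc = contributing_split(group, self._enr({"G1"}), patients)
        assert c == frozenset(patients) and nc == frozenset()

    def test_generator_carrier_labels_recovered(self, small_bundle):
        from phenoconverge.cohort import annotate_affected_genes, build_groups, filter_cohort
        from phenoconverge.enrichment import enrich_group

        patients = small_bundle.patients()
        annotate_affected_genes(patients, small_bundle.genes,
                                small_bundle.control_gains, small_bundle.control_losses)
        retained, _ = filter_cohort(patients)
        truth = small_bundle.truth
        target = truth.target_terms["pathway1"]
        group = {g.term: g for g in build_groups(retained)}[target]
        res = enrich_group(group, small_bundle.annotations["GO"])
        planted = next(r for r in res
                       if r.annotation_term == truth.planted_annotation_terms["GO"]["pathway1"])
        by_id = {p.patient_id: p for p in retained}
        c, _nc = contributing_split(group, planted, by_id)
        carriers_in_group = set(truth.carriers["pathway1"]) & set(group.member_ids)
        assert carriers_in_group <= set(c)


def _cohort_with_split(rng, n_c=15, n_nc=15, n_terms=60, bg=0.1, comorbid=None,
                       comorbid_rate=0.8):
    """Patients with independent background terms; contributing patients get
    extra co-morbid terms at an elevated rate."""
    terms = [f"T{i}" for i in range(n_terms)]
    comorbid = comorbid or []
    patients = {}
    for i in range(n_c + n_nc):
        present = {t for t in terms if rng.random() < bg}
        if i < n_c:
            present |= {t for t in comorbid if rng.random() < comorbid_rate}
        present.add("GROUP")
        patients[f"P{i:03d}"] = _patient(f"P{i:03d}", present)
    contributing = frozenset(f"P{i:03d}" for i in range(n_c))
    non_contributing = frozenset(f"P{i:03d}" for i in range(n_c, n_c + n_nc))
    group = PatientPhenotypeGroup(term="GROUP", member_ids=frozenset(patients),
                                  gene_set=frozenset())
    freqs = phenotype_frequencies(list(patients.values()))
    return group, (contributing, non_contributing), patients, freqs


class TestConvergenceTest:
    def test_below_minimum_untestable(self):
        rng = np.random.default_rng(0)
        group, split, patients, freqs = _cohort_with_split(rng, n_c=9, n_nc=15)
        res = convergence_test(group, split, patients, freqs)
        assert res.untestable

    def test_null_value_sets_give_calibrated_rejection(self):
        """Intra and inter value sets drawn i.i.d. from one distribution:
        the two-sided rank-sum rejects at ~ alpha."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            intra = rng.normal(size=105)
            inter = rng.normal(size=225)
            _s, p = wilcoxon_rank_sum(intra, inter)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.075

    def test_patient_level_null_pleiotropy_rejection_bounded(self):
        """Patient-level null: similarity pairs share patients, so the raw
        rank-sum is anticonservative; the rate stays bounded and the test
        is used as a descriptive index (direction feeds the binomial
        meta-test, which is calibrated)."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            group, split, patients, freqs = _cohort_with_split(rng)
            res = convergence_test(group, split, patients, freqs)
            rejections += res.p < 0.05
        assert rejections / n_rep <= 0.2

    def test_planted_pleiotropy_detected_with_power(self):
        rng = np.random.default_rng(6)
        comorbid = [f"T{i}" for i in range(5)]
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            group, split, patients, freqs = _cohort_with_split(
                rng, comorbid=comorbid, comorbid_rate=0.8
            )
            res = convergence_test(group, split, patients, freqs)
            hits += res.significant and res.direction > 0
        assert hits / n_rep >= 0.8

    def test_pair_counts(self):
        rng = np.random.default_rng(7)
        group, split, patients, freqs = _cohort_with_split(rng, n_c=12, n_nc=11)
        res = convergence_test(group, split, patients, freqs)
        assert len(res.intra) == 12 * 11 // 2
        assert len(res.inter) == 12 * 11


class TestSubtermConvergence:
    def test_leaf_group_term_untestable(self):
        dag = random_dag(40, np.random.default_rng(8))
        leaves = sorted(dag.term_ids - {p for _c, p in dag.is_a_edges})
        rng = np.random.default_rng(9)
        group, split, patients, freqs = _cohort_with_split(rng)
        group = PatientPhenotypeGroup(term=leaves[0], member_ids=group.member_ids,
                                      gene_set=frozenset())
        res = subterm_convergence(group, split, patients, dag)
        assert res.untestable

    def _dag_with_branch(self):
        """ROOT <- GROUP <- C0..C9 (subterms), plus OUT0..OUT4 off-branch."""
        edges = {("GROUP", "ROOT")}
        for i in range(10):
            edges.add((f"C{i}", "GROUP"))
        for i in range(5):
            edges.add((f"OUT{i}", "ROOT"))
        ids = {c for c, _ in edges} | {"ROOT"}
        from phenoconverge.ontology import OntologyDAG

        return OntologyDAG(term_ids=ids, labels={t: t for t in ids}, is_a_edges=edges)

    def _build(self, rng, inside: bool, n_c=15, n_nc=15):
        dag = self._dag_with_branch()
        patients = {}
        planted = [f"C{i}" for i in range(5)] if inside else [f"OUT{i}" for i in range(5)]
        for i in range(n_c + n_nc):
            present = {"GROUP", "ROOT"}
            present |= {t for t in [f"C{i}" for i in range(10)] if rng.random() < 0.1}
            present |= {t for t in [f"OUT{i}" for i in range(5)] if rng.random() < 0.1}
            if i < n_c:
                present |= {t for t in planted if rng.random() < 0.85}
            if any(t.startswith("C") for t in present):
                present.add("GROUP")
            patients[f"P{i:03d}"] = _patient(f"P{i:03d}", present)
        split = (frozenset(f"P{i:03d}" for i in range(n_c)),
                 frozenset(f"P{i:03d}" for i in range(n_c, n_c + n_nc)))
        group = PatientPhenotypeGroup(term="GROUP", member_ids=frozenset(patients),
                                      gene_set=frozenset())
        freqs = phenotype_frequencies(list(patients.values()))
        return dag, group, split, patients, freqs

    def test_comorbidity_outside_branch_full_significant_subterm_null(self):
        """Distinct co-morbid phenotypes: whole-universe test fires, the
        subterm-restricted test does not."""
        rng = np.random.default_rng(10)
        full_sig = sub_sig = 0
        for _ in range(40):
            dag, group, split, patients, freqs = self._build(rng, inside=False)
            full = convergence_test(group, split, patients, freqs)
            sub = subterm_convergence(group, split, patients, dag)
            full_sig += full.significant and full.direction > 0
            sub_sig += (not sub.untestable) and sub.p < 0.05 and sub.direction > 0
        assert full_sig >= 30
        assert sub_sig <= 10

    def test_subtype_structure_inside_branch_detected_by_subterm_test(self):
        rng = np.random.default_rng(11)
        sub_sig = 0
        for _ in range(40):
            dag, group, split, patients, freqs = self._build(rng, inside=True)
            sub = subterm_convergence(group, split, patients, dag)
            sub_sig += (not sub.untestable) and sub.p < 0.05 and sub.direction > 0
        assert sub_sig >= 30


class TestExcessBinomial:
    def _res(self, direction, untestable=False):
        return ConvergenceResult("T", "r", frozenset(), frozenset(),
                                 np.array([]), np.array([]), 0.0, 0.5,
                                 direction=direction, untestable=untestable)

    def test_all_positive_closed_form(self):
        p, k, n = excess_binomial([self._res(1) for _ in range(10)])
        assert p == pytest.approx(2.0**-10)
        assert (k, n) == (10, 10)

    def test_half_positive_is_not_significant(self):
        results = [self._res(1)] * 5 + [self._res(-1)] * 5
        p, _k, _n = excess_binomial(results)
        assert p > 0.5

    def test_ties_dropped_from_denominator(self):
        results = [self._res(1)] * 3 + [self._res(0)] * 4
        p, k, n = excess_binomial(results)
        assert (k, n) == (3, 3)
        assert p == pytest.approx(0.125)

    def test_untestable_results_excluded_and_empty_errors(self):
        with pytest.raises(ValueError):
            excess_binomial([self._res(1, untestable=True)])

    def test_null_simulation_is_calibrated(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(300):
            dirs = rng.choice([-1, 1], size=20)
            pvals.append(excess_binomial([self._res(int(d)) for d in dirs])[0])
        # one-sided binomial p under the null: P(p <= 0.05) should be <= ~0.05
        assert np.mean(np.array(pvals) < 0.05) <= 0.08


class TestCombineByAnnotation:
    def _setup(self, rng, n_groups=3, shared=True):
        patients = {}
        groups = {}
        enrichments = []
        terms = [f"T{i}" for i in range(40)]
        for gi in range(n_groups):
            members = []
            for i in range(24):
                pid = f"G{gi}P{i:02d}"
                present = {t for t in terms if rng.random() < 0.1} | {f"GRP{gi}"}
                genes = {"GPATH"} if i < 12 else {"GOTHER"}
                patients[pid] = _patient(pid, present, genes=genes)
                members.append(pid)
            groups[f"GRP{gi}"] = PatientPhenotypeGroup(
                term=f"GRP{gi}", member_ids=frozenset(members), gene_set=frozenset()
            )
            term = "GO:shared" if shared else f"GO:term{gi}"
            enrichments.append(
                EnrichmentResult(f"GRP{gi}", "GO", term, 1, 1, 1, 2, 1.0, 1e-4,
                                 q=1e-4, significant=True,
                                 contributing_genes=frozenset({"GPATH"}))
            )
        freqs = phenotype_frequencies(list(patients.values()))
        return enrichments, groups, patients, freqs

    def test_single_group_annotation_equals_single_result(self):
        rng = np.random.default_rng(13)
        enr, groups, patients, freqs = self._setup(rng, n_groups=1)
        combined = combine_by_annotation(enr, groups, patients, freqs)
        assert len(combined) == 1
        single = convergence_test(groups["GRP0"],
                                  contributing_split(groups["GRP0"], enr[0], patients),
                                  patients, freqs)
        assert combined[0].p == pytest.approx(single.p)
        assert combined[0].n_groups == 1

    def test_disjoint_groups_pool_pairs(self):
        rng = np.random.default_rng(14)
        enr, groups, patients, freqs = self._setup(rng, n_groups=2)
        combined = combine_by_annotation(enr, groups, patients, freqs)
        assert len(combined) == 1
        r = combined[0]
        assert r.n_groups == 2
        n_c = len(r.contributing)
        assert len(r.intra) == n_c * (n_c - 1) // 2

    def test_distinct_annotations_stay_separate(self):
        rng = np.random.default_rng(15)
        enr, groups, patients, freqs = self._setup(rng, n_groups=3, shared=False)
        combined = combine_by_annotation(enr, groups, patients, freqs)
        assert len(combined) == 3
        assert all(r.n_groups == 1 for r in combined)


class TestReplicationGrouping:
    def test_partition_rules(self):
        patients = [
            _patient("PA", {"T"}, genes={"CAND", "EXT"}),  # candidate wins
            _patient("PB", {"T"}, genes={"EXT"}),
            _patient("PC", {"T"}, genes={"ZZZ"}),
            _patient("PD", {"T"}),  # no CNV genes at all
        ]
        out = replication_grouping(patients, "T", frozenset({"CAND"}),
                                   frozenset({"EXT"}), min_each=1)
        assert out["candidate"] == {"PA"}
        assert out["extended"] == {"PB"}
        assert out["none"] == {"PC", "PD"}

    def test_planted_inherited_signal_detected(self, small_bundle):
        """Replication carriers hitting pathway genes converge phenotypically."""
        from phenoconverge.cohort import annotate_affected_genes, filter_cohort

        patients = small_bundle.patients()
        annotate_affected_genes(patients, small_bundle.genes,
                                small_bundle.control_gains, small_bundle.control_losses)
        _retained, pool = filter_cohort(patients)
        truth = small_bundle.truth
        target = truth.target_terms["pathway1"]
        cand = frozenset(truth.pathway_genes["pathway1"])
        out = replication_grouping(pool, target, cand, frozenset(), min_each=3)
        res = out["candidate_vs_rest"]
        assert not res.untestable
        assert res.direction > 0
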