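"""Cohort filtering, CNV-gene overlap, control removal, CNVR merging, grouping."""

import numpy as np
import pytest

from phenoconverge.cohort import (
    CnvCall,
    GeneModel,
    PatientRecord,
    build_groups,
    filter_cohort,
    filter_control_genes,
    genes_affected,
    merge_cnvrs,
)
from phenoconverge.ontology import propagate_ancestors


def _patient(pid, cnvs, terms=None):
    return PatientRecord(
        patient_id=pid,
        direct_terms=set(terms or []),
        propagated_terms=set(terms or []),
        cnv_calls=cnvs,
    )


def _cnv(start, end, inh="de_novo", pid="P1", dosage="loss", chrom="chr1", cid=""):
    return CnvCall(chrom, start, end, dosage, inh, pid, cid or f"{pid}:{start}")


class TestFilterCohort:
    def test_large_de_novo_excludes_patient(self):
        retained, repl = filter_cohort([_patient("P1", [_cnv(0, 6_000_000)])])
        assert retained == [] and repl == []

    def test_exactly_at_cap_is_excluded(self):
        retained, _ = filter_cohort([_patient("P1", [_cnv(0, 5_000_000)])])
        assert retained == []

    def test_small_de_novo_with_inherited_is_retained(self):
        p = _patient("P1", [_cnv(0, 1_000_000), _cnv(0, 2_000_000, inh="inherited")])
        retained, repl = filter_cohort([p])
        assert [q.patient_id for q in retained] == ["P1"] and repl == []
        assert len(retained[0].de_novo_calls()) == 1

    def test_inherited_only_goes_to_replication_pool(self):
        retained, repl = filter_cohort([_patient("P1", [_cnv(0, 1000, inh="inherited")])])
        assert retained == [] and [q.patient_id for q in repl] == ["P1"]

    def test_no_cnv_records_excluded_everywhere(self):
        retained, repl = filter_cohort([_patient("P1", [])])
        assert retained == [] and repl == []


def _gene(gid, start, end, transcripts, chrom="chr1"):
    return GeneModel(gene_id=gid, chromosome=chrom, gene_start=start, gene_end=end,
                     transcripts=transcripts)


class TestGenesAffected:
    def test_full_containment(self):
        g = _gene("G1", 100, 200, (((100, 150), (180, 200)),))
        assert genes_affected(_cnv(50, 250), [g]) == {"G1"}

    def test_partial_hit_must_cover_every_transcript(self):
        # CNV hits an exon of transcript 1 only -> excluded
        g = _gene("G1", 100, 1000, (((100, 200), (900, 1000)), ((600, 700), (900, 1000))))
        assert genes_affected(_cnv(150, 250), [g]) == set()
        # hits at least one exon of each transcript -> included
        assert genes_affected(_cnv(150, 650), [g]) == {"G1"}

    def test_other_chromosome_skipped(self):
        g = _gene("G1", 100, 200, (((100, 200),),), chrom="chr2")
        assert genes_affected(_cnv(0, 1000), [g]) == set()

    def test_random_pairs_match_interval_oracle(self):
        """10,000 random CNV/gene pairs agree with a brute-force oracle."""
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            gs = int(rng.integers(0, 5000))
            ge = gs + int(rng.integers(10, 2000))
            n_tx = int(rng.integers(1, 4))
            txs = []
            for _t in range(n_tx):
                n_ex = int(rng.integers(1, 4))
                cuts = np.sort(rng.choice(np.arange(1, ge - gs), size=2 * n_ex, replace=False))
                txs.append(tuple((gs + int(cuts[2 * k]), gs + int(cuts[2 * k + 1]))
                                 for k in range(n_ex)))
            gene = _gene("G1", gs, ge, tuple(txs))
            cs = int(rng.integers(0, 6000))
            ce = cs + int(rng.integers(10, 3000))
            cnv = _cnv(cs, ce)

            def overlaps(a, b):  # independent half-open interval arithmetic
                return max(a[0], b[0]) < min(a[1], b[1])

            contained = cs <= gs and ge <= ce
            all_tx = all(any(overlaps(e, (cs, ce)) for e in tx) for tx in txs)
            expected = {"G1"} if (contained or all_tx) else set()
            assert genes_affected(cnv, [gene]) == expected

    def test_monotone_in_cnv_span(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            gs = int(rng.integers(0, 1000))
            ge = gs + int(rng.integers(50, 400))
            cuts = np.sort(rng.choice(np.arange(1, ge - gs), size=4, replace=False))
            gene = _gene("G1", gs, ge, (
                ((gs + int(cuts[0]), gs + int(cuts[1])),),
                ((gs + int(cuts[2]), gs + int(cuts[3])),),
            ))
            cs = int(rng.integers(0, 1500))
            ce = cs + int(rng.integers(10, 500))
            small = genes_affected(_cnv(cs, ce), [gene])
            large = genes_affected(_cnv(max(0, cs - 100), ce + 100), [gene])
            assert small <= large


class TestControlFilter:
    def test_direction_matched_removal_only(self):
        gain = _cnv(0, 100, dosage="gain", cid="c1")
        loss = _cnv(0, 100, dosage="loss", cid="c2")
        by_cnv = {"c1": {"A", "B"}, "c2": {"A", "B"}}
        cnvs = {"c1": gain, "c2": loss}
        out = filter_control_genes(by_cnv, cnvs, control_gains={"A"}, control_losses={"B"})
        assert out == {"c1": {"B"}, "c2": {"A"}}

    def test_empty_controls_are_identity(self):
        gain = _cnv(0, 100, dosage="gain", cid="c1")
        out = filter_control_genes({"c1": {"A"}}, {"c1": gain}, set(), set())
        assert out == {"c1": {"A"}}


class TestMergeCnvrs:
    def test_bookended_merge(self):
        regions = merge_cnvrs([_cnv(1000, 2000, cid="a"), _cnv(2000, 3000, cid="b")])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1000, 3000)

    def test_one_bp_gap_stays_separate(self):
        regions = merge_cnvrs([_cnv(1000, 2000, cid="a"), _cnv(2001, 3000, cid="b")])
        assert len(regions) == 2

    def test_matches_union_find_oracle(self):
        """Random CNVs: component count equals a union-find oracle's."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            calls = []
            for i in range(93):
                s = int(rng.integers(0, 50_000))
                calls.append(_cnv(s, s + int(rng.integers(100, 5000)), cid=f"c{i}",
                                  chrom=f"chr{int(rng.integers(1, 4))}"))
            parent = list(range(len(calls)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i, a in enumerate(calls):
                for k, b in enumerate(calls):
                    if k <= i or a.chromosome != b.chromosome:
                        continue
                    if a.start <= b.end and b.start <= a.end:  # overlap or bookend
                        parent[find(i)] = find(k)
            n_components = len({find(i) for i in range(len(calls))})
            regions = merge_cnvrs(calls)
            assert len(regions) == n_components
            # regions on one chromosome are pairwise non-overlapping, non-bookended
            by_chrom = {}
            for r in regions:
                by_chrom.setdefault(r.chromosome, []).append(r)
            for rs in by_chrom.values():
                rs.sort(key=lambda r: r.start)
                assert all(a.end < b.start for a, b in zip(rs, rs[1:]))


class TestBuildGroups:
    def test_min_size_threshold(self):
        patients = [_patient(f"P{i}", [_cnv(0, 100, pid=f"P{i}")], ["T1"]) for i in range(2)]
        assert build_groups(patients, min_size=3) == []
        patients.append(_patient("P3", [_cnv(0, 100, pid="P3")], ["T1"]))
        groups = build_groups(patients, min_size=3)
        assert [g.term for g in groups] == ["T1"] and groups[0].size == 3

    def test_parent_groups_dominate_child_groups(self, small_bundle):
        """Propagation makes parent-term groups at least as large as any child's."""
        patients = small_bundle.patients()
        groups = {g.term: g for g in build_groups(patients, min_size=1)}
        for child, parent in small_bundle.dag.is_a_edges:
            if child in groups and parent in groups:
                assert groups[parent].size >= groups[child].size

    def test_membership_counting_identity(self, small_bundle):
        patients = small_bundle.patients()
        groups = build_groups(patients, min_size=3)
        group_terms = {g.term for g in groups}
        total = sum(g.size for g in groups)
        expected = sum(len(p.propagated_terms & group_terms) for p in patients)
        assert total == expected

    def test_exactly_the_terms_with_enough_carriers(self, small_bundle):
        patients = small_bundle.patients()
        retained, _ = filter_cohort(patients)
        carriers = {}
        for p in retained:
            for t in p.propagated_terms:
                carriers[t] = carriers.get(t, 0) + 1
        expected = {t for t, n in carriers.items() if n >= 3}
        groups = build_groups(retained, min_size=3)
        assert {g.term for g in groups} == expected


def test_propagated_terms_are_closed(small_bundle):
    for p in small_bundle.patients():
        assert p.direct_terms <= p.propagated_terms
        assert propagate_ancestors(small_bundle.dag, p.propagated_terms) == p.propagated_terms
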