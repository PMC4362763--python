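"""Configuration-driven orchestration of the full analysis.

Stages, in order: cohort filtering (de novo CNVs below the size cap) →
patient-phenotype grouping → four enrichment engines (GO-like, KEGG-like,
model-organism knockouts, co-expression clustering) → multi-method
candidate genes → PPI validation → the phenotypic-convergence suite
(per-enrichment Wilcoxon tests, subterm restriction, binomial excess,
pooling by shared annotation) → optional bait-network extension and the
inherited-CNV replication analysis.

Every threshold is config-exposed; results are written as TSV/JSON files
stamped with the config hash and seed, and a run is a pure function of
(inputs, config): the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import candidates as cand_mod
from .candidates import CandidateSet, multi_method_candidates, validate_candidates_ppi
from .cohort import (
    PatientPhenotypeGroup,
    PatientRecord,
    annotate_affected_genes,
    build_groups,
    build_patients,
    filter_cohort,
    merge_cnvrs,
    read_cnv_table,
    read_gene_models_json,
    read_phenotype_table,
)
from .convergence import (
    ConvergenceResult,
    combine_by_annotation,
    contributing_split,
    convergence_test,
    excess_binomial,
    phenotype_frequencies,
    replication_grouping,
    subterm_convergence,
)
from .enrichment import (
    AnnotationCollection,
    EnrichmentResult,
    enrich_group,
    enrich_group_mgi,
    read_gmt,
    read_two_column_map,
)
from .networks import (
    ClusterTestResult,
    GeneNetwork,
    bait_extension_test,
    build_coexpression_network,
    cluster_test,
    read_edge_list,
)
from .ontology import CategoryMap, OntologyDAG, hpo_to_mpo_category, load_category_map, parse_obo

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "summarize", "load_inputs"]


@dataclass
class PipelineConfig:
    """Thresholds and run parameters; defaults follow the study design."""

    max_cnv_len: int = 5_000_000
    min_group_size: int = 3
    alpha: float = 0.05
    rpkm_min: float = 1.0
    expr_low_frac: float = 0.95
    r_min: float = 0.7
    mgi_min_frac: float = 0.01
    min_methods: int = 2
    min_each: int = 10
    n_samples: int = 2_000  # degree-matched sets per cluster test (<= 10,000)
    n_ppi_samples: int = 10_000
    n_rand: int = 500  # CNVR randomisations for the bait test
    seed: int = 0
    run_bait_extension: bool = True
    run_replication: bool = True
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class InputData:
    """Everything the pipeline reads, already parsed."""

    dag: OntologyDAG
    genes: list
    annotations: dict[str, AnnotationCollection]
    category_map: CategoryMap
    control_gains: set[str]
    control_losses: set[str]
    cnvs: list
    phenotypes: dict[str, set[str]]
    expression: "object"  # genes x samples DataFrame, or None
    ppi: GeneNetwork | None


def load_inputs(paths: dict) -> InputData:
    """Parse an input bundle from a {name: path} mapping.

    Expected keys: ontology, genes, cnvs, phenotypes, go, kegg, mgi,
    orthologs, mpo_categories, hpo_categories, control_gains,
    control_losses, expression, ppi (the last six optional).
    """
    import pandas as pd

    dag = parse_obo(paths["ontology"])
    genes = read_gene_models_json(paths["genes"])
    gene_universe = frozenset(g.gene_id for g in genes)
    annotations = {
        "GO": read_gmt(paths["go"], "GO", universe=gene_universe),
        "KEGG": read_gmt(paths["kegg"], "KEGG", universe=gene_universe),
    }
    category_map = CategoryMap({}, {})
    if "mgi" in paths:
        orthologs = read_two_column_map(paths["orthologs"])
        mpo_cats = read_two_column_map(paths["mpo_categories"])
        hpo_cats = read_two_column_map(paths["hpo_categories"])
        category_map = CategoryMap(mpo_to_category=mpo_cats, hpo_to_category=hpo_cats)
        annotations["MGI"] = read_gmt(
            paths["mgi"], "MGI",
            universe=frozenset(orthologs.values()),
            orthologs=orthologs,
            term_categories=mpo_cats,
        )

    def _read_genes(key):
        if key not in paths:
            return set()
        with open(paths[key]) as fh:
            return {line.strip() for line in fh if line.strip()}

    expression = (
        pd.read_csv(paths["expression"], sep="\t", index_col=0)
        if "expression" in paths
        else None
    )
    ppi = read_edge_list(paths["ppi"], name="ppi") if "ppi" in paths else None
    return InputData(
        dag=dag,
        genes=genes,
        annotations=annotations,
        category_map=category_map,
        control_gains=_read_genes("control_gains"),
        control_losses=_read_genes("control_losses"),
        cnvs=read_cnv_table(paths["cnvs"]),
        phenotypes=read_phenotype_table(paths["phenotypes"]),
        expression=expression,
        ppi=ppi,
    )


def inputs_from_bundle(bundle) -> InputData:
    """Adapt a :class:`~phenoconverge.synthdata.SyntheticBundle`."""
    return InputData(
        dag=bundle.dag,
        genes=bundle.genes,
        annotations=bundle.annotations,
        category_map=bundle.category_map,
        control_gains=bundle.control_gains,
        control_losses=bundle.control_losses,
        cnvs=bundle.cnvs,
        phenotypes=bundle.phenotypes,
        expression=bundle.expression,
        ppi=bundle.ppi,
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    retained: list[PatientRecord]
    replication_pool: list[PatientRecord]
    groups: list[PatientPhenotypeGroup]
    enrichments: list[EnrichmentResult]
    cluster_results: dict[str, ClusterTestResult]
    candidate_sets: list[CandidateSet]
    convergence: list[ConvergenceResult]
    subterm: list[ConvergenceResult]
    combined: list[ConvergenceResult]
    excess_p: float
    excess_counts: tuple[int, int]
    replication: list[dict]
    bait: dict | None
    coexpression: GeneNetwork | None

    def patients_by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.retained}


def run_pipeline(inputs: InputData, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute every stage on parsed inputs; deterministic under the seed."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)

    # --- cohort -----------------------------------------------------------
    patients = build_patients(inputs.phenotypes, inputs.cnvs, inputs.dag)
    annotate_affected_genes(
        patients, inputs.genes, inputs.control_gains, inputs.control_losses
    )
    retained, replication_pool = filter_cohort(patients, config.max_cnv_len)
    logger.info(
        "cohort: %d retained, %d replication-pool patients", len(retained), len(replication_pool)
    )
    groups = build_groups(retained, config.min_group_size)
    logger.info("formed %d patient-phenotype groups", len(groups))
    by_id = {p.patient_id: p for p in retained}
    groups_by_term = {g.term: g for g in groups}

    # --- enrichment engines ----------------------------------------------
    enrichments: list[EnrichmentResult] = []
    for group in groups:
        for resource in ("GO", "KEGG"):
            if resource in inputs.annotations:
                enrichments.extend(
                    enrich_group(group, inputs.annotations[resource], config.alpha)
                )
        if "MGI" in inputs.annotations:
            cat = hpo_to_mpo_category(group.term, inputs.category_map)
            enrichments.extend(
                enrich_group_mgi(
                    group,
                    inputs.annotations["MGI"],
                    cat,
                    config.alpha,
                    config.mgi_min_frac,
                )
            )

    # --- co-expression clustering engine ---------------------------------
    coexpr = None
    cluster_results: dict[str, ClusterTestResult] = {}
    if inputs.expression is not None:
        coexpr = build_coexpression_network(
            inputs.expression, config.rpkm_min, config.expr_low_frac, config.r_min
        )
        logger.info(
            "co-expression network: %d nodes, %d edges",
            len(coexpr), coexpr.graph.number_of_edges(),
        )
        for group in groups:
            cluster_results[group.term] = cluster_test(
                coexpr,
                group.gene_set,
                statistic="weight-sum",
                n_samples=config.n_samples,
                rng=np.random.default_rng(rng.integers(2**31)),
            )

    # --- multi-method candidates + PPI validation -------------------------
    enr_by_group: dict[str, list[EnrichmentResult]] = {}
    for e in enrichments:
        enr_by_group.setdefault(e.group_term, []).append(e)
    candidate_sets: list[CandidateSet] = []
    for group in groups:
        cs = multi_method_candidates(
            group.term,
            enr_by_group.get(group.term, []),
            {"coexpression": cluster_results.get(group.term)},
            config.min_methods,
        )
        if cs.genes and inputs.ppi is not None:
            validate_candidates_ppi(
                cs,
                inputs.ppi,
                n_samples=config.n_ppi_samples,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
        candidate_sets.append(cs)

    # --- convergence suite -------------------------------------------------
    freqs = phenotype_frequencies(retained)
    convergence: list[ConvergenceResult] = []
    subterm: list[ConvergenceResult] = []
    sig_enrichments = [e for e in enrichments if e.significant]
    for e in sig_enrichments:
        group = groups_by_term[e.group_term]
        split = contributing_split(group, e, by_id)
        ref = f"{e.resource}:{e.annotation_term}"
        res = convergence_test(group, split, by_id, freqs, ref, config.min_each)
        convergence.append(res)
        if res.significant:
            subterm.append(
                subterm_convergence(group, split, by_id, inputs.dag, ref, config.min_each)
            )
    for term, cres in sorted(cluster_results.items()):
        if cres.untestable or cres.p >= config.alpha:
            continue
        group = groups_by_term[term]
        split = contributing_split(group, cres, by_id)
        res = convergence_test(group, split, by_id, freqs, "coexpression", config.min_each)
        convergence.append(res)
        if res.significant:
            subterm.append(
                subterm_convergence(group, split, by_id, inputs.dag, "coexpression", config.min_each)
            )
    testable = [r for r in convergence if not r.untestable]
    if testable:
        excess_p, k, n = excess_binomial(convergence)
    else:
        excess_p, k, n = float("nan"), 0, 0
    combined = combine_by_annotation(
        sig_enrichments, groups_by_term, by_id, freqs, config.min_each
    )

    # --- replication on inherited CNVs ------------------------------------
    replication: list[dict] = []
    if config.run_replication and replication_pool:
        mgi = inputs.annotations.get("MGI")
        rev_orth = (
            {m: h for h, m in mgi.orthologs.items()} if mgi and mgi.orthologs else {}
        )
        for e in sig_enrichments:
            cand = frozenset(
                rev_orth.get(g, g) for g in e.contributing_genes
            )
            annot = inputs.annotations[e.resource]
            same_annot = annot.term_genes.get(e.annotation_term, frozenset())
            if e.resource == "MGI":
                same_annot = frozenset(rev_orth.get(g, g) for g in same_annot)
            extended = frozenset(same_annot) - cand
            replication.append(
                replication_grouping(
                    replication_pool, e.group_term, cand, extended,
                    reference=f"{e.resource}:{e.annotation_term}",
                    min_each=config.min_each,
                )
                | {"group_term": e.group_term, "reference": f"{e.resource}:{e.annotation_term}"}
            )
        for term, cres in sorted(cluster_results.items()):
            if cres.untestable or cres.p >= config.alpha or coexpr is None:
                continue
            cand = frozenset(cres.contributing_genes)
            neighbours: set[str] = set()
            for g in cand:
                if g in coexpr:
                    neighbours.update(coexpr.graph.adj[g])
            replication.append(
                replication_grouping(
                    replication_pool, term, cand, frozenset(neighbours - cand),
                    reference="coexpression",
                    min_each=config.min_each,
                )
                | {"group_term": term, "reference": "coexpression"}
            )

    # --- bait-network extension --------------------------------------------
    bait_out = None
    if config.run_bait_extension and inputs.ppi is not None and replication_pool:
        validated = [c for c in candidate_sets if c.ppi_significant]
        if validated:
            best = max(validated, key=lambda c: len(c.genes))
            repl_cnvs = [c for p in replication_pool for c in p.cnv_calls]
            cnvrs = merge_cnvrs(repl_cnvs)
            try:
                p, extension, info = bait_extension_test(
                    best.genes & inputs.ppi.nodes,
                    cnvrs,
                    inputs.ppi,
                    inputs.genes,
                    n_rand=config.n_rand,
                    rng=np.random.default_rng(rng.integers(2**31)),
                )
                bait_out = {
                    "group_term": best.group_term,
                    "p": p,
                    "extension_genes": sorted(extension),
                    **info,
                }
            except RuntimeError as exc:
                logger.warning("bait extension skipped: %s", exc)

    return PipelineResult(
        config=config,
        retained=retained,
        replication_pool=replication_pool,
        groups=groups,
        enrichments=enrichments,
        cluster_results=cluster_results,
        candidate_sets=candidate_sets,
        convergence=convergence,
        subterm=subterm,
        combined=combined,
        excess_p=excess_p,
        excess_counts=(k, n),
        replication=replication,
        bait=bait_out,
        coexpression=coexpr,
    )


def summarize(result: PipelineResult) -> dict:
    """Per-stage counts consistent with the stage outputs."""
    sig_by_group: dict[str, set[str]] = {}
    for e in result.enrichments:
        if e.significant:
            sig_by_group.setdefault(e.group_term, set()).add(e.resource)
    for term, c in result.cluster_results.items():
        if not c.untestable and c.p < result.config.alpha:
            sig_by_group.setdefault(term, set()).add("coexpression")
    n_engines = {t: len(v) for t, v in sig_by_group.items()}
    testable = [r for r in result.convergence if not r.untestable]
    return {
        "n_patients_retained": len(result.retained),
        "n_replication_pool": len(result.replication_pool),
        "n_groups": len(result.groups),
        "n_significant_enrichments": sum(1 for e in result.enrichments if e.significant),
        "n_groups_with_assoc": sum(1 for v in n_engines.values() if v >= 1),
        "n_groups_2plus_engines": sum(1 for v in n_engines.values() if v >= 2),
        "n_groups_3plus_engines": sum(1 for v in n_engines.values() if v >= 3),
        "n_groups_4_engines": sum(1 for v in n_engines.values() if v >= 4),
        "n_candidate_sets_nonempty": sum(1 for c in result.candidate_sets if c.genes),
        "n_ppi_validated": sum(1 for c in result.candidate_sets if c.ppi_significant),
        "n_convergence_testable": len(testable),
        "n_convergence_significant": sum(1 for r in testable if r.significant),
        "binomial_excess_p": result.excess_p,
        "binomial_excess_counts": list(result.excess_counts),
        "bait_extension_p": None if result.bait is None else result.bait["p"],
    }


# ---------------------------------------------------------------------------
# writers


def write_outputs(result: PipelineResult, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    stamp = f"# config_hash={result.config.hash()} seed={result.config.seed}\n"
    j = os.path.join

    with open(j(outdir, "enrichments.tsv"), "w") as fh:
        fh.write(stamp)
        fh.write("group_term\tresource\tannotation_term\tk\tn\tK\tN\tfold\tp\tq\t"
                 "significant\tcontributing_genes\n")
        for e in result.enrichments:
            fh.write(
                f"{e.group_term}\t{e.resource}\t{e.annotation_term}\t{e.k}\t{e.n}\t"
                f"{e.K}\t{e.N}\t{e.fold:.6g}\t{e.p:.6g}\t{e.q:.6g}\t{int(e.significant)}\t"
                f"{','.join(sorted(e.contributing_genes))}\n"
            )
    with open(j(outdir, "cluster_tests.tsv"), "w") as fh:
        fh.write(stamp)
        fh.write("group_term\tstatistic\tobserved\tn_samples\tp\tuntestable\tcontributing_genes\n")
        for term in sorted(result.cluster_results):
            c = result.cluster_results[term]
            fh.write(
                f"{term}\t{c.statistic}\t{c.observed:.6g}\t{c.n_samples}\t{c.p:.6g}\t"
                f"{int(c.untestable)}\t{','.join(sorted(c.contributing_genes))}\n"
            )
    with open(j(outdir, "candidates.tsv"), "w") as fh:
        fh.write(stamp)
        fh.write("group_term\tgene\tmethods\tppi_p\n")
        for cs in result.candidate_sets:
            pp = "" if cs.ppi_result is None or cs.ppi_result.untestable else f"{cs.ppi_result.p:.6g}"
            for g in sorted(cs.genes):
                fh.write(f"{cs.group_term}\t{g}\t{','.join(sorted(cs.provenance[g]))}\t{pp}\n")

    def _write_conv(path, rows):
        with open(path, "w") as fh:
            fh.write(stamp)
            fh.write("group_term\treference\tn_contributing\tn_non_contributing\t"
                     "n_groups\tstatistic\tp\tdirection\tuntestable\n")
            for r in rows:
                fh.write(
                    f"{r.group_term}\t{r.reference}\t{len(r.contributing)}\t"
                    f"{len(r.non_contributing)}\t{r.n_groups}\t{r.statistic:.6g}\t"
                    f"{r.p:.6g}\t{r.direction}\t{int(r.untestable)}\n"
                )

    _write_conv(j(outdir, "convergence.tsv"), result.convergence)
    _write_conv(j(outdir, "subterm_convergence.tsv"), result.subterm)
    _write_conv(j(outdir, "combined_convergence.tsv"), result.combined)
    with open(j(outdir, "replication.tsv"), "w") as fh:
        fh.write(stamp)
        fh.write("group_term\treference\tcomparison\tn_candidate\tn_extended\tn_none\t"
                 "p\tdirection\tuntestable\n")
        for rec in result.replication:
            for key in ("candidate_vs_rest", "extended_vs_none"):
                r = rec[key]
                if r is None:
                    continue
                fh.write(
                    f"{rec['group_term']}\t{rec['reference']}\t{key}\t"
                    f"{len(rec['candidate'])}\t{len(rec['extended'])}\t{len(rec['none'])}\t"
                    f"{r.p:.6g}\t{r.direction}\t{int(r.untestable)}\n"
                )
    summary = summarize(result) | {
        "config_hash": result.config.hash(),
        "seed": result.config.seed,
    }
    if result.bait is not None:
        with open(j(outdir, "bait_extension.json"), "w") as fh:
            json.dump(result.bait | {"config_hash": result.config.hash(),
                                     "seed": result.config.seed}, fh, indent=1, sort_keys=True)
    with open(j(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
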