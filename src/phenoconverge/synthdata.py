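"""Seeded synthetic cohorts with planted pathway→phenotype structure.

The generator emulates the study design the pipeline is built for: a
phenotype-ontology DAG (~500 terms), a multi-chromosome genome of
non-overlapping multi-transcript genes, a cohort of patients carrying
small (<5 Mb) de novo CNVs plus a replication pool with inherited CNVs,
annotation resources (GO-like, KEGG-like, and a model-organism knockout
resource with a strict 1:1 ortholog table and overarching categories),
a co-expression matrix with planted correlated modules, and a PPI
network with planted module and bait↔extension edges.

Causal structure is planted per pathway: a gene set, a set of carrier
patients whose de novo CNV covers a pathway gene, a target phenotype
expressed with configurable penetrance, and either (default) a set of
distinct co-morbid phenotypes elevated in carriers — pleiotropy — or
(``subtype_mode``) elevated rates of the target's child terms.  A
machine-readable truth record ties everything together, and every output
is deterministic under (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CnvCall, GeneModel, PatientRecord, build_patients
from .enrichment import AnnotationCollection
from .networks import GeneNetwork
from .ontology import CategoryMap, OntologyDAG, proper_descendants

__all__ = ["PlantedPathway", "SimulationConfig", "TruthRecord", "SyntheticBundle", "simulate"]


@dataclass
class PlantedPathway:
    """One planted pathway: genes, carriers, and their phenotype signature."""

    name: str = "pathway1"
    n_genes: int = 10
    n_carriers: int = 20
    n_replication_carriers: int = 15
    penetrance: float = 0.9
    n_pleiotropy: int = 5
    comorbidity: float = 0.8
    engines: tuple[str, ...] = ("GO", "KEGG", "MGI", "coexpression", "PPI")
    subtype_mode: bool = False  # plant elevated child-term rates instead


@dataclass
class SimulationConfig:
    """Study-scale defaults for every synthetic component."""

    # ontology
    n_terms: int = 500
    max_depth: int = 6
    frac_two_parents: float = 0.1
    # genome
    n_chromosomes: int = 10
    n_genes: int = 2000
    gene_len: tuple[int, int] = (10_000, 200_000)
    gap_len: tuple[int, int] = (10_000, 100_000)
    max_transcripts: int = 3
    max_exons: int = 8
    # cohort
    n_patients: int = 200
    n_replication: int = 200
    frac_second_denovo: float = 0.1
    frac_extra_inherited: float = 0.3
    cnv_len: tuple[int, int] = (50_000, 5_000_000)  # log-uniform, < 5 Mb
    background_terms_mean: float = 6.0
    noncarrier_target_rate: float = 0.08
    min_target_descendants: int = 8
    max_target_descendants: int = 25
    # annotations
    n_go_terms: int = 100
    n_kegg_terms: int = 50
    n_mpo_terms: int = 80
    term_size: tuple[int, int] = (5, 40)
    ortholog_frac: float = 0.8
    n_categories: int = 33
    control_gene_frac: float = 0.05
    # networks
    n_expr_samples: int = 50
    module_r: float = 0.9
    n_bg_modules: int = 150  # small co-expressed background modules
    bg_module_size: tuple[int, int] = (6, 14)  # sizes drawn uniformly
    bg_module_r: float = 0.78
    silent_frac: float = 0.05
    ppi_frac: float = 0.5
    ppi_mean_degree: float = 4.0
    ppi_module_edge_prob: float = 0.8
    n_extension_genes: int = 10
    extension_edge_prob: float = 0.6
    # planted structure
    pathways: tuple[PlantedPathway, ...] = (PlantedPathway(),)

    def validate(self) -> None:
        for p in (self.frac_two_parents, self.ortholog_frac, self.silent_frac,
                  self.ppi_frac, self.ppi_module_edge_prob, self.extension_edge_prob,
                  self.noncarrier_target_rate, self.control_gene_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for pw in self.pathways:
            if not 0 <= pw.penetrance <= 1 or not 0 <= pw.comorbidity <= 1:
                raise ValueError("pathway probabilities must lie in [0, 1]")
        if self.n_terms < self.max_depth:
            raise ValueError("n_terms must be >= max_depth")
        needed = sum(pw.n_carriers for pw in self.pathways)
        if needed > self.n_patients:
            raise ValueError("more planted carriers than patients")


@dataclass
class TruthRecord:
    """Ground truth of everything planted, for end-to-end recovery checks."""

    pathway_genes: dict[str, list[str]] = field(default_factory=dict)
    target_terms: dict[str, str] = field(default_factory=dict)
    pleiotropy_terms: dict[str, list[str]] = field(default_factory=dict)
    carriers: dict[str, list[str]] = field(default_factory=dict)
    replication_carriers: dict[str, list[str]] = field(default_factory=dict)
    planted_annotation_terms: dict[str, dict[str, str]] = field(default_factory=dict)
    extension_genes: dict[str, list[str]] = field(default_factory=dict)
    module_genes: dict[str, list[str]] = field(default_factory=dict)
    ontology_edges: list[list[str]] = field(default_factory=list)
    control_gains: list[str] = field(default_factory=list)
    control_losses: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# ontology


def generate_ontology(config: SimulationConfig, rng: np.random.Generator):
    """Rooted DAG with bounded depth and a fraction of two-parent terms.

    Returns (OntologyDAG, OBO text).  Edges always point to lower-index
    terms, so acyclicity holds by construction; ``max_depth`` of 1 yields
    a star of leaves beneath the root.
    """
    config.validate()
    ids = [f"HP:{i:07d}" for i in range(config.n_terms)]
    level = {ids[0]: 0}
    edges: set[tuple[str, str]] = set()
    for i in range(1, config.n_terms):
        eligible = [t for t in ids[:i] if level[t] < config.max_depth]
        parent = eligible[int(rng.integers(len(eligible)))]
        edges.add((ids[i], parent))
        level[ids[i]] = level[parent] + 1
        if rng.random() < config.frac_two_parents:
            second = [t for t in ids[:i] if level[t] < level[ids[i]] and t != parent]
            if second:
                edges.add((ids[i], second[int(rng.integers(len(second)))]))
    labels = {t: f"synthetic term {t}" for t in ids}
    dag = OntologyDAG(term_ids=set(ids), labels=labels, is_a_edges=edges)
    lines = ["format-version: 1.2", "ontology: synthetic-phenotype", ""]
    parents_of: dict[str, list[str]] = {t: [] for t in ids}
    for c, p in sorted(edges):
        parents_of[c].append(p)
    for t in ids:
        lines.append("[Term]")
        lines.append(f"id: {t}")
        lines.append(f"name: {labels[t]}")
        for p in sorted(parents_of[t]):
            lines.append(f"is_a: {p} ! {labels[p]}")
        lines.append("")
    return dag, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# genome and annotations


def generate_genome(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Non-overlapping multi-transcript genes laid along chromosomes."""
    genes: list[GeneModel] = []
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    gi = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(*config.gap_len))
        for _ in range(per_chrom):
            if gi >= config.n_genes:
                break
            glen = int(rng.integers(*config.gene_len))
            start, end = cursor, cursor + glen
            n_tx = int(rng.integers(1, config.max_transcripts + 1))
            txs = []
            for ti in range(n_tx):
                n_ex = int(rng.integers(2, config.max_exons + 1))
                # 2*n_ex breakpoints -> alternating exon/intron segments
                cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2, replace=False))
                bounds = np.concatenate([[0], cuts, [glen]])
                exons = tuple(
                    (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                    for k in range(n_ex)
                )
                txs.append(exons)
            # first transcript spans the gene ends; keep span invariant exact
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:05d}",
                    chromosome=chrom,
                    gene_start=start,
                    gene_end=end,
                    transcripts=tuple(txs),
                )
            )
            cursor = end + int(rng.integers(*config.gap_len))
            gi += 1
    return genes


def _random_gene_sets(gene_ids, n_terms, size_range, rng) -> list[frozenset[str]]:
    out = []
    for _ in range(n_terms):
        k = int(rng.integers(size_range[0], size_range[1] + 1))
        out.append(frozenset(rng.choice(gene_ids, size=k, replace=False).tolist()))
    return out


def generate_annotations(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: TruthRecord,
    rng: np.random.Generator,
):
    """GO/KEGG/MPO-like resources with planted terms covering the planted
    pathway genes, decoy terms, a 1:1 ortholog map and category maps."""
    gene_ids = np.array([g.gene_id for g in genes])
    annots: dict[str, AnnotationCollection] = {}
    for resource, n_terms in (("GO", config.n_go_terms), ("KEGG", config.n_kegg_terms)):
        term_genes: dict[str, frozenset[str]] = {}
        for i, gs in enumerate(_random_gene_sets(gene_ids, n_terms, config.term_size, rng)):
            term_genes[f"{resource}:decoy{i:04d}"] = gs
        for pw in config.pathways:
            if resource in pw.engines:
                term = f"{resource}:planted_{pw.name}"
                term_genes[term] = frozenset(truth.pathway_genes[pw.name])
                truth.planted_annotation_terms.setdefault(resource, {})[pw.name] = term
        annots[resource] = AnnotationCollection(
            name=resource, term_genes=term_genes, universe=frozenset(gene_ids.tolist())
        )

    # 1:1 orthologs over a fraction of genes, always covering planted genes
    planted = {g for pw in config.pathways for g in truth.pathway_genes[pw.name]}
    n_orth = int(config.ortholog_frac * len(gene_ids))
    pool = [g for g in gene_ids if g not in planted]
    chosen = set(rng.choice(pool, size=max(0, n_orth - len(planted)), replace=False).tolist())
    orth_domain = sorted(planted | chosen)
    orthologs = {g: f"m{g}" for g in orth_domain}
    mouse_ids = np.array(sorted(orthologs.values()))

    categories = [f"CAT{i:02d}" for i in range(config.n_categories)]
    term_genes = {}
    term_categories: dict[str, str] = {}
    for i, gs in enumerate(_random_gene_sets(mouse_ids, config.n_mpo_terms, config.term_size, rng)):
        term = f"MP:decoy{i:04d}"
        term_genes[term] = gs
        term_categories[term] = categories[int(rng.integers(config.n_categories))]
    hpo_to_category: dict[str, str] = {}
    for pi, pw in enumerate(config.pathways):
        if "MGI" in pw.engines:
            term = f"MP:planted_{pw.name}"
            term_genes[term] = frozenset(
                orthologs[g] for g in truth.pathway_genes[pw.name] if g in orthologs
            )
            cat = categories[pi % config.n_categories]
            term_categories[term] = cat
            hpo_to_category[truth.target_terms[pw.name]] = cat
            truth.planted_annotation_terms.setdefault("MGI", {})[pw.name] = term
    annots["MGI"] = AnnotationCollection(
        name="MGI",
        term_genes=term_genes,
        universe=frozenset(mouse_ids.tolist()),
        term_categories=term_categories,
        orthologs=orthologs,
    )
    category_map = CategoryMap(
        mpo_to_category=term_categories, hpo_to_category=hpo_to_category
    )

    # dosage-specific control gene lists, never covering planted genes
    n_ctrl = int(config.control_gene_frac * len(gene_ids))
    ctrl_pool = np.array([g for g in gene_ids if g not in planted])
    gains = sorted(rng.choice(ctrl_pool, size=n_ctrl, replace=False).tolist()) if n_ctrl else []
    losses = sorted(rng.choice(ctrl_pool, size=n_ctrl, replace=False).tolist()) if n_ctrl else []
    truth.control_gains = gains
    truth.control_losses = losses
    return annots, category_map, set(gains), set(losses)


# ---------------------------------------------------------------------------
# cohort


def _place_cnv_over_gene(
    gene: GeneModel, config: SimulationConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """A CNV interval containing a gene, log-uniform length below the cap."""
    lo = max(gene.gene_end - gene.gene_start + 1, config.cnv_len[0])
    length = int(np.exp(rng.uniform(np.log(lo), np.log(config.cnv_len[1]))))
    length = min(length, config.cnv_len[1] - 1)
    slack = length - (gene.gene_end - gene.gene_start)
    pad_left = int(rng.integers(0, slack + 1))
    start = max(0, gene.gene_start - pad_left)
    return start, start + length


def _random_cnv(
    genes_by_chrom: dict[str, list[GeneModel]],
    config: SimulationConfig,
    rng: np.random.Generator,
    forbidden: set[str],
) -> tuple[str, int, int]:
    """A CNV at a random genomic position avoiding planted pathway genes."""
    chroms = sorted(genes_by_chrom)
    for _ in range(100):
        chrom = chroms[int(rng.integers(len(chroms)))]
        span_end = max(g.gene_end for g in genes_by_chrom[chrom])
        length = int(
            np.exp(rng.uniform(np.log(config.cnv_len[0]), np.log(config.cnv_len[1])))
        )
        start = int(rng.integers(0, max(1, span_end - length)))
        hit = {
            g.gene_id
            for g in genes_by_chrom[chrom]
            if g.gene_start < start + length and start < g.gene_end
        }
        if not hit & forbidden:
            return chrom, start, start + length
    raise RuntimeError("could not place a CNV avoiding planted genes")


def _draw_phenotypes(
    terms: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> set[str]:
    n_bg = 1 + int(rng.poisson(config.background_terms_mean))
    n_bg = min(n_bg, len(terms) - 1)
    return set(rng.choice(terms[1:], size=n_bg, replace=False).tolist())


def generate_cohort(
    config: SimulationConfig,
    genes: list[GeneModel],
    dag: OntologyDAG,
    truth: TruthRecord,
    rng: np.random.Generator,
) -> tuple[list[CnvCall], dict[str, set[str]]]:
    """De novo cohort plus replication pool: CNV calls and direct terms.

    Carriers get a de novo CNV covering a planted pathway gene, express
    the target phenotype with the configured penetrance, and draw each
    co-morbid phenotype with the co-morbidity frequency (or, in subtype
    mode, elevated child terms of the target).  Everyone draws background
    phenotypes; replication-pool patients carry only inherited CNVs,
    with the pathway signature planted over inherited CNVs in the
    replication carriers.
    """
    terms = sorted(dag.term_ids)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    genes_by_id = {g.gene_id: g for g in genes}
    for g in genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)
    planted_gene_ids = {g for pw in config.pathways for g in truth.pathway_genes[pw.name]}

    patient_ids = [f"P{i:04d}" for i in range(config.n_patients)]
    repl_ids = [f"R{i:04d}" for i in range(config.n_replication)]
    order = rng.permutation(config.n_patients)
    cursor = 0
    carrier_of: dict[str, PlantedPathway] = {}
    for pw in config.pathways:
        ids = [patient_ids[order[cursor + j]] for j in range(pw.n_carriers)]
        cursor += pw.n_carriers
        truth.carriers[pw.name] = sorted(ids)
        for pid in ids:
            carrier_of[pid] = pw
    rorder = rng.permutation(config.n_replication)
    rcursor = 0
    repl_carrier_of: dict[str, PlantedPathway] = {}
    for pw in config.pathways:
        ids = [repl_ids[rorder[rcursor + j]] for j in range(pw.n_replication_carriers)]
        rcursor += pw.n_replication_carriers
        truth.replication_carriers[pw.name] = sorted(ids)
        for pid in ids:
            repl_carrier_of[pid] = pw

    calls: list[CnvCall] = []
    counter = 0

    def add_call(chrom, start, end, inh, pid):
        nonlocal counter
        dosage = "gain" if rng.random() < 0.4 else "loss"
        calls.append(CnvCall(chrom, start, end, dosage, inh, pid, f"cnv{counter:05d}"))
        counter += 1

    ext_pool = {g for gl in truth.extension_genes.values() for g in gl}
    for pid in patient_ids:
        pw = carrier_of.get(pid)
        if pw is not None:
            gset = truth.pathway_genes[pw.name]
            gene = genes_by_id[gset[int(rng.integers(len(gset)))]]
            start, end = _place_cnv_over_gene(gene, config, rng)
            add_call(gene.chromosome, start, end, "de_novo", pid)
        else:
            chrom, s, e = _random_cnv(genes_by_chrom, config, rng, planted_gene_ids | ext_pool)
            add_call(chrom, s, e, "de_novo", pid)
        if rng.random() < config.frac_second_denovo:
            chrom, s, e = _random_cnv(genes_by_chrom, config, rng, planted_gene_ids | ext_pool)
            add_call(chrom, s, e, "de_novo", pid)
        if rng.random() < config.frac_extra_inherited:
            chrom, s, e = _random_cnv(genes_by_chrom, config, rng, planted_gene_ids | ext_pool)
            add_call(chrom, s, e, "inherited", pid)

    for pid in repl_ids:
        pw = repl_carrier_of.get(pid)
        if pw is not None:
            choices = list(truth.pathway_genes[pw.name])
            if "PPI" in pw.engines and truth.extension_genes.get(pw.name):
                # half the replication carriers hit extension genes instead
                if rng.random() < 0.5:
                    choices = list(truth.extension_genes[pw.name])
            gene = genes_by_id[choices[int(rng.integers(len(choices)))]]
            start, end = _place_cnv_over_gene(gene, config, rng)
            add_call(gene.chromosome, start, end, "inherited", pid)
        else:
            chrom, s, e = _random_cnv(genes_by_chrom, config, rng, planted_gene_ids | ext_pool)
            add_call(chrom, s, e, "inherited", pid)

    phenotypes: dict[str, set[str]] = {}
    for pid in patient_ids + repl_ids:
        direct = _draw_phenotypes(terms, config, rng)
        pw = carrier_of.get(pid) or repl_carrier_of.get(pid)
        if pw is not None:
            target = truth.target_terms[pw.name]
            if rng.random() < pw.penetrance:
                direct.add(target)
            for t in truth.pleiotropy_terms[pw.name]:
                if rng.random() < pw.comorbidity:
                    direct.add(t)
        else:
            for pw2 in config.pathways:
                if rng.random() < config.noncarrier_target_rate:
                    direct.add(truth.target_terms[pw2.name])
        phenotypes[pid] = direct
    return calls, phenotypes


def choose_planted_structure(
    config: SimulationConfig,
    dag: OntologyDAG,
    genes: list[GeneModel],
    rng: np.random.Generator,
    truth: TruthRecord,
) -> None:
    """Pick pathway genes, target terms and pleiotropy/subtype terms."""
    gene_ids = [g.gene_id for g in genes]
    used: set[str] = set()
    terms = sorted(dag.term_ids)
    eligible_targets = [
        t for t in terms[1:]
        if config.min_target_descendants
        <= len(proper_descendants(dag, t))
        <= config.max_target_descendants
    ]
    if len(eligible_targets) < len(config.pathways):
        raise ValueError("ontology too shallow: not enough targets with descendants")
    used_terms: set[str] = set()
    for pw in config.pathways:
        pool = [g for g in gene_ids if g not in used]
        chosen = rng.choice(pool, size=pw.n_genes, replace=False).tolist()
        used.update(chosen)
        truth.pathway_genes[pw.name] = sorted(chosen)
        tpool = [t for t in eligible_targets if t not in used_terms]
        target = tpool[int(rng.integers(len(tpool)))]
        used_terms.add(target)
        truth.target_terms[pw.name] = target
        branch = proper_descendants(dag, target) | {target}
        if pw.subtype_mode:
            ppool = sorted(proper_descendants(dag, target))
        else:
            ppool = [t for t in terms[1:] if t not in branch and t not in used_terms]
        pleio = rng.choice(ppool, size=min(pw.n_pleiotropy, len(ppool)), replace=False)
        truth.pleiotropy_terms[pw.name] = sorted(pleio.tolist())
        used_terms.update(truth.pleiotropy_terms[pw.name])
        if "coexpression" in pw.engines:
            truth.module_genes[pw.name] = truth.pathway_genes[pw.name]
        if "PPI" in pw.engines and config.n_extension_genes:
            pool = [g for g in gene_ids if g not in used]
            ext = rng.choice(pool, size=config.n_extension_genes, replace=False).tolist()
            used.update(ext)
            truth.extension_genes[pw.name] = sorted(ext)


# ---------------------------------------------------------------------------
# networks


def generate_networks(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: TruthRecord,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GeneNetwork]:
    """Expression matrix with latent-factor modules, and a PPI graph.

    Module genes load on a shared latent factor with loading sqrt(r), so
    their pairwise Pearson correlation concentrates around the target r;
    background genes are independent.  The PPI graph is a Chung-Lu
    (expected-degree) random graph over a gene subset, plus planted edges
    among module genes and between bait (pathway) and extension genes.
    """
    gene_ids = [g.gene_id for g in genes]
    n, m = len(gene_ids), config.n_expr_samples
    expr = 5.0 + rng.normal(size=(n, m))
    idx = {g: i for i, g in enumerate(gene_ids)}
    a = math.sqrt(config.module_r)
    for name, module in truth.module_genes.items():
        factor = rng.normal(size=m)
        for g in module:
            expr[idx[g]] = 5.0 + a * factor + math.sqrt(1 - a * a) * rng.normal(size=m)
    # small background modules so the thresholded network has realistic
    # structure (nodes and degrees) away from the planted modules
    module_all = {g for gl in truth.module_genes.values() for g in gl}
    bg_pool = [g for g in gene_ids if g not in module_all]
    a_bg = math.sqrt(config.bg_module_r)
    sizes = rng.integers(config.bg_module_size[0], config.bg_module_size[1] + 1,
                         size=config.n_bg_modules)
    n_bg_genes = min(int(sizes.sum()), len(bg_pool))
    bg_members = rng.choice(bg_pool, size=n_bg_genes, replace=False)
    pos = 0
    for size in sizes:
        chunk = bg_members[pos : pos + int(size)]
        pos += int(size)
        if len(chunk) < 2:
            break
        factor = rng.normal(size=m)
        for g in chunk:
            expr[idx[g]] = 5.0 + a_bg * factor + math.sqrt(1 - a_bg * a_bg) * rng.normal(size=m)
    n_silent = int(config.silent_frac * n)
    in_module = module_all | set(bg_members.tolist())
    silent_pool = [g for g in gene_ids if g not in in_module]
    silent = rng.choice(silent_pool, size=min(n_silent, len(silent_pool)), replace=False) if n_silent else []
    for g in silent:
        expr[idx[g]] = rng.uniform(0.0, 0.5, size=m)
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=[f"S{j:03d}" for j in range(m)])

    # PPI: ensure planted pathway (bait) and extension genes are nodes
    forced = {g for pw in config.pathways if "PPI" in pw.engines
              for g in truth.pathway_genes.get(pw.name, [])}
    forced |= {g for gl in truth.extension_genes.values() for g in gl}
    n_nodes = max(int(config.ppi_frac * n), len(forced))
    others = [g for g in gene_ids if g not in forced]
    extra = rng.choice(others, size=n_nodes - len(forced), replace=False).tolist()
    nodes = sorted(forced | set(extra))
    w = rng.exponential(config.ppi_mean_degree, size=len(nodes))
    g0 = nx.expected_degree_graph(w, seed=int(rng.integers(2**31)), selfloops=False)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for i, j in g0.edges:
        graph.add_edge(nodes[i], nodes[j], weight=1.0)
    for pw in config.pathways:
        if "PPI" not in pw.engines:
            continue
        bait = truth.pathway_genes.get(pw.name, [])
        for i in range(len(bait)):
            for j in range(i + 1, len(bait)):
                if rng.random() < config.ppi_module_edge_prob:
                    graph.add_edge(bait[i], bait[j], weight=1.0)
        for e in truth.extension_genes.get(pw.name, []):
            for b in bait:
                if rng.random() < config.extension_edge_prob:
                    graph.add_edge(e, b, weight=1.0)
    return expr_df, GeneNetwork(graph=graph, name="ppi")


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SyntheticBundle:
    """In-memory simulation output plus writers for every pipeline format."""

    config: SimulationConfig
    seed: int
    dag: OntologyDAG
    obo_text: str
    genes: list[GeneModel]
    annotations: dict[str, AnnotationCollection]
    category_map: CategoryMap
    control_gains: set[str]
    control_losses: set[str]
    cnvs: list[CnvCall]
    phenotypes: dict[str, set[str]]
    expression: pd.DataFrame
    ppi: GeneNetwork
    truth: TruthRecord

    def patients(self) -> list[PatientRecord]:
        return build_patients(self.phenotypes, self.cnvs, self.dag)

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        j = os.path.join
        with open(j(outdir, "ontology.obo"), "w") as fh:
            fh.write(self.obo_text)
        with open(j(outdir, "genes.json"), "w") as fh:
            json.dump(
                [
                    {
                        "gene_id": g.gene_id,
                        "chromosome": g.chromosome,
                        "start": g.gene_start,
                        "end": g.gene_end,
                        "transcripts": [[list(e) for e in tx] for tx in g.transcripts],
                    }
                    for g in self.genes
                ],
                fh,
            )
        with open(j(outdir, "cnvs.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tdosage\tinheritance\tpatient_id\tcnv_id\n")
            for c in self.cnvs:
                fh.write(
                    f"{c.chromosome}\t{c.start}\t{c.end}\t{c.dosage}\t"
                    f"{c.inheritance}\t{c.patient_id}\t{c.cnv_id}\n"
                )
        with open(j(outdir, "phenotypes.tsv"), "w") as fh:
            fh.write("patient_id\tterm_id\n")
            for pid in sorted(self.phenotypes):
                for t in sorted(self.phenotypes[pid]):
                    fh.write(f"{pid}\t{t}\n")
        for name, annot in self.annotations.items():
            with open(j(outdir, f"{name.lower()}.gmt"), "w") as fh:
                for term in sorted(annot.term_genes):
                    genes = "\t".join(sorted(annot.term_genes[term]))
                    fh.write(f"{term}\tsynthetic\t{genes}\n")
        mgi = self.annotations["MGI"]
        with open(j(outdir, "orthologs.tsv"), "w") as fh:
            for h, mse in sorted(mgi.orthologs.items()):
                fh.write(f"{h}\t{mse}\n")
        with open(j(outdir, "mpo_categories.tsv"), "w") as fh:
            for t, c in sorted(self.category_map.mpo_to_category.items()):
                fh.write(f"{t}\t{c}\n")
        with open(j(outdir, "hpo_categories.tsv"), "w") as fh:
            for t, c in sorted(self.category_map.hpo_to_category.items()):
                fh.write(f"{t}\t{c}\n")
        with open(j(outdir, "control_gains.txt"), "w") as fh:
            fh.write("\n".join(sorted(self.control_gains)) + "\n")
        with open(j(outdir, "control_losses.txt"), "w") as fh:
            fh.write("\n".join(sorted(self.control_losses)) + "\n")
        self.expression.round(6).to_csv(j(outdir, "expression.tsv"), sep="\t")
        with open(j(outdir, "ppi.tsv"), "w") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.ppi.graph.edges):
                fh.write(f"{a}\t{b}\t1.0\n")
        with open(j(outdir, "truth.json"), "w") as fh:
            fh.write(self.truth.to_json())


def simulate(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Run the whole generator deterministically under (config, seed)."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    truth = TruthRecord()
    dag, obo_text = generate_ontology(config, rng)
    truth.ontology_edges = sorted([list(e) for e in dag.is_a_edges])
    genes = generate_genome(config, rng)
    choose_planted_structure(config, dag, genes, rng, truth)
    annotations, category_map, gains, losses = generate_annotations(config, genes, truth, rng)
    expression, ppi = generate_networks(config, genes, truth, rng)
    cnvs, phenotypes = generate_cohort(config, genes, dag, truth, rng)
    return SyntheticBundle(
        config=config,
        seed=seed,
        dag=dag,
        obo_text=obo_text,
        genes=genes,
        annotations=annotations,
        category_map=category_map,
        control_gains=gains,
        control_losses=losses,
        cnvs=cnvs,
        phenotypes=phenotypes,
        expression=expression,
        ppi=ppi,
        truth=truth,
    )
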