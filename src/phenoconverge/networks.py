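"""Gene networks: co-expression construction and permutation clustering tests.

A co-expression network is built from an expression matrix by thresholding
pairwise Pearson correlation (r >= 0.7 by default; positive correlations
only), after removing genes that are essentially unexpressed.  A protein-
protein interaction (PPI) network is the same container with unit weights.

Whether a gene set "clusters" in a network is judged against a null of
random gene sets matched in size and node-degree distribution: the observed
statistic (sum of edge weights, or edge count) over the induced subgraph is
compared to up to 10,000 degree-matched resamples, giving an empirical
p-value with the +1/+1 estimator (never exactly zero).

The bait-extension test asks whether genes hit by a set of CNV regions in
an independent cohort interact with a fixed "bait" subnetwork more often
than genes hit by randomised region sets matched in the number of
contiguous in-network genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CnvRegion, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "ClusterTestResult",
    "build_coexpression_network",
    "degree_matched_samples",
    "cluster_test",
    "bait_extension_test",
    "read_edge_list",
]


@dataclass
class GeneNetwork:
    """Undirected weighted gene graph (no self-edges)."""

    graph: nx.Graph
    name: str = "network"

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], name: str = "network"
    ) -> "GeneNetwork":
        g = nx.Graph()
        for a, b, w in edges:
            if a == b:
                continue
            g.add_edge(a, b, weight=float(w))
        return cls(graph=g, name=name)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def induced_statistic(self, nodes: Iterable[str], statistic: str) -> float:
        """Sum of weights ("weight-sum") or edge count ("edge-count") of the
        subgraph induced by ``nodes`` (restricted to in-network nodes)."""
        adj = self.graph.adj
        nodeset = {n for n in nodes if n in adj}
        total = 0.0
        for n in nodeset:
            for m, data in adj[n].items():
                if m in nodeset and m > n:
                    total += data["weight"] if statistic == "weight-sum" else 1.0
        return total


@dataclass
class ClusterTestResult:
    test_genes: frozenset[str]  # in-network subset actually tested
    statistic: str
    observed: float
    n_samples: int
    p: float
    contributing_genes: frozenset[str]
    untestable: bool = False
    n_dropped: int = 0  # test genes absent from the network


def build_coexpression_network(
    expr: pd.DataFrame,
    rpkm_min: float = 1.0,
    frac: float = 0.95,
    r_min: float = 0.7,
    name: str = "coexpression",
) -> GeneNetwork:
    """Threshold a genes × samples expression matrix into a weighted network.

    Genes below ``rpkm_min`` in more than ``frac`` of samples are dropped,
    as are zero-variance genes; an edge joins two genes when their Pearson
    correlation r >= ``r_min`` (signed, not absolute), weighted by r.
    Isolated genes are not part of the node set.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    mat = expr.to_numpy(dtype=float)
    low = (mat < rpkm_min).mean(axis=1) > frac
    keep = ~low
    const = mat.std(axis=1) == 0
    if (keep & const).any():
        logger.warning("%d zero-variance genes excluded", int((keep & const).sum()))
        keep &= ~const
    genes = expr.index.to_numpy()[keep]
    sub = mat[keep]
    if len(genes) < 2:
        return GeneNetwork(nx.Graph(), name=name)
    r = np.corrcoef(sub)
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = r[iu, ju] >= r_min
    edges = zip(genes[iu[mask]], genes[ju[mask]], r[iu, ju][mask])
    return GeneNetwork.from_edges(edges, name=name)


def _sample_class_indices(
    cls: np.ndarray, count: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_samples, count) draws without replacement within each row.

    Sparse classes use rejection of rows with duplicates (rare when
    count << class size); dense classes use row-wise permutations.
    """
    if count == len(cls):
        return np.broadcast_to(cls, (n_samples, count)).copy()
    # rejection is only viable when row collisions are rare (birthday bound)
    if count * count > len(cls):
        perms = rng.permuted(
            np.broadcast_to(np.arange(len(cls)), (n_samples, len(cls))).copy(), axis=1
        )
        return cls[perms[:, :count]]
    out = rng.choice(cls, size=(n_samples, count), replace=True)
    if count > 1:
        while True:
            srt = np.sort(out, axis=1)
            bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
            if not bad.any():
                break
            out[bad] = rng.choice(cls, size=(int(bad.sum()), count), replace=True)
    return out


def _degree_matched_matrix(
    net: GeneNetwork,
    seeds: Sequence[str],
    n_samples: int,
    rng: np.random.Generator,
    node_index: dict[str, int],
) -> np.ndarray:
    """(n_samples, |seeds|) node-index matrix of degree-matched null sets.

    Every seed gene belongs to its own degree class, so exact-degree
    matching is always feasible; classes are disjoint, so rows have no
    duplicates across classes.  A log2-binned nearest-degree fallback
    covers restricted sampling pools.
    """
    by_degree: dict[int, list[int]] = {}
    for node in net.graph.nodes:
        by_degree.setdefault(net.degree(node), []).append(node_index[node])
    by_degree_arr = {d: np.array(sorted(v)) for d, v in by_degree.items()}
    need: dict[int, int] = {}
    for g in seeds:
        d = net.degree(g)
        need[d] = need.get(d, 0) + 1
    cols = []
    for d in sorted(need):
        count = need[d]
        cls = by_degree_arr[d]
        if count > len(cls):  # only reachable with a restricted pool
            logger.warning("degree class %d exhausted; log2-bin fallback", d)
            target = np.floor(np.log2(max(d, 1)))
            cls = np.concatenate(
                [v for dd, v in by_degree_arr.items() if np.floor(np.log2(max(dd, 1))) == target]
            )
        cols.append(_sample_class_indices(cls, count, n_samples, rng))
    return np.concatenate(cols, axis=1)


def degree_matched_samples(
    net: GeneNetwork,
    seed_genes: Sequence[str],
    n_max: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> list[set[str]]:
    """Random gene sets matched in size and degree distribution to the seed.

    For each seed gene one gene of identical degree is drawn (the seed's
    own degree class always contains it, so exact matching is feasible);
    sampling within one set is without replacement, while duplicate sets
    may recur across draws.  Up to ``n_max`` sets are returned.
    """
    rng = np.random.default_rng(rng)
    seeds = list(dict.fromkeys(seed_genes))
    missing = [g for g in seeds if g not in net]
    if missing:
        raise ValueError(f"seed genes not in network: {missing[:5]}")
    if len(seeds) > len(net):
        raise ValueError("seed set larger than network")
    nodes = sorted(net.graph.nodes)
    node_index = {g: i for i, g in enumerate(nodes)}
    mat = _degree_matched_matrix(net, seeds, n_max, rng, node_index)
    node_arr = np.array(nodes)
    return [set(node_arr[row].tolist()) for row in mat]


def cluster_test(
    net: GeneNetwork,
    test_genes: Iterable[str],
    statistic: str = "weight-sum",
    n_samples: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ClusterTestResult:
    """Empirical test of whether ``test_genes`` cluster in the network.

    The observed statistic over the induced subgraph is compared to
    degree-matched null samples; p = (1 + #{null >= observed}) / (1 + n).
    Test genes absent from the network are dropped (count recorded); with
    fewer than two in-network genes the result is flagged untestable.
    """
    if statistic not in ("weight-sum", "edge-count"):
        raise ValueError(f"unknown statistic {statistic!r}")
    test = sorted(set(test_genes))
    in_net = [g for g in test if g in net]
    dropped = len(test) - len(in_net)
    if dropped:
        logger.info("cluster_test: %d test genes not in network", dropped)
    if len(in_net) < 2:
        return ClusterTestResult(
            test_genes=frozenset(in_net),
            statistic=statistic,
            observed=0.0,
            n_samples=0,
            p=1.0,
            contributing_genes=frozenset(),
            untestable=True,
            n_dropped=dropped,
        )
    observed = net.induced_statistic(in_net, statistic)
    rng = np.random.default_rng(rng)
    nodes = sorted(net.graph.nodes)
    node_index = {g: i for i, g in enumerate(nodes)}
    mat = _degree_matched_matrix(net, in_net, n_samples, rng, node_index)
    adj = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight="weight", format="csr")
    if statistic == "edge-count":
        adj = adj.copy()
        adj.data = np.ones_like(adj.data)
    # null statistic per sample: x^T A x / 2 over the membership indicator
    from scipy import sparse

    n_null, k = mat.shape
    rows = np.repeat(np.arange(n_null), k)
    x = sparse.csr_array(
        (np.ones(n_null * k), (rows, mat.ravel())), shape=(n_null, adj.shape[0])
    )
    null_stats = np.asarray((x @ adj).multiply(x).sum(axis=1)).ravel() / 2.0
    exceed = int((null_stats >= observed - 1e-9).sum())
    p = (1 + exceed) / (1 + n_null)
    in_set = set(in_net)
    adj = net.graph.adj
    contributing = frozenset(
        g for g in in_net if any(m in in_set for m in adj[g])
    )
    return ClusterTestResult(
        test_genes=frozenset(in_net),
        statistic=statistic,
        observed=observed,
        n_samples=n_null,
        p=p,
        contributing_genes=contributing,
        n_dropped=dropped,
    )


def _region_genes(region: CnvRegion, genes: Sequence[GeneModel]) -> set[str]:
    """Genes overlapping a region by >= 1 bp (region hit, not the stricter
    exon-aware patient-CNV rule; regions are merged multi-patient spans)."""
    return {
        g.gene_id
        for g in genes
        if g.chromosome == region.chromosome
        and g.gene_start < region.end
        and region.start < g.gene_end
    }


def bait_extension_test(
    bait_genes: Iterable[str],
    cnvrs: Sequence[CnvRegion],
    ppi: GeneNetwork,
    genes: Sequence[GeneModel],
    n_rand: int = 500,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, set[str], dict]:
    """Test whether CNVR-hit genes interact with a bait subnetwork.

    CNVRs containing bait genes are dropped, as are CNVRs hitting no
    in-network gene (both counts reported).  The observed statistic is the
    number of PPI edges between the bait set and the union of in-network
    genes hit by the remaining CNVRs.  Each of ``n_rand`` randomisations
    replaces every CNVR by a random run of consecutive genes (genomic
    order) containing the same number of in-network genes and no bait
    gene; runs are anchored on in-network genes, with the chromosome
    chosen proportionally to its count of feasible anchors.

    Returns (empirical p, extension gene set, info dict).
    """
    rng = np.random.default_rng(rng)
    bait = set(bait_genes)
    adj = ppi.graph.adj
    # genomic order per chromosome
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chromosome, g.gene_start)):
        by_chrom.setdefault(g.chromosome, []).append(g)
    ppi_by_chrom = {
        c: [g.gene_id for g in gl if g.gene_id in ppi] for c, gl in by_chrom.items()
    }

    kept: list[tuple[CnvRegion, int]] = []
    n_bait_drop = n_empty_drop = 0
    hit_union: set[str] = set()
    for region in cnvrs:
        rg = _region_genes(region, by_chrom.get(region.chromosome, []))
        if rg & bait:
            n_bait_drop += 1
            continue
        in_net = rg & ppi.nodes
        if not in_net:
            n_empty_drop += 1
            continue
        kept.append((region, len(in_net)))
        hit_union |= in_net
    logger.info(
        "bait extension: %d CNVRs dropped (bait overlap), %d dropped (no in-network genes), %d kept",
        n_bait_drop, n_empty_drop, len(kept),
    )

    def bait_edges(target: set[str]) -> int:
        return sum(1 for b in bait if b in adj for m in adj[b] if m in target)

    observed = bait_edges(hit_union - bait)
    extension = {g for g in hit_union - bait if g in adj and any(m in bait for m in adj[g])}
    info = {
        "observed_edges": observed,
        "n_cnvrs_tested": len(kept),
        "n_dropped_bait_overlap": n_bait_drop,
        "n_dropped_no_ppi_genes": n_empty_drop,
        "n_hit_genes": len(hit_union),
    }
    if not kept or observed == 0 and not any(b in adj and len(adj[b]) for b in bait):
        return 1.0, extension, info

    # feasible run anchors per (chromosome, m): a run is the span of m
    # consecutive in-network genes (interleaved non-network genes included)
    # and must not contain a bait gene, in- or out-of-network
    chrom_ids = {c: [g.gene_id for g in gl] for c, gl in by_chrom.items()}
    ppi_pos = {
        c: [i for i, gid in enumerate(ids) if gid in ppi.graph]
        for c, ids in chrom_ids.items()
    }
    bait_prefix = {
        c: np.cumsum([0] + [1 if gid in bait else 0 for gid in ids])
        for c, ids in chrom_ids.items()
    }
    anchor_cache: dict[int, tuple[list[str], list[np.ndarray], np.ndarray]] = {}

    def anchors_for(m: int):
        if m not in anchor_cache:
            chroms, anchor_lists = [], []
            for c in sorted(ppi_pos):
                pos = ppi_pos[c]
                pref = bait_prefix[c]
                ok = [
                    j
                    for j in range(len(pos) - m + 1)
                    if pref[pos[j + m - 1] + 1] - pref[pos[j]] == 0
                ]
                if ok:
                    chroms.append(c)
                    anchor_lists.append(np.array(ok))
            counts = np.array([len(a) for a in anchor_lists], dtype=float)
            anchor_cache[m] = (chroms, anchor_lists, counts)
        return anchor_cache[m]

    def draw_run(m: int) -> list[str]:
        chroms, anchor_lists, counts = anchors_for(m)
        if not chroms:
            raise RuntimeError(
                f"no feasible matched run for a CNVR with {m} in-network genes"
            )
        ci = int(rng.choice(len(chroms), p=counts / counts.sum()))
        j = int(anchor_lists[ci][int(rng.integers(len(anchor_lists[ci])))])
        pos = ppi_pos[chroms[ci]]
        ids = chrom_ids[chroms[ci]]
        return [ids[p_] for p_ in pos[j : j + m]]

    exceed = 0
    for _ in range(n_rand):
        null_union: set[str] = set()
        for _region, m in kept:
            null_union.update(draw_run(m))
        if bait_edges(null_union - bait) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_rand)
    return p, extension, info


def read_edge_list(path, name: str = "network", default_weight: float = 1.0) -> GeneNetwork:
    """Edge-list TSV: gene_a, gene_b[, weight]; weight defaults to 1 (PPI)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            parts = line.split("\t")
            w = float(parts[2]) if len(parts) > 2 else default_weight
            edges.append((parts[0], parts[1], w))
    return GeneNetwork.from_edges(edges, name=name)
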