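"""Cohort assembly: CNV calls, gene overlap, control filtering, grouping.

The analysis cohort is restricted to patients carrying likely-causative
de novo copy-number variants shorter than a size cap (default 5 Mb; very
large events disrupt too many genes to resolve a specific pathway).
CNVs are mapped to genes with an exon-aware rule that requires either
full containment of the gene or disruption of at least one exon in every
transcript, genes recurrently copy-changed in control individuals are
removed in a dosage-matched way, and patients are grouped by each
propagated phenotype term they share.

Coordinates are 0-based half-open throughout (BED convention); readers
of 1-based inclusive inputs convert at the boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .ontology import OntologyDAG, propagate_ancestors

logger = logging.getLogger(__name__)

__all__ = [
    "CnvCall",
    "GeneModel",
    "PatientRecord",
    "CnvRegion",
    "PatientPhenotypeGroup",
    "filter_cohort",
    "genes_affected",
    "filter_control_genes",
    "build_groups",
    "merge_cnvrs",
    "read_cnv_table",
    "read_phenotype_table",
    "read_gene_models_json",
    "read_gene_models_gtf",
]

MAX_CNV_LEN = 5_000_000  # keep iff length < 5 Mb, strictly


@dataclass(frozen=True)
class CnvCall:
    """A copy-number call on one chromosome, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    dosage: str  # "gain" | "loss"
    inheritance: str  # "de_novo" | "inherited" | "unknown"
    patient_id: str
    cnv_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"CNV {self.cnv_id or ''} has start >= end")
        if self.dosage not in ("gain", "loss"):
            raise ValueError(f"dosage must be gain|loss, got {self.dosage!r}")
        if self.inheritance not in ("de_novo", "inherited", "unknown"):
            raise ValueError(f"bad inheritance {self.inheritance!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts, each a tuple of exon intervals.

    ``gene_start``/``gene_end`` span all transcripts; all intervals are
    0-based half-open on one chromosome.
    """

    gene_id: str
    chromosome: str
    gene_start: int
    gene_end: int
    transcripts: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for tx in self.transcripts:
            for s, e in tx:
                if not (self.gene_start <= s < e <= self.gene_end):
                    raise ValueError(
                        f"gene {self.gene_id}: exon [{s},{e}) outside gene span"
                    )


@dataclass
class PatientRecord:
    patient_id: str
    direct_terms: set[str]
    propagated_terms: set[str]
    cnv_calls: list[CnvCall]
    affected_genes: dict[str, set[str]] = field(default_factory=dict)  # cnv_id -> genes

    def de_novo_calls(self) -> list[CnvCall]:
        return [c for c in self.cnv_calls if c.inheritance == "de_novo"]

    def de_novo_gene_set(self) -> set[str]:
        """Union of filtered genes over this patient's de novo CNVs."""
        out: set[str] = set()
        for c in self.de_novo_calls():
            out |= self.affected_genes.get(c.cnv_id, set())
        return out

    def all_cnv_gene_set(self) -> set[str]:
        out: set[str] = set()
        for c in self.cnv_calls:
            out |= self.affected_genes.get(c.cnv_id, set())
        return out


@dataclass
class CnvRegion:
    """Union span of a connected component of overlapping/bookended CNVs."""

    chromosome: str
    start: int
    end: int
    member_cnv_ids: frozenset[str]
    patient_ids: frozenset[str]


@dataclass
class PatientPhenotypeGroup:
    """All retained patients whose propagated terms include ``term``."""

    term: str
    member_ids: frozenset[str]
    gene_set: frozenset[str]  # pooled filtered de novo CNV genes

    @property
    def size(self) -> int:
        return len(self.member_ids)


def filter_cohort(
    patients: Sequence[PatientRecord], max_cnv_len: int = MAX_CNV_LEN
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Split patients into the analysis cohort and the replication pool.

    Retained: patients with at least one de novo CNV, all of whose de novo
    CNVs are strictly shorter than ``max_cnv_len``.  Patients with no
    de novo CNV but at least one CNV record go to the replication pool
    (used later with their inherited/unknown-inheritance CNVs).  Patients
    with any de novo CNV at or above the cap are excluded entirely, as are
    patients with no CNV records at all.
    """
    retained: list[PatientRecord] = []
    replication: list[PatientRecord] = []
    for p in patients:
        if not p.cnv_calls:
            logger.warning("patient %s has no CNV records; excluded", p.patient_id)
            continue
        de_novo = p.de_novo_calls()
        if not de_novo:
            replication.append(p)
        elif all(c.length < max_cnv_len for c in de_novo):
            retained.append(p)
        else:
            logger.info(
                "patient %s excluded: de novo CNV >= %d bp", p.patient_id, max_cnv_len
            )
    return retained, replication


def genes_affected(cnv: CnvCall, genes: Iterable[GeneModel]) -> set[str]:
    """Genes whose every coding transcript is disrupted by the CNV.

    A gene is affected iff (a) the whole gene span lies within the CNV, or
    (b) for every transcript at least one exon interval intersects the CNV.
    Rule (b) avoids counting genes where only a fraction of very long
    transcripts is touched.  Genes on other chromosomes are skipped.
    """
    hit: set[str] = set()
    for g in genes:
        if g.chromosome != cnv.chromosome:
            continue
        if cnv.start <= g.gene_start and g.gene_end <= cnv.end:
            hit.add(g.gene_id)
            continue
        if all(
            any(s < cnv.end and cnv.start < e for s, e in tx) for tx in g.transcripts
        ):
            hit.add(g.gene_id)
    return hit


def filter_control_genes(
    genes_by_cnv: dict[str, set[str]],
    cnvs_by_id: dict[str, CnvCall],
    control_gains: set[str],
    control_losses: set[str],
) -> dict[str, set[str]]:
    """Remove genes seen copy-changed in the same direction in controls.

    A gene leaves a gain-CNV's set only if it is in the gain control set,
    and a loss-CNV's set only if in the loss control set; membership in
    the opposite-direction control set does not remove it.
    """
    out: dict[str, set[str]] = {}
    removed = 0
    for cnv_id, gene_set in genes_by_cnv.items():
        ctrl = control_gains if cnvs_by_id[cnv_id].dosage == "gain" else control_losses
        kept = gene_set - ctrl
        removed += len(gene_set) - len(kept)
        out[cnv_id] = kept
    if removed:
        logger.info("control filter removed %d gene assignments", removed)
    return out


def build_groups(
    patients: Sequence[PatientRecord], min_size: int = 3
) -> list[PatientPhenotypeGroup]:
    """One non-exclusive group per propagated term held by >= min_size patients.

    The group's gene set pools each member's filtered de novo CNV genes.
    """
    carriers: dict[str, set[str]] = {}
    by_id = {p.patient_id: p for p in patients}
    for p in patients:
        for t in p.propagated_terms:
            carriers.setdefault(t, set()).add(p.patient_id)
    groups = []
    for term in sorted(carriers):
        members = carriers[term]
        if len(members) < min_size:
            continue
        pooled: set[str] = set()
        for pid in members:
            pooled |= by_id[pid].de_novo_gene_set()
        groups.append(
            PatientPhenotypeGroup(
                term=term, member_ids=frozenset(members), gene_set=frozenset(pooled)
            )
        )
    return groups


def merge_cnvrs(cnvs: Sequence[CnvCall]) -> list[CnvRegion]:
    """Merge CNVs overlapping by >= 1 bp or bookended into CNV regions.

    Dosage is ignored (gains and losses merge together).  Bookended means
    one interval ends exactly where the next starts.  Regions are the
    connected components of this relation per chromosome, reported as
    union spans.
    """
    regions: list[CnvRegion] = []
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in cnvs:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom in sorted(by_chrom):
        calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cur: list[CnvCall] = []
        cur_end = None
        for c in calls:
            if cur and c.start <= cur_end:  # overlap or bookend
                cur.append(c)
                cur_end = max(cur_end, c.end)
            else:
                if cur:
                    regions.append(_make_region(chrom, cur))
                cur = [c]
                cur_end = c.end
        if cur:
            regions.append(_make_region(chrom, cur))
    return regions


def _make_region(chrom: str, members: list[CnvCall]) -> CnvRegion:
    return CnvRegion(
        chromosome=chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        member_cnv_ids=frozenset(c.cnv_id or f"{c.patient_id}:{c.start}-{c.end}" for c in members),
        patient_ids=frozenset(c.patient_id for c in members),
    )


# ---------------------------------------------------------------------------
# readers


def read_cnv_table(path) -> list[CnvCall]:
    """BED-like TSV: chrom, start, end, dosage, inheritance, patient_id[, cnv_id]."""
    calls: list[CnvCall] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            chrom, start, end, dosage, inh, pid = parts[:6]
            cnv_id = parts[6] if len(parts) > 6 else f"cnv{i}"
            calls.append(
                CnvCall(chrom, int(start), int(end), dosage, inh, pid, cnv_id)
            )
    return calls


def read_phenotype_table(path) -> dict[str, set[str]]:
    """Two-column TSV (patient_id, term_id) of direct assignments."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("patient_id\t"):
                continue
            pid, term = line.split("\t")[:2]
            out.setdefault(pid, set()).add(term)
    return out


def build_patients(
    phenotypes: dict[str, set[str]],
    cnvs: Sequence[CnvCall],
    dag: OntologyDAG,
) -> list[PatientRecord]:
    """Assemble PatientRecords, propagating direct terms up the ontology."""
    calls_by_pid: dict[str, list[CnvCall]] = {}
    for c in cnvs:
        calls_by_pid.setdefault(c.patient_id, []).append(c)
    patients = []
    for pid in sorted(set(phenotypes) | set(calls_by_pid)):
        direct = phenotypes.get(pid, set())
        patients.append(
            PatientRecord(
                patient_id=pid,
                direct_terms=set(direct),
                propagated_terms=propagate_ancestors(dag, direct) if direct else set(),
                cnv_calls=sorted(
                    calls_by_pid.get(pid, []), key=lambda c: (c.chromosome, c.start)
                ),
            )
        )
    return patients


def annotate_affected_genes(
    patients: Sequence[PatientRecord],
    genes: Sequence[GeneModel],
    control_gains: set[str] | None = None,
    control_losses: set[str] | None = None,
) -> None:
    """Fill each patient's per-CNV affected gene sets (control-filtered), in place."""
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)
    for p in patients:
        genes_by_cnv = {
            c.cnv_id: genes_affected(c, genes_by_chrom.get(c.chromosome, []))
            for c in p.cnv_calls
        }
        cnvs_by_id = {c.cnv_id: c for c in p.cnv_calls}
        p.affected_genes = filter_control_genes(
            genes_by_cnv, cnvs_by_id, control_gains or set(), control_losses or set()
        )


def read_gene_models_json(path) -> list[GeneModel]:
    """Simplified JSON gene-model format: list of objects with gene_id,
    chromosome, start, end, transcripts=[[ [s,e], ... ], ...]."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        GeneModel(
            gene_id=g["gene_id"],
            chromosome=g["chromosome"],
            gene_start=g["start"],
            gene_end=g["end"],
            transcripts=tuple(
                tuple((int(s), int(e)) for s, e in tx) for tx in g["transcripts"]
            ),
        )
        for g in data
    ]


def read_gene_models_gtf(path) -> list[GeneModel]:
    """GTF-like TSV with gene/transcript/exon feature rows.

    Columns: chrom, source, feature, start, end, score, strand, frame,
    attributes (gene_id "..."; transcript_id "...").  Coordinates are
    1-based inclusive in the file and converted to 0-based half-open here.
    """
    import re

    gene_attr = re.compile(r'gene_id "([^"]+)"')
    tx_attr = re.compile(r'transcript_id "([^"]+)"')
    exons: dict[str, dict[str, list[tuple[int, int]]]] = {}
    chroms: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, _src, feature, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            attrs = parts[8]
            if feature != "exon":
                continue
            gid = gene_attr.search(attrs).group(1)
            tid = tx_attr.search(attrs).group(1)
            chroms[gid] = chrom
            exons.setdefault(gid, {}).setdefault(tid, []).append(
                (int(start) - 1, int(end))
            )
    out = []
    for gid in sorted(exons):
        txs = tuple(
            tuple(sorted(iv)) for _tid, iv in sorted(exons[gid].items())
        )
        all_iv = [iv for tx in txs for iv in tx]
        out.append(
            GeneModel(
                gene_id=gid,
                chromosome=chroms[gid],
                gene_start=min(s for s, _ in all_iv),
                gene_end=max(e for _, e in all_iv),
                transcripts=txs,
            )
        )
    return out
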