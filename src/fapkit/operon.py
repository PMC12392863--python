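"""Fap-operon mining from profile-HMM hit tables.

The fap operon (fapABCDEF) encodes the Pseudomonas functional-amyloid
machinery.  Because the nucleator FapB and the major fibril subunit FapC are
too variable for separate profiles, both are detected by a single
FapBC_repeat HMM that matches their homologous ~39-residue imperfect
repeats; the two genes are then told apart by synteny (fapB precedes fapC in
the operon).  This module parses HMMER3 tabular output, clusters HMM-hit
genes along each contig, applies the operon filters, designates fapB/fapC,
resolves overlapping repeat domains, and tabulates the census histograms
(genes per cluster, repeats per gene, gene/repeat length distributions).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "FAP_HMMS",
    "GeneRecord",
    "DomainHit",
    "GeneCluster",
    "FapOperon",
    "RepeatInstance",
    "CensusTables",
    "DomtbloutError",
    "parse_domtblout",
    "parse_tblout",
    "best_hmm_annotation",
    "cluster_genes",
    "intergenic_distance",
    "filter_fap_clusters",
    "assign_fapB_fapC",
    "count_repeats",
    "operon_census",
    "read_gene_table",
    "write_gene_table",
    "mine_operons",
]

#: The five profile HMMs covering the fap operon; FapBC_repeat matches the
#: imperfect repeats shared by fapB and fapC.
FAP_HMMS = ("FapA", "FapBC_repeat", "FapD", "FapE", "FapF")

#: Default full-sequence e-value cutoff applied to hits.
DEFAULT_EVALUE = 1e-5

#: Default clustering threshold: adjacent genes join a cluster iff their
#: intergenic distance is strictly below this many bp.
DEFAULT_MAX_GAP_BP = 5000


class DomtbloutError(ValueError):
    """Raised for malformed HMMER3 tabular rows."""


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    genome_id: str
    contig_id: str
    start_bp: int
    end_bp: int
    strand: str
    protein_length_aa: int

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"gene {self.gene_id}: end_bp {self.end_bp} < start_bp {self.start_bp}"
            )
        if self.protein_length_aa < 1:
            raise ValueError(f"gene {self.gene_id}: protein_length_aa must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    hmm_name: str
    full_seq_evalue: float
    full_seq_bitscore: float
    domain_index: int
    ali_from_aa: int
    ali_to_aa: int

    def __post_init__(self) -> None:
        if self.full_seq_evalue < 0:
            raise ValueError("e-value must be nonnegative")
        if self.ali_from_aa < 1 or self.ali_to_aa < self.ali_from_aa:
            raise ValueError(
                f"hit {self.gene_id}/{self.hmm_name}: bad alignment coords "
                f"{self.ali_from_aa}-{self.ali_to_aa}"
            )


@dataclass
class GeneCluster:
    genome_id: str
    contig_id: str
    genes: list[GeneRecord]
    hmm_annotations: dict[str, str]

    def __len__(self) -> int:
        return len(self.genes)

    def fapbc_genes(self) -> list[GeneRecord]:
        return [
            g for g in self.genes if self.hmm_annotations.get(g.gene_id) == "FapBC_repeat"
        ]


@dataclass
class FapOperon:
    cluster: GeneCluster
    fapB_gene_id: str | None
    fapC_gene_id: str | None
    role_map: dict[str, str]
    review_flag: bool = False  # >2 FapBC_repeat genes in the cluster


@dataclass(frozen=True)
class RepeatInstance:
    gene_id: str
    ir_index: int  # IR1 = 1, in order of location on the gene
    start_aa: int
    end_aa: int
    sequence: str | None = None

    @property
    def length_aa(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass
class CensusTables:
    """Histograms of operon organisation and repeat occurrence."""

    genes_per_cluster: Counter = field(default_factory=Counter)
    fapbc_genes_per_cluster: Counter = field(default_factory=Counter)
    repeats_per_fapB: Counter = field(default_factory=Counter)
    repeats_per_fapC: Counter = field(default_factory=Counter)
    fapB_length_3rep: Counter = field(default_factory=Counter)
    fapC_length_3rep: Counter = field(default_factory=Counter)
    repeat_lengths: Counter = field(default_factory=Counter)


# ---------------------------------------------------------------------------
# HMMER3 tabular parsing

# domtblout: 22 whitespace-separated columns followed by a free-text
# description.  Column indices (0-based):
#   0 target  3 query  6 full E-value  7 full score  9 dom#  17 ali_from  18 ali_to
_DOMTBL_NCOL = 22


def parse_domtblout(
    path: str | Path,
    evalue_cutoff: float = DEFAULT_EVALUE,
    per_domain: bool = False,
) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table, dropping hits above the e-value cutoff.

    The cutoff applies to the full-sequence e-value by default; with
    ``per_domain=True`` the independent per-domain e-value (i-Evalue) is
    used instead.  Row order is preserved.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, _DOMTBL_NCOL)
            if len(fields) < _DOMTBL_NCOL:
                raise DomtbloutError(
                    f"line {lineno}: expected {_DOMTBL_NCOL} columns before the "
                    f"description, found {len(fields)}"
                )
            try:
                hit = DomainHit(
                    gene_id=fields[0],
                    hmm_name=fields[3],
                    full_seq_evalue=float(fields[6]),
                    full_seq_bitscore=float(fields[7]),
                    domain_index=int(fields[9]),
                    ali_from_aa=int(fields[17]),
                    ali_to_aa=int(fields[18]),
                )
            except ValueError as exc:
                raise DomtbloutError(f"line {lineno}: {exc}") from exc
            evalue = float(fields[12]) if per_domain else hit.full_seq_evalue
            if evalue <= evalue_cutoff:
                hits.append(hit)
    return hits


def parse_tblout(
    path: str | Path, evalue_cutoff: float = DEFAULT_EVALUE
) -> list[tuple[str, str, float, float]]:
    """Parse a HMMER3 per-sequence table.

    Returns (gene_id, hmm_name, full e-value, full bitscore) tuples for hits
    passing the cutoff.  Per-sequence scores sum over every repeat the HMM
    detects in a gene.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 18)
            if len(fields) < 18:
                raise DomtbloutError(
                    f"line {lineno}: expected 18 columns before the description, "
                    f"found {len(fields)}"
                )
            evalue = float(fields[4])
            if evalue <= evalue_cutoff:
                rows.append((fields[0], fields[2], evalue, float(fields[5])))
    return rows


def best_hmm_annotation(hits: list[DomainHit]) -> dict[str, str]:
    """Annotate each gene with the HMM of its best full-sequence bitscore hit.

    A gene hit by several HMMs gets a single identity (ties broken by HMM
    name for determinism).
    """
    best: dict[str, DomainHit] = {}
    for h in hits:
        cur = best.get(h.gene_id)
        if (
            cur is None
            or h.full_seq_bitscore > cur.full_seq_bitscore
            or (h.full_seq_bitscore == cur.full_seq_bitscore and h.hmm_name < cur.hmm_name)
        ):
            best[h.gene_id] = h
    return {gid: h.hmm_name for gid, h in best.items()}


# ---------------------------------------------------------------------------
# clustering and filtering


def intergenic_distance(upstream: GeneRecord, downstream: GeneRecord) -> int:
    """Gap in bp between annotated gene boundaries (start − end − 1)."""
    return downstream.start_bp - upstream.end_bp - 1


def cluster_genes(
    genes: list[GeneRecord],
    hmm_annotations: dict[str, str],
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[GeneCluster]:
    """Single-linkage chain HMM-hit genes along each contig.

    Two genes adjacent on a contig join the same cluster iff their
    intergenic distance is strictly less than ``max_gap_bp``.  The result is
    a partition of the input genes, invariant to input order.
    """
    for g in genes:
        if not g.genome_id:
            raise ValueError(
                f"gene {g.gene_id} lacks a genome_id; cannot mix genes from "
                "multiple genomes without genome ids"
            )
    by_contig: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_contig[(g.genome_id, g.contig_id)].append(g)
    clusters: list[GeneCluster] = []
    for (genome_id, contig_id) in sorted(by_contig):
        ordered = sorted(
            by_contig[(genome_id, contig_id)],
            key=lambda g: (g.start_bp, g.end_bp, g.gene_id),
        )
        current = [ordered[0]]
        current_end = ordered[0].end_bp
        for g in ordered[1:]:
            # measure the gap from the furthest right edge reached so far so
            # nested/overlapping genes cannot break single-linkage chaining
            if g.start_bp - current_end - 1 < max_gap_bp:
                current.append(g)
                current_end = max(current_end, g.end_bp)
            else:
                clusters.append(_make_cluster(genome_id, contig_id, current, hmm_annotations))
                current = [g]
                current_end = g.end_bp
        clusters.append(_make_cluster(genome_id, contig_id, current, hmm_annotations))
    return clusters


def _make_cluster(genome_id, contig_id, genes, hmm_annotations) -> GeneCluster:
    ann = {g.gene_id: hmm_annotations[g.gene_id] for g in genes if g.gene_id in hmm_annotations}
    return GeneCluster(genome_id=genome_id, contig_id=contig_id, genes=list(genes), hmm_annotations=ann)


def filter_fap_clusters(clusters: list[GeneCluster]) -> list[GeneCluster]:
    """Keep clusters with >= 1 FapBC_repeat gene and >= 3 other HMM-hit genes.

    Distinct genes are counted as genes, not distinct HMM identities, so a
    complete fapABCDEF operon (6 genes, two of them FapBC_repeat) passes.
    """
    kept = []
    for c in clusters:
        n_bc = len(c.fapbc_genes())
        n_other = len(c.genes) - n_bc
        if n_bc >= 1 and (n_other + n_bc - 1) >= 3:
            kept.append(c)
    return kept


def assign_fapB_fapC(cluster: GeneCluster) -> FapOperon:
    """Designate fapB and fapC by synteny.

    With two or more FapBC_repeat genes, the first in genomic order is fapB
    and the second fapC (clusters with more than two are flagged for
    review).  A cluster with a single FapBC_repeat gene yields an operon
    with both designations absent: without a partner gene synteny cannot
    distinguish fapB from fapC, and such clusters are excluded from the
    repeat census.
    """
    bc = cluster.fapbc_genes()
    role_map = dict(cluster.hmm_annotations)
    fapB = fapC = None
    flag = False
    if len(bc) >= 2:
        fapB, fapC = bc[0].gene_id, bc[1].gene_id
        role_map[fapB] = "fapB"
        role_map[fapC] = "fapC"
        flag = len(bc) > 2
    return FapOperon(
        cluster=cluster,
        fapB_gene_id=fapB,
        fapC_gene_id=fapC,
        role_map=role_map,
        review_flag=flag,
    )


# ---------------------------------------------------------------------------
# repeats


def count_repeats(
    gene_id: str,
    hits: list[DomainHit],
    protein_seq: str | None = None,
    max_overlap_frac: float = 0.5,
) -> list[RepeatInstance]:
    """Resolve FapBC_repeat domain hits on one gene into numbered repeats.

    Overlapping domain pairs (alignment overlap exceeding
    ``max_overlap_frac`` of the shorter domain) are resolved by keeping the
    higher-bitscore hit; survivors are numbered IR1..IRn in order of
    location on the gene.
    """
    mine = [h for h in hits if h.gene_id == gene_id and h.hmm_name == "FapBC_repeat"]
    # greedy by bitscore: accept a hit unless it overlaps an accepted one
    accepted: list[DomainHit] = []
    for h in sorted(mine, key=lambda h: (-h.full_seq_bitscore, h.ali_from_aa)):
        ok = True
        for a in accepted:
            lo = max(h.ali_from_aa, a.ali_from_aa)
            hi = min(h.ali_to_aa, a.ali_to_aa)
            overlap = max(0, hi - lo + 1)
            shorter = min(h.ali_to_aa - h.ali_from_aa + 1, a.ali_to_aa - a.ali_from_aa + 1)
            if overlap > max_overlap_frac * shorter:
                ok = False
                break
        if ok:
            accepted.append(h)
    accepted.sort(key=lambda h: h.ali_from_aa)
    out = []
    for i, h in enumerate(accepted, start=1):
        seq = None
        if protein_seq is not None:
            seq = protein_seq[h.ali_from_aa - 1 : h.ali_to_aa]
            if not seq:
                raise ValueError(
                    f"gene {gene_id}: alignment {h.ali_from_aa}-{h.ali_to_aa} "
                    f"outside protein of length {len(protein_seq)}"
                )
        out.append(
            RepeatInstance(
                gene_id=gene_id,
                ir_index=i,
                start_aa=h.ali_from_aa,
                end_aa=h.ali_to_aa,
                sequence=seq,
            )
        )
    return out


def operon_census(
    operons: list[FapOperon],
    repeats: dict[str, list[RepeatInstance]],
) -> CensusTables:
    """Tabulate the organisation histograms over a set of fap operons.

    ``repeats`` maps gene_id to its resolved repeat instances.  Operons
    without a fapB/fapC designation contribute to the cluster-level
    histograms but are excluded from the per-gene repeat census.  Gene
    length histograms are restricted to genes with exactly 3 repeats.
    """
    t = CensusTables()
    for op in operons:
        t.genes_per_cluster[len(op.cluster)] += 1
        t.fapbc_genes_per_cluster[len(op.cluster.fapbc_genes())] += 1
        gene_by_id = {g.gene_id: g for g in op.cluster.genes}
        for gid, per_gene, length_hist in (
            (op.fapB_gene_id, t.repeats_per_fapB, t.fapB_length_3rep),
            (op.fapC_gene_id, t.repeats_per_fapC, t.fapC_length_3rep),
        ):
            if gid is None:
                continue
            reps = repeats.get(gid, [])
            per_gene[len(reps)] += 1
            if len(reps) == 3:
                length_hist[gene_by_id[gid].protein_length_aa] += 1
            for r in reps:
                t.repeat_lengths[r.length_aa] += 1
    return t


# ---------------------------------------------------------------------------
# tables and pipeline

_GENE_COLS = ["gene_id", "genome_id", "contig_id", "start", "end", "strand", "aa_length"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene coordinate table (TSV with header) into GeneRecords."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "genome_id": str, "contig_id": str})
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return [
        GeneRecord(
            gene_id=r.gene_id,
            genome_id=r.genome_id,
            contig_id=r.contig_id,
            start_bp=int(r.start),
            end_bp=int(r.end),
            strand=r.strand,
            protein_length_aa=int(r.aa_length),
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.genome_id, g.contig_id, g.start_bp, g.end_bp, g.strand, g.protein_length_aa)
            for g in genes
        ],
        columns=_GENE_COLS,
    ).to_csv(path, sep="\t", index=False)


def mine_operons(
    genes: list[GeneRecord],
    hits: list[DomainHit],
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    protein_seqs: dict[str, str] | None = None,
) -> tuple[list[FapOperon], dict[str, list[RepeatInstance]], CensusTables]:
    """Full mining pipeline: annotate → cluster → filter → assign → census.

    Only genes with at least one retained hit enter clustering.  Returns the
    operons, the per-gene repeat instances for designated fapB/fapC genes,
    and the census tables.
    """
    annotations = best_hmm_annotation(hits)
    hit_genes = [g for g in genes if g.gene_id in annotations]
    clusters = cluster_genes(hit_genes, annotations, max_gap_bp=max_gap_bp)
    operons = [assign_fapB_fapC(c) for c in filter_fap_clusters(clusters)]
    repeats: dict[str, list[RepeatInstance]] = {}
    for op in operons:
        for gid in (op.fapB_gene_id, op.fapC_gene_id):
            if gid is not None:
                seq = protein_seqs.get(gid) if protein_seqs else None
                repeats[gid] = count_repeats(gid, hits, protein_seq=seq)
    return operons, repeats, operon_census(operons, repeats)
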