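"""Tandem and segmental duplication detection.

A pair of family genes is a duplicate pair when a global protein alignment
shows (a) the shorter sequence's aligned span covering > 70% of the longer
sequence and (b) > 70% identity over aligned columns (both strict). Tandem
duplicates additionally sit on one chromosome, separated by at most five
intervening genes, inside a 100-kb window applied per adjacent pair;
clusters are the connected components of that relation, so a chain a–b–c
is a single cluster even if a–c fails pairwise. Segmental duplicates are
family pairs anchored in a supplied collinearity block table (MCScanX-like),
mirroring the database lookup such surveys perform.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GeneModel


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_length: int
    identity_pct: float
    coverage_pct: float
    score: float


@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]  # ordered by start
    span_bp: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SegmentalPair:
    id_a: str
    id_b: str
    block_id: str
    block_length_bp: int


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def global_align(a, b) -> PairwiseAlignment:
    """Needleman–Wunsch alignment with identity and coverage statistics.

    Identity is matches over aligned columns excluding terminal gaps;
    coverage is the shorter sequence's aligned span as a percentage of the
    longer sequence's length.
    """
    from .identification import _as_id_seq

    id_a, seq_a = _as_id_seq(a)
    id_b, seq_b = _as_id_seq(b)
    if not seq_a or not seq_b:
        raise ValueError("empty protein passed to global_align")
    aln = _global_aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned if aligned else 0.0
    short, long_ = sorted((seq_a, seq_b), key=len)
    # aligned span of the shorter sequence: residues sitting in aligned
    # (non-gap-paired) columns
    coverage = 100.0 * aligned / len(long_)
    return PairwiseAlignment(
        id_a=id_a, id_b=id_b, aligned_length=aln.length,
        identity_pct=identity, coverage_pct=min(coverage, 100.0),
        score=float(aln.score),
    )


def is_duplicate_pair(
    alignment: PairwiseAlignment,
    min_coverage: float = 70.0,
    min_identity: float = 70.0,
) -> bool:
    """Strict >70/>70 coverage-and-identity duplicate criterion."""
    return alignment.coverage_pct > min_coverage and alignment.identity_pct > min_identity


def _intervening_count(a: GeneModel, b: GeneModel, chrom_genes: list[GeneModel]) -> int:
    lo = min(a.end, b.end)
    hi = max(a.start, b.start)
    return sum(
        1 for g in chrom_genes
        if g.gene_id not in (a.gene_id, b.gene_id) and g.start > lo and g.end < hi
    )


def find_tandem_clusters(
    members: list[GeneModel],
    full_annotation: list[GeneModel] | None = None,
    proteins: dict[str, str] | None = None,
    max_intervening: int = 5,
    window_bp: int = 100_000,
    min_coverage: float = 70.0,
    min_identity: float = 70.0,
) -> list[TandemCluster]:
    """Maximal clusters of tandem-duplicated family genes.

    The pair relation requires the same chromosome, <= max_intervening
    genes between the pair (counted in the full annotation when given,
    otherwise among the family members, with a warning), a per-pair window
    of window_bp, and — when protein sequences are supplied — the >70/>70
    duplicate-pair criterion. Clusters are connected components of the
    relation, members sorted by start; the result is deterministic and
    input-order invariant.
    """
    if full_annotation is None:
        warnings.warn("no full annotation supplied; counting intervening genes "
                      "among family members only")
        annotation = members
    else:
        annotation = full_annotation
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(str(g.chromosome), []).append(g)

    ordered = sorted(members, key=lambda g: (str(g.chromosome), g.start, g.gene_id))
    index = {g.gene_id: i for i, g in enumerate(ordered)}
    parent = list(range(len(ordered)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    align_cache: dict[tuple, bool] = {}

    def sequence_ok(a: GeneModel, b: GeneModel) -> bool:
        if proteins is None:
            return True
        key = tuple(sorted((a.gene_id, b.gene_id)))
        if key not in align_cache:
            pa, pb = proteins.get(a.gene_id), proteins.get(b.gene_id)
            if pa is None or pb is None:
                align_cache[key] = False
            else:
                align_cache[key] = is_duplicate_pair(
                    global_align(pa, pb), min_coverage, min_identity
                )
        return align_cache[key]

    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if str(b.chromosome) != str(a.chromosome):
                break
            if max(a.end, b.end) - min(a.start, b.start) > window_bp:
                continue
            chrom_genes = by_chrom.get(str(a.chromosome), [])
            if _intervening_count(a, b, chrom_genes) > max_intervening:
                continue
            if sequence_ok(a, b):
                union(index[a.gene_id], index[b.gene_id])

    groups: dict[int, list[GeneModel]] = {}
    for g in ordered:
        groups.setdefault(find(index[g.gene_id]), []).append(g)
    clusters = []
    for group in groups.values():
        if len(group) < 2:
            continue
        group.sort(key=lambda g: g.start)
        clusters.append(
            TandemCluster(
                chromosome=str(group[0].chromosome),
                members=[g.gene_id for g in group],
                span_bp=max(g.end for g in group) - min(g.start for g in group),
            )
        )
    clusters.sort(key=lambda c: (c.chromosome, c.members[0]))
    return clusters


BLOCK_COLUMNS = ["block_id", "chr_a", "chr_b", "gene_a", "gene_b",
                 "block_start_a", "block_end_a", "block_start_b", "block_end_b"]


def read_block_table(path) -> pd.DataFrame:
    """Read an MCScanX-like collinearity anchor table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(BLOCK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"block table missing columns: {sorted(missing)}")
    return df


def find_segmental_pairs(member_ids, blocks: pd.DataFrame) -> list[SegmentalPair]:
    """Family pairs co-anchored in a collinearity block."""
    member_set = set(member_ids)
    pairs = []
    seen = set()
    for _, row in blocks.iterrows():
        a, b = str(row.gene_a), str(row.gene_b)
        if a in member_set and b in member_set:
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            length = int(row.block_end_a) - int(row.block_start_a) + 1
            pairs.append(SegmentalPair(id_a=a, id_b=b,
                                       block_id=str(row.block_id),
                                       block_length_bp=length))
    pairs.sort(key=lambda p: (p.block_id, p.id_a))
    return pairs


def duplication_summary(
    clusters: list[TandemCluster],
    pairs: list[SegmentalPair],
    family_size: int,
) -> dict:
    """Tandem/segmental gene counts with one-decimal percentages."""
    tandem_genes = sorted({m for c in clusters for m in c.members})
    segmental_genes = sorted({g for p in pairs for g in (p.id_a, p.id_b)})

    def pct(n):
        return round(100.0 * n / family_size, 1) if family_size else 0.0

    return {
        "family_size": family_size,
        "tandem_gene_count": len(tandem_genes),
        "tandem_gene_pct": pct(len(tandem_genes)),
        "tandem_cluster_sizes": sorted((len(c) for c in clusters), reverse=True),
        "segmental_pair_count": len(pairs),
        "segmental_gene_count": len(segmental_genes),
        "segmental_gene_pct": pct(len(segmental_genes)),
        "tandem_genes": tandem_genes,
        "segmental_genes": segmental_genes,
    }
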