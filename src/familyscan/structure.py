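"""Exon–intron structure, intron phases and consensus-motif scanning.

Intron phase follows the donor-side convention: phase of intron *i* is the
cumulative coding length 5' of the intron modulo 3, so phase 0 means the
intron falls exactly between codons. Because exons are stored in
transcription order the computation is strand-free.

Intron-pattern classes follow the three-way scheme used across plant
small-heat-shock-protein surveys: class 1 = intronless, class 2 = one
intron, class 3 = two or more introns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .genome_io import FamilyTableRow, GeneModel, load_motif_table

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class GeneStructure:
    gene_id: str
    intron_count: int
    intron_phases: list[int]
    exon_lengths: list[int]


@dataclass
class MotifOccurrence:
    motif_id: int
    protein_id: str
    start: int  # 1-based
    end: int
    score: float


def derive_structure(gene: GeneModel) -> GeneStructure:
    lengths = [e - s + 1 for s, e in gene.exons]
    phases = [sum(lengths[: i + 1]) % 3 for i in range(len(lengths) - 1)]
    return GeneStructure(
        gene_id=gene.gene_id,
        intron_count=max(0, len(lengths) - 1),
        intron_phases=phases,
        exon_lengths=lengths,
    )


def classify_intron_pattern(structure_or_count) -> int:
    """Intron-pattern class: 1 (no intron), 2 (one), 3 (two or more)."""
    n = (
        structure_or_count.intron_count
        if isinstance(structure_or_count, GeneStructure)
        else int(structure_or_count)
    )
    if n == 0:
        return 1
    if n == 1:
        return 2
    return 3


def summarize_intron_classes(rows: list[FamilyTableRow]) -> pd.DataFrame:
    """Counts and one-decimal percentages of the three intron classes."""
    classes = [classify_intron_pattern(r.exon_count - 1) for r in rows]
    total = len(classes)
    data = []
    for cls in (1, 2, 3):
        n = classes.count(cls)
        pct = round(100.0 * n / total, 1) if total else 0.0
        data.append({"pattern_class": cls, "count": n, "percent": pct})
    return pd.DataFrame(data)


def _blosum_score(a: str, b: str) -> float:
    try:
        return _BLOSUM62[a, b]
    except KeyError:
        return -4.0


def motif_self_score(consensus: str) -> float:
    return sum(_blosum_score(c, c) for c in consensus)


def scan_motif(
    protein,
    consensus: str,
    motif_id: int = 0,
    min_fraction: float = 0.5,
) -> list[MotifOccurrence]:
    """All windows scoring >= min_fraction of the consensus self-score.

    Scoring is ungapped BLOSUM62 similarity of each window against the
    consensus string; occurrences are reported 1-based, best score first.
    """
    from .identification import _as_id_seq

    pid, seq = _as_id_seq(protein)
    w = len(consensus)
    if len(seq) < w:
        return []
    threshold = min_fraction * motif_self_score(consensus)
    occurrences = []
    for off in range(len(seq) - w + 1):
        score = sum(_blosum_score(consensus[i], seq[off + i]) for i in range(w))
        if score >= threshold:
            occurrences.append(
                MotifOccurrence(motif_id=motif_id, protein_id=pid,
                                start=off + 1, end=off + w, score=float(score))
            )
    occurrences.sort(key=lambda o: (-o.score, o.start))
    return occurrences


def scan_all_motifs(
    proteins, motif_table: pd.DataFrame | None = None, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Scan every protein for every packaged consensus motif."""
    if motif_table is None:
        motif_table = load_motif_table()
    rows = []
    for rec in proteins:
        for _, m in motif_table.iterrows():
            for occ in scan_motif(rec, m.consensus, int(m.motif_id), min_fraction):
                rows.append(
                    {"protein_id": occ.protein_id, "motif_id": occ.motif_id,
                     "start": occ.start, "end": occ.end, "score": occ.score}
                )
    return pd.DataFrame(rows, columns=["protein_id", "motif_id", "start", "end", "score"])


def structures_table(genes: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        s = derive_structure(g)
        rows.append(
            {"gene_id": s.gene_id, "intron_count": s.intron_count,
             "intron_phases": ",".join(map(str, s.intron_phases)),
             "pattern_class": classify_intron_pattern(s)}
        )
    return pd.DataFrame(rows, columns=["gene_id", "intron_count", "intron_phases", "pattern_class"])
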