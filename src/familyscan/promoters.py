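"""Promoter extraction and stress-element scanning.

The promoter is the 1.5-kb window upstream of the translation start.
Six stress-response element classes (ABRE, DRE, HSE, LTRE, TC-rich
repeats, W-box) are scanned as exact IUPAC consensus matches on both
strands; positions are reported as 1-based distances upstream of the ATG
(position 1 is the base adjacent to the start codon), on the promoter's
forward coordinate regardless of the matching strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .genome_io import GeneModel, SequenceRecord, _packaged, reverse_complement

ELEMENT_CLASSES = ("ABRE", "DRE", "HSE", "LTRE", "TC-rich", "W-box")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class ElementDefinition:
    class_name: str
    iupac_patterns: list[str]


@dataclass
class CisElementHit:
    gene_id: str
    class_name: str
    position: int  # bp upstream of the translation start, 1-based
    strand: str
    matched_sequence: str


@dataclass
class PromoterStatus:
    gene_id: str
    available: bool
    truncated: bool = False


def load_element_table(path=None) -> list[ElementDefinition]:
    """Default stress-element consensus table (user-overridable TSV)."""
    if path is None:
        path = _packaged("elements.tsv")
    df = pd.read_csv(path, sep="\t")
    defs = []
    for cls, group in df.groupby("class_name", sort=False):
        defs.append(ElementDefinition(class_name=cls,
                                      iupac_patterns=list(group.pattern)))
    return defs


def iupac_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[c] for c in pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc} in pattern {pattern!r}") from None


def extract_upstream(
    gene: GeneModel, genome: list[SequenceRecord], length: int = 1500
) -> tuple[str | None, PromoterStatus]:
    """Upstream sequence of a gene, 5'→3' toward the translation start.

    Plus strand: the ``length`` bases before ``start``; minus strand: the
    reverse complement of the ``length`` bases after ``end``. Windows
    truncated by the contig edge are flagged; zero upstream bases means
    the promoter is unavailable.
    """
    if gene.strand not in "+-":
        raise ValueError(f"{gene.gene_id}: strand must be known to extract a promoter")
    chrom = next((r for r in genome if r.id == gene.chromosome), None)
    if chrom is None:
        raise ValueError(f"{gene.gene_id}: chromosome {gene.chromosome!r} not in genome")
    seq = chrom.residues
    if gene.strand == "+":
        lo = max(0, gene.start - 1 - length)
        window = seq[lo:gene.start - 1]
    else:
        hi = min(len(seq), gene.end + length)
        window = reverse_complement(seq[gene.end:hi])
    truncated = len(window) < length
    if not window:
        return None, PromoterStatus(gene.gene_id, available=False)
    return window, PromoterStatus(gene.gene_id, available=True, truncated=truncated)


def scan_elements(
    promoter: str,
    definitions: list[ElementDefinition] | None = None,
    gene_id: str = "",
) -> list[CisElementHit]:
    """Exact IUPAC matches of every element pattern, both strands.

    Overlapping matches are all reported. For a promoter of length L, a
    match whose leftmost (5'-most forward) base sits at 0-based forward
    offset o gets position L − o − w + 1: the upstream distance of the
    base nearest the ATG, so position 1 is adjacent to the start codon
    and positions run 1..L − w + 1 on either strand.
    """
    if definitions is None:
        definitions = load_element_table()
    L = len(promoter)
    promoter = promoter.upper()
    rc = reverse_complement(promoter)
    hits = []
    for definition in definitions:
        for pattern in definition.iupac_patterns:
            rx = iupac_regex(pattern)
            w = len(pattern)
            for off in range(L - w + 1):
                fwd = promoter[off:off + w]
                if rx.fullmatch(fwd):
                    hits.append(CisElementHit(gene_id, definition.class_name,
                                              position=L - off - w + 1, strand="+",
                                              matched_sequence=fwd))
                rev = rc[off:off + w]
                if rx.fullmatch(rev):
                    # rc offset off -> forward offset L - off - w
                    hits.append(CisElementHit(gene_id, definition.class_name,
                                              position=off + 1, strand="-",
                                              matched_sequence=rev))
    hits.sort(key=lambda h: (-h.position, h.class_name, h.strand))
    return hits


def summarize_elements(
    hits_per_gene: dict[str, list[CisElementHit]],
    family_ids: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene element-class count matrix and the element-free gene list."""
    matrix = pd.DataFrame(0, index=list(family_ids), columns=list(ELEMENT_CLASSES))
    for gene_id, hits in hits_per_gene.items():
        for hit in hits:
            matrix.loc[gene_id, hit.class_name] += 1
    matrix["has_any_stress_element"] = matrix[list(ELEMENT_CLASSES)].sum(axis=1) > 0
    element_free = [g for g in family_ids if not matrix.loc[g, "has_any_stress_element"]]
    return matrix, element_free


def scan_family_promoters(
    genes: list[GeneModel],
    genome: list[SequenceRecord],
    definitions: list[ElementDefinition] | None = None,
    length: int = 1500,
):
    """Extract and scan every family promoter; returns (hits, statuses)."""
    if definitions is None:
        definitions = load_element_table()
    hits_per_gene: dict[str, list[CisElementHit]] = {}
    statuses = []
    for gene in genes:
        promoter, status = extract_upstream(gene, genome, length)
        statuses.append(status)
        hits_per_gene[gene.gene_id] = (
            scan_elements(promoter, definitions, gene.gene_id) if promoter else []
        )
    return hits_per_gene, statuses
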