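"""Sequence, annotation and fixture I/O.

All genomic coordinates are 1-based inclusive internally (the convention of
GFF3 and of the packaged family table); conversion to BED's 0-based
half-open happens only at the BED boundary. Gene models carry their coding
exons in transcription order, so downstream intron-phase arithmetic never
needs to know the strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named DNA or protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParseError(f"record {self.id!r}: empty sequence")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_dna(self) -> bool:
        return set(self.residues) <= DNA_ALPHABET

    @property
    def is_protein(self) -> bool:
        return set(self.residues) <= PROTEIN_ALPHABET


@dataclass
class GeneModel:
    """A gene's coding structure on a chromosome.

    ``exons`` are the coding exons as (start, end) 1-based inclusive pairs,
    ordered 5'→3' in transcription order (descending coordinates on the
    minus strand). ``cds_sequence`` is the spliced, strand-corrected CDS.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_sequence: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-?":
            raise ValueError(f"{self.gene_id}: strand must be '+', '-' or '?'")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return max(0, len(self.exons) - 1)


@dataclass
class FamilyTableRow:
    """One row of the packaged 48-gene family feature table."""

    name: str
    gene_id: str
    chromosome: int
    start: int
    end: int
    orf_length: int
    exon_count: int
    aa_count: int
    mw_kda: float
    pi: float

    def __post_init__(self) -> None:
        if self.orf_length != 3 * (self.aa_count + 1):
            raise ParseError(
                f"{self.name}: ORF {self.orf_length} != 3 x (AA {self.aa_count} + 1)"
            )
        if self.exon_count < 1:
            raise ParseError(f"{self.name}: exon_count must be >= 1")
        if not 1 <= self.chromosome <= 12:
            raise ParseError(f"{self.name}: chromosome {self.chromosome} outside 1..12")


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, order preserved, uppercased."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def _gff3_attributes(col: str) -> dict:
    out = {}
    for item in col.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path, genome: list[SequenceRecord]) -> list[GeneModel]:
    """Assemble GeneModels from a GFF3 file with gene/mRNA/CDS features.

    CDS pieces are spliced in transcription order and minus-strand models
    are reverse-complemented. Genes with several mRNAs keep the longest
    CDS (one protein per gene). Models whose CDS length is not a multiple
    of 3 are dropped with a warning; an unknown chromosome is an error.
    """
    chrom_seq = {r.id: r.residues for r in genome}
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_cds: dict[str, list] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            start, end = int(start), int(end)
            attrs = _gff3_attributes(attrs)
            if ftype == "gene":
                genes[attrs["ID"]] = {
                    "chromosome": chrom, "strand": strand, "start": start, "end": end,
                }
            elif ftype == "mRNA":
                mrna_parent[attrs["ID"]] = attrs["Parent"]
                mrna_cds.setdefault(attrs["ID"], [])
            elif ftype == "CDS":
                mrna_cds.setdefault(attrs["Parent"], []).append((start, end, chrom, strand))

    models = []
    for gene_id, info in genes.items():
        # pick the transcript with the longest total CDS
        best = None
        for mrna_id, parent in mrna_parent.items():
            if parent != gene_id:
                continue
            pieces = mrna_cds.get(mrna_id, [])
            total = sum(e - s + 1 for s, e, *_ in pieces)
            if pieces and (best is None or total > best[0]):
                best = (total, pieces)
        if best is None:
            continue
        total, pieces = best
        if total % 3 != 0:
            warnings.warn(
                f"{gene_id}: CDS length {total} not divisible by 3; model rejected"
            )
            continue
        chrom = info["chromosome"]
        if chrom not in chrom_seq:
            raise ParseError(f"{gene_id}: chromosome {chrom!r} not present in genome")
        seq = chrom_seq[chrom]
        exons = sorted((s, e) for s, e, *_ in pieces)
        cds = "".join(seq[s - 1:e] for s, e in exons)
        if info["strand"] == "-":
            cds = reverse_complement(cds)
            exons = exons[::-1]
        models.append(
            GeneModel(
                gene_id=gene_id, chromosome=chrom, strand=info["strand"],
                start=info["start"], end=info["end"], exons=exons, cds_sequence=cds,
            )
        )
    return models


# ---------------------------------------------------------------------------
# packaged family table


def _packaged(name: str) -> Path:
    return Path(resources.files("familyscan").joinpath("data", name))


def load_family_table(path=None) -> list[FamilyTableRow]:
    """Load the packaged 48-member family feature table (or a compatible TSV).

    Every row is checked against the ORF = 3 x (AA + 1) stop-codon
    invariant at load time; a violation names the offending row.
    """
    if path is None:
        path = _packaged("table1.tsv")
    df = pd.read_csv(path, sep="\t")
    return [FamilyTableRow(**row) for row in df.to_dict("records")]


def family_table_models(rows: list[FamilyTableRow] | None = None) -> list[GeneModel]:
    """Positional GeneModels from the family table (strand unknown).

    The printed table does not state strand, so strand-dependent
    operations (promoter extraction, CDS assembly) require GFF3 input;
    positional analyses (naming, tandem windows) work from these models.
    """
    if rows is None:
        rows = load_family_table()
    return [
        GeneModel(gene_id=r.name, chromosome=str(r.chromosome), strand="?",
                  start=r.start, end=r.end)
        for r in rows
    ]


def family_table_frame(path=None) -> pd.DataFrame:
    if path is None:
        path = _packaged("table1.tsv")
    return pd.read_csv(path, sep="\t")


def load_motif_table(path=None) -> pd.DataFrame:
    """The 10 family consensus motifs (motif_id, width, consensus)."""
    if path is None:
        path = _packaged("table2_motifs.tsv")
    df = pd.read_csv(path, sep="\t")
    bad = df[df.consensus.str.len() != df.width]
    if len(bad):
        raise ParseError(f"motif widths inconsistent for ids {list(bad.motif_id)}")
    return df


def load_acd_seed(path=None) -> list[SequenceRecord]:
    """The packaged synthetic ACD seed alignment (equal-width, ungapped)."""
    if path is None:
        path = _packaged("acd_seed_synthetic.afa")
    return read_fasta(path)


# ---------------------------------------------------------------------------
# Newick / BED


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, name[, score[, strand]]) 1-based inclusive
    intervals as BED6 lines (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end, *rest = iv
            name = rest[0] if len(rest) > 0 else "."
            score = rest[1] if len(rest) > 1 else 0
            strand = rest[2] if len(rest) > 2 else "."
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path) -> list[tuple]:
    """Read BED lines back to 1-based inclusive (chrom, start, end, name, score, strand)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            chrom, start, end = cols[0], int(cols[1]) + 1, int(cols[2])
            name = cols[3] if len(cols) > 3 else "."
            score = cols[4] if len(cols) > 4 else 0
            strand = cols[5] if len(cols) > 5 else "."
            out.append((chrom, start, end, name, score, strand))
    return out
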