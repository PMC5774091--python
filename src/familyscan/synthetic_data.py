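"""Synthetic genomes, expression matrices and qPCR tables with known truth.

The generator plants a small-heat-shock-protein-like gene family on a
multi-chromosome genome: every family protein carries a mutated copy of
the packaged ACD consensus, tandem clusters sit at controlled spacing and
identity, one segmental pair is duplicated across chromosomes and
anchored in an emitted collinearity-block table, promoters carry planted
stress elements at recorded positions, and introns are inserted with
valid GT..AG boundaries at chosen codon phases. Decoy genes either lack
the domain or violate the 15–42 kDa window. Everything is a pure
function of (config, seed).

The default configuration mirrors the shape of a real plant survey of
this family: 48 members on 12 chromosomes, tandem clusters of sizes
3/5/3/4/2/2 (19 genes), one segmental pair, a 20/23/5 intron-class
split, two silent genes and fourteen >100-fold heat responders — so that
pipeline summaries are directly comparable with published counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import GeneModel, SequenceRecord, reverse_complement, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"

ACD_CONSENSUS = (
    "FPPSSSRETSAFANTRIDWKETPEAHVFKVDVPGLKKEEVKVEVEEDRVLQISGERSREKEEKNDKWHRV"
    "ERSSGKFMRRFRLPENAKMDQIKASMENGVLTVTVPKEEEKKP"
)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    _CODONS.setdefault(_aa, []).append(_codon)
_STOPS = sorted(_STANDARD.stop_codons)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# one concrete planted instance per element class (each matches its own
# class's consensus table exactly once on the forward strand; HSE's
# GAA..TTC core is self-complementary, so a planted HSE also matches on
# the minus strand at the same position)
PLANT_INSTANCES = {
    "ABRE": "ACGTG",
    "DRE": "ACCGAC",
    "HSE": "AGAACATTCA",
    "LTRE": "CCGAAA",
    "TC-rich": "ATTTTCTTCA",
    "W-box": "TTGACC",
}

ELEMENT_PATTERNS = {
    "ABRE": ["ACGTG", "YACGTGGC"],
    "DRE": ["RCCGAC"],
    "HSE": ["NGAANNTTCN", "AGAANNTTCT"],
    "LTRE": ["CCGAAA"],
    "TC-rich": ["ATTTTCTTCA", "GTTTTCTTAC"],
    "W-box": ["TTGACY"],
}

# survey-shaped defaults (1-based family gene indices)
_DEFAULT_CHROM_COUNTS = (4, 2, 4, 5, 1, 5, 2, 5, 9, 3, 2, 6)
_DEFAULT_CLUSTERS = (
    (1, 3, 3000, 95.0), (6, 5, 3000, 95.0), (8, 3, 3000, 95.0),
    (9, 4, 3000, 95.0), (10, 2, 3000, 95.0), (12, 2, 3000, 95.0),
)
_DEFAULT_INTRONLESS = {4, 9, 17, 18, 19, 20, 21, 24, 25, 32, 33, 34, 35,
                       36, 37, 38, 39, 41, 43, 44}
_DEFAULT_MULTI_INTRON = {15: 12, 16: 2, 22: 5, 45: 8, 48: 5}
_DEFAULT_SILENT = (2, 45)
_DEFAULT_UP_EXTREME = (4, 6, 7, 9, 20, 21, 33, 34, 35, 37, 41, 43, 44, 46)
_DEFAULT_ELEMENT_FREE = (23, 41)


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chromosomes: int = 12
    chromosome_length_bp: int = 800_000
    n_family_genes: int = 48
    chrom_counts: tuple = _DEFAULT_CHROM_COUNTS
    tandem_cluster_spec: tuple = _DEFAULT_CLUSTERS
    segmental_pair: bool = True
    segmental_gene_indices: tuple = (15, 48)
    segmental_block_length_bp: int = 625_000
    intronless_indices: frozenset = frozenset(_DEFAULT_INTRONLESS)
    multi_intron_counts: dict = field(default_factory=lambda: dict(_DEFAULT_MULTI_INTRON))
    planted_elements: dict | None = None  # index -> {class: count}; None = default recipe
    element_free_indices: tuple = _DEFAULT_ELEMENT_FREE
    silent_gene_indices: tuple = _DEFAULT_SILENT
    up_extreme_indices: tuple = _DEFAULT_UP_EXTREME
    fold_change_truth: dict | None = None  # index -> {condition: fold}; None = default
    decoy_genes: int = 6
    qpcr_noise_sd: float = 0.1
    qpcr_efficiency_pct: float = 100.0
    fpkm_noise_sdlog: float = 0.1
    tissues: tuple = ("leaf", "stem", "root", "shoot", "callus",
                     "flower", "petiole", "stolon", "tuber", "sepal")
    conditions: tuple = ("heat", "salt", "drought")
    timepoints: tuple = ("0h", "3h", "24h")
    intergenic_gap_bp: int = 120_000
    acd_mutation_rate: float = 0.20
    min_protein_len: int = 150
    max_protein_len: int = 300

    def gene_name(self, index: int) -> str:
        return f"g{index:03d}"


def default_fold_truth(config: SimulationConfig) -> dict[int, dict[str, float]]:
    """Per-gene true fold changes (applied at both stress timepoints)."""
    truth = {}
    up = set(config.up_extreme_indices)
    for i in range(1, config.n_family_genes + 1):
        heat = 150.0 if i in up else (1.0 if i in (29, 30) else 8.0)
        salt = 0.5 if i % 7 == 0 else (1.0 if i % 5 == 0 else 3.0)
        drought = 0.5 if i % 6 == 0 else (1.0 if i % 4 == 0 else 2.5)
        truth[i] = {"heat": heat, "salt": salt, "drought": drought}
    return truth


def default_planted_elements(config: SimulationConfig) -> dict[int, dict[str, int]]:
    """Per-gene planted element-class counts (two genes element-free)."""
    planted = {}
    free = set(config.element_free_indices)
    for i in range(1, config.n_family_genes + 1):
        if i in free:
            planted[i] = {}
            continue
        counts = {"HSE": 1 + (1 if i % 3 == 0 else 0)}
        if i % 2 == 0:
            counts["TC-rich"] = 1
        if i % 4 == 0:
            counts["W-box"] = 1
        if i % 5 == 0:
            counts["LTRE"] = 1
        if i % 6 == 0:
            counts["ABRE"] = 1
        if i == 33:
            counts["DRE"] = 1
        planted[i] = counts
    return planted


# ---------------------------------------------------------------------------
# low-level sequence helpers


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_protein(rng, n: int) -> str:
    return "M" + "".join(rng.choice(list(AA20), size=n - 1))


def _mutate_protein(rng, protein: str, rate: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):  # keep the initiator Met
        if rng.random() < rate:
            out[i] = AA20[rng.integers(0, 20)]
    return "".join(out)


def back_translate(rng, protein: str) -> str:
    """Seeded back-translation, uniform over synonymous codons, plus a stop."""
    codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein]
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(codons)


def _intron_cuts(rng, cds_len: int, phases: list[int]) -> list[int]:
    """Coding-offset cut points realising the requested intron phases."""
    n = len(phases)
    cuts = []
    for i, phase in enumerate(phases):
        base = (i + 1) * cds_len // (n + 1)
        cut = base - (base - phase) % 3  # largest c <= base with c % 3 == phase
        if cut <= (cuts[-1] if cuts else 0):
            cut += 3
        cuts.append(cut)
    if cuts and cuts[-1] >= cds_len:
        raise ValueError("CDS too short for the requested intron count")
    return cuts


def _make_genebody(rng, cds: str, phases: list[int]):
    """Split a CDS at phase-chosen cuts and interleave GT..AG introns.

    Returns (genebody sequence, exon (start, end) 0-based offsets within it).
    """
    if not phases:
        return cds, [(0, len(cds) - 1)]
    cuts = _intron_cuts(rng, len(cds), phases)
    pieces = []
    exon_offsets = []
    prev = 0
    cursor = 0
    for cut in cuts + [len(cds)]:
        exon = cds[prev:cut]
        exon_offsets.append((cursor, cursor + len(exon) - 1))
        pieces.append(exon)
        cursor += len(exon)
        if cut != len(cds):
            ilen = int(rng.integers(200, 2001))
            intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
            pieces.append(intron)
            cursor += len(intron)
        prev = cut
    return "".join(pieces), exon_offsets


# ---------------------------------------------------------------------------
# independent brute-force IUPAC matcher (used only to build promoter truth)


def brute_iupac_matches(seq: str, pattern: str) -> list[int]:
    """0-based offsets where the pattern matches exactly (naive loop)."""
    w = len(pattern)
    allowed = [IUPAC_SETS[c] for c in pattern.upper()]
    out = []
    for off in range(len(seq) - w + 1):
        if all(seq[off + k] in allowed[k] for k in range(w)):
            out.append(off)
    return out


def brute_scan_both_strands(promoter: str) -> list[tuple[str, int, str]]:
    """(class, upstream position, strand) for every element match."""
    L = len(promoter)
    rc = reverse_complement(promoter)
    hits = []
    for cls, patterns in ELEMENT_PATTERNS.items():
        for pat in patterns:
            w = len(pat)
            for off in brute_iupac_matches(promoter, pat):
                hits.append((cls, L - off - w + 1, "+"))
            for off in brute_iupac_matches(rc, pat):
                hits.append((cls, off + 1, "-"))
    return hits


def _build_promoter(rng, length: int, planted: dict[str, int]):
    """Scrubbed random promoter with planted elements at recorded offsets.

    Returns (sequence, truth) where truth maps class -> list of upstream
    positions of the planted instances. The background is re-randomised
    until the only element matches are those produced by the planted
    instances themselves.
    """
    seq = list(_random_dna(rng, length))
    slots = []
    planted_positions: dict[str, list[int]] = {}
    # reserve non-overlapping windows, spread across the promoter
    cursor = 20
    for cls in sorted(planted):
        for _ in range(planted[cls]):
            inst = PLANT_INSTANCES[cls]
            off = cursor + int(rng.integers(0, 60))
            cursor = off + len(inst) + 40
            if cursor > length - 20:
                raise ValueError("promoter too short for the requested elements")
            slots.append((off, inst))
            planted_positions.setdefault(cls, []).append(length - off - len(inst) + 1)
    protected = set()
    for off, inst in slots:
        seq[off:off + len(inst)] = list(inst)
        protected.update(range(off, off + len(inst)))
    # scrub background matches that do not stem from planted instances
    for _ in range(50):
        dirty = False
        text = "".join(seq)
        rc = reverse_complement(text)
        for patterns in ELEMENT_PATTERNS.values():
            for pat in patterns:
                w = len(pat)
                for strand_seq, is_rc in ((text, False), (rc, True)):
                    for off in brute_iupac_matches(strand_seq, pat):
                        fwd = length - off - w if is_rc else off
                        span = set(range(fwd, fwd + w))
                        if span <= protected:
                            continue  # produced by a planted instance
                        for p in sorted(span - protected):
                            seq[p] = "ACGT"[rng.integers(0, 4)]
                        dirty = True
        if not dirty:
            break
    return "".join(seq), planted_positions


# ---------------------------------------------------------------------------
# genome generation


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    chromosomes: list[SequenceRecord]
    gene_models: list[GeneModel]  # family + decoys, in placement order
    family_ids: list[str]
    proteins: dict[str, str]
    annotations: dict[str, str]
    blocks: pd.DataFrame
    truth: dict

    @property
    def family_models(self) -> list[GeneModel]:
        fam = set(self.family_ids)
        return [g for g in self.gene_models if g.gene_id in fam]

    def write(self, outdir) -> dict:
        """Write FASTA/GFF3/TSV artifacts plus truth.json; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gff3": outdir / "annotation.gff3",
            "proteins": outdir / "proteins.faa",
            "annotations": outdir / "descriptions.tsv",
            "blocks": outdir / "blocks.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.chromosomes, paths["genome"])
        write_fasta(
            [SequenceRecord(gid, seq, self.annotations.get(gid, ""))
             for gid, seq in self.proteins.items()],
            paths["proteins"],
        )
        with open(paths["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.gene_models:
                fh.write(f"{g.chromosome}\tfamilyscan_sim\tgene\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}\n")
                mrna = f"{g.gene_id}.1"
                fh.write(f"{g.chromosome}\tfamilyscan_sim\tmRNA\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
                for s, e in sorted(g.exons):
                    fh.write(f"{g.chromosome}\tfamilyscan_sim\tCDS\t{s}\t{e}\t.\t"
                             f"{g.strand}\t0\tID={mrna}.cds;Parent={mrna}\n")
        pd.DataFrame(
            [{"id": k, "description": v} for k, v in self.annotations.items()]
        ).to_csv(paths["annotations"], sep="\t", index=False)
        self.blocks.to_csv(paths["blocks"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)
        return paths


def _plan_gene_indices(config: SimulationConfig):
    """Map family gene indices to (chromosome, slot); mark cluster members."""
    counts = list(config.chrom_counts)
    if len(counts) != config.n_chromosomes or sum(counts) != config.n_family_genes:
        raise ValueError("chrom_counts inconsistent with n_chromosomes/n_family_genes")
    index = 1
    placement = {}  # gene index -> (chrom_num, slot)
    per_chrom = {}
    for chrom_num, n in enumerate(counts, 1):
        per_chrom[chrom_num] = list(range(index, index + n))
        for slot, i in enumerate(per_chrom[chrom_num]):
            placement[i] = (chrom_num, slot)
        index += n
    clusters = []  # list of (gene index list, spacing, identity)
    used = set()
    for chrom_num, size, spacing, identity in config.tandem_cluster_spec:
        chrom_genes = [i for i in per_chrom.get(chrom_num, []) if i not in used]
        if len(chrom_genes) < size:
            raise ValueError(f"chromosome {chrom_num} has too few genes for a "
                             f"cluster of {size}")
        members = chrom_genes[:size]
        used.update(members)
        clusters.append((members, spacing, identity))
    return per_chrom, clusters


def generate_genome(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SimulatedGenome:
    """Generate the genome, annotation, proteome, blocks and truth table."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_family_genes
    per_chrom, clusters = _plan_gene_indices(config)
    cluster_of = {}
    for ci, (members, spacing, identity) in enumerate(clusters):
        for m in members:
            cluster_of[m] = ci

    # --- intron plan
    phases_plan: dict[int, list[int]] = {}
    seg_a, seg_b = config.segmental_gene_indices
    for i in range(1, n + 1):
        if i in config.intronless_indices:
            phases_plan[i] = []
        elif i in config.multi_intron_counts:
            k = config.multi_intron_counts[i]
            # the segmental pair shares a conserved 1,2,0,0,0 phase run
            planted = [1, 2, 0, 0, 0] if i in (seg_a, seg_b) else []
            extra = [int(rng.integers(0, 3)) for _ in range(k - len(planted))]
            phases_plan[i] = (planted + extra)[:k]
        else:
            phases_plan[i] = [int(rng.integers(0, 3))]

    # --- proteins
    proteins: dict[int, str] = {}
    for members, spacing, identity in clusters:
        length = int(rng.integers(config.min_protein_len, config.max_protein_len))
        nt_len = max(10, (length - len(ACD_CONSENSUS)) // 2)
        ancestor = (
            _random_protein(rng, nt_len)
            + _mutate_protein(rng, "M" + ACD_CONSENSUS, config.acd_mutation_rate)[1:]
            + "".join(rng.choice(list(AA20), size=length - nt_len - len(ACD_CONSENSUS)))
        )
        per_member_rate = (100.0 - identity) / 200.0
        for m in members:
            proteins[m] = _mutate_protein(rng, ancestor, per_member_rate)
    if config.segmental_pair:
        length = 220
        ancestor = (
            _random_protein(rng, 50)
            + _mutate_protein(rng, "M" + ACD_CONSENSUS, config.acd_mutation_rate)[1:]
            + "".join(rng.choice(list(AA20), size=length - 50 - len(ACD_CONSENSUS)))
        )
        for m in (seg_a, seg_b):
            if m not in proteins:
                proteins[m] = _mutate_protein(rng, ancestor, 0.07)
    for i in range(1, n + 1):
        if i in proteins:
            continue
        length = int(rng.integers(config.min_protein_len, config.max_protein_len))
        nt_len = max(10, int(rng.integers(10, max(11, length - len(ACD_CONSENSUS) - 5))))
        ct_len = max(5, length - nt_len - len(ACD_CONSENSUS))
        proteins[i] = (
            _random_protein(rng, nt_len)
            + _mutate_protein(rng, "M" + ACD_CONSENSUS, config.acd_mutation_rate)[1:]
            + "".join(rng.choice(list(AA20), size=ct_len))
        )

    # --- decoys: no-domain, oversized (domain but >42 kDa), undersized
    decoys: dict[str, str] = {}
    for d in range(config.decoy_genes):
        did = f"decoy{d + 1:02d}"
        kind = ("no_domain", "no_domain", "no_domain",
                "oversized", "oversized", "undersized")[d % 6]
        if kind == "no_domain":
            decoys[did] = _random_protein(rng, int(rng.integers(160, 260)))
        elif kind == "oversized":
            decoys[did] = (
                _random_protein(rng, 200)
                + _mutate_protein(rng, "M" + ACD_CONSENSUS, 0.15)[1:]
                + "".join(rng.choice(list(AA20), size=150))
            )
        else:
            decoys[did] = (
                _random_protein(rng, 6)
                + _mutate_protein(rng, "M" + ACD_CONSENSUS, 0.15)[1:]
            )

    # --- promoters with planted elements
    planted_spec = (config.planted_elements
                    if config.planted_elements is not None
                    else default_planted_elements(config))
    promoters: dict[int, str] = {}
    element_truth: dict[str, dict] = {}
    for i in range(1, n + 1):
        promoter, positions = _build_promoter(rng, 1500, planted_spec.get(i, {}))
        promoters[i] = promoter
        all_hits = brute_scan_both_strands(promoter)
        counts: dict[str, int] = {}
        for cls, _, _ in all_hits:
            counts[cls] = counts.get(cls, 0) + 1
        element_truth[config.gene_name(i)] = {
            "planted_positions": positions,
            "expected_counts": counts,
        }

    # --- gene bodies
    genebodies: dict[int, tuple[str, list]] = {}
    for i in range(1, n + 1):
        cds = back_translate(rng, proteins[i])
        genebodies[i] = _make_genebody(rng, cds, phases_plan[i])
    decoy_bodies = {did: (back_translate(rng, seq), None) for did, seq in decoys.items()}

    # --- chromosome assembly
    chrom_seqs: list[SequenceRecord] = []
    gene_models: list[GeneModel] = []
    decoy_ids = sorted(decoy_bodies)
    decoy_home = {}  # decoys appended to the least crowded chromosomes
    sparse = sorted(per_chrom, key=lambda c: len(per_chrom[c]))
    for k, did in enumerate(decoy_ids):
        decoy_home.setdefault(sparse[k % len(sparse)], []).append(did)

    for chrom_num in range(1, config.n_chromosomes + 1):
        chrom_name = f"chr{chrom_num:02d}"
        parts: list[str] = []
        cursor = 0  # 0-based length so far

        def _pad(nbp):
            nonlocal cursor
            parts.append(_random_dna(rng, nbp))
            cursor += nbp

        def _place(gene_id, promoter, genebody, exon_offsets, strand):
            nonlocal cursor
            construct = promoter + genebody
            G = len(genebody)
            locus_start = cursor
            if strand == "+":
                parts.append(construct)
                gene_start = locus_start + len(promoter) + 1  # 1-based
                gene_end = locus_start + len(construct)
                exons = [(gene_start + s, gene_start + e) for s, e in exon_offsets]
            else:
                parts.append(reverse_complement(construct))
                gene_start = locus_start + 1
                gene_end = locus_start + G
                exons = [(locus_start + G - e, locus_start + G - s)
                         for s, e in exon_offsets]  # transcription order
            cursor += len(construct)
            gene_models.append(GeneModel(
                gene_id=gene_id, chromosome=chrom_name, strand=strand,
                start=gene_start, end=gene_end, exons=exons,
                cds_sequence="",  # filled below from the assembled chromosome
            ))

        _pad(int(rng.integers(8000, 15000)))
        genes_here = per_chrom[chrom_num]
        slot = 0
        while slot < len(genes_here):
            i = genes_here[slot]
            ci = cluster_of.get(i)
            if ci is not None and (slot == 0 or cluster_of.get(genes_here[slot - 1]) != ci):
                members, spacing, identity = clusters[ci]
                for k, m in enumerate(members):
                    strand = "-" if (m % 3 == 0) else "+"
                    body, offs = genebodies[m]
                    _place(config.gene_name(m), promoters[m], body, offs, strand)
                    if k < len(members) - 1:
                        _pad(int(spacing))
                slot += len(members)
            else:
                strand = "-" if (i % 3 == 0) else "+"
                body, offs = genebodies[i]
                _place(config.gene_name(i), promoters[i], body, offs, strand)
                slot += 1
            if slot < len(genes_here):
                _pad(config.intergenic_gap_bp)
        for did in decoy_home.get(chrom_num, []):
            _pad(config.intergenic_gap_bp)
            body, _ = decoy_bodies[did]
            _place(did, _random_dna(rng, 1500), body, [(0, len(body) - 1)], "+")
        if cursor > config.chromosome_length_bp:
            raise ValueError(
                f"{chrom_name}: content needs {cursor} bp but "
                f"chromosome_length_bp is {config.chromosome_length_bp}"
            )
        _pad(config.chromosome_length_bp - cursor)
        chrom_seqs.append(SequenceRecord(chrom_name, "".join(parts)))

    # fill CDS sequences from the assembled chromosomes
    chrom_lookup = {c.id: c.residues for c in chrom_seqs}
    for g in gene_models:
        seq = chrom_lookup[g.chromosome]
        pieces = [seq[s - 1:e] for s, e in sorted(g.exons)]
        cds = "".join(pieces)
        g.cds_sequence = reverse_complement(cds) if g.strand == "-" else cds

    family_ids = [config.gene_name(i) for i in range(1, n + 1)]
    all_proteins = {config.gene_name(i): proteins[i] for i in range(1, n + 1)}
    all_proteins.update(decoys)

    annotations = {}
    for i in range(1, n + 1):
        gid = config.gene_name(i)
        if i % 3 == 0:
            annotations[gid] = "hypothetical protein"
        elif i % 2 == 0:
            annotations[gid] = "Hsp20 family protein"
        else:
            annotations[gid] = "17.6 kDa class I small heat shock protein-like"
    for k, did in enumerate(decoy_ids):
        annotations[did] = "heat shock factor" if k == 0 else "hypothetical protein"

    # --- collinearity block table for the segmental pair
    blocks_rows = []
    if config.segmental_pair:
        ga = next(g for g in gene_models if g.gene_id == config.gene_name(seg_a))
        gb = next(g for g in gene_models if g.gene_id == config.gene_name(seg_b))
        L = config.segmental_block_length_bp
        blocks_rows.append({
            "block_id": "B1", "chr_a": ga.chromosome, "chr_b": gb.chromosome,
            "gene_a": ga.gene_id, "gene_b": gb.gene_id,
            "block_start_a": max(1, ga.start - L // 2),
            "block_end_a": max(1, ga.start - L // 2) + L - 1,
            "block_start_b": max(1, gb.start - L // 2),
            "block_end_b": max(1, gb.start - L // 2) + L - 1,
        })
    blocks = pd.DataFrame(blocks_rows, columns=[
        "block_id", "chr_a", "chr_b", "gene_a", "gene_b",
        "block_start_a", "block_end_a", "block_start_b", "block_end_b"])

    fold_truth = (config.fold_change_truth
                  if config.fold_change_truth is not None
                  else default_fold_truth(config))
    truth = {
        "family_members": family_ids,
        "decoys": decoy_ids,
        "clusters": [[config.gene_name(m) for m in members]
                     for members, _, _ in clusters],
        "tandem_gene_count": sum(len(members) for members, _, _ in clusters),
        "segmental_pair": ([config.gene_name(seg_a), config.gene_name(seg_b)]
                           if config.segmental_pair else []),
        "intron_counts": {config.gene_name(i): len(phases_plan[i])
                          for i in range(1, n + 1)},
        "intron_phases": {config.gene_name(i): phases_plan[i]
                          for i in range(1, n + 1)},
        "intron_class_counts": {
            "1": sum(1 for p in phases_plan.values() if len(p) == 0),
            "2": sum(1 for p in phases_plan.values() if len(p) == 1),
            "3": sum(1 for p in phases_plan.values() if len(p) >= 2),
        },
        "elements": element_truth,
        "silent_genes": [config.gene_name(i) for i in config.silent_gene_indices],
        "fold_changes": {config.gene_name(i): folds
                         for i, folds in fold_truth.items()},
        "up_extreme": [config.gene_name(i) for i in config.up_extreme_indices],
    }
    return SimulatedGenome(
        config=config, chromosomes=chrom_seqs, gene_models=gene_models,
        family_ids=family_ids, proteins=all_proteins,
        annotations=annotations, blocks=blocks, truth=truth,
    )


# ---------------------------------------------------------------------------
# expression simulation


def simulate_fpkm(config: SimulationConfig | None = None,
                  seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Tissue FPKM matrix plus per-condition control/stress matrices.

    Baselines are log-normal per gene x tissue; silent genes sit near
    zero everywhere; each stress matrix is the control scaled by the true
    fold change with multiplicative log-normal noise.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    genes = [config.gene_name(i) for i in range(1, config.n_family_genes + 1)]
    silent = {config.gene_name(i) for i in config.silent_gene_indices}
    fold_truth = (config.fold_change_truth
                  if config.fold_change_truth is not None
                  else default_fold_truth(config))

    base = rng.lognormal(mean=3.0, sigma=1.0, size=(len(genes), len(config.tissues)))
    tissue = pd.DataFrame(base, index=genes, columns=list(config.tissues))
    for g in silent:
        tissue.loc[g] = rng.uniform(0.0, 0.05, size=len(config.tissues))

    out = {"tissues": tissue}
    control = rng.lognormal(mean=3.0, sigma=0.5, size=len(genes))
    control_df = pd.DataFrame({"24h": control}, index=genes)
    for g in silent:
        control_df.loc[g, "24h"] = rng.uniform(0.0, 0.05)
    out["control"] = control_df
    for cond in config.conditions:
        folds = np.array([fold_truth[i][cond] for i in range(1, len(genes) + 1)])
        noise = rng.lognormal(mean=0.0, sigma=config.fpkm_noise_sdlog, size=len(genes))
        out[cond] = pd.DataFrame(
            {"24h": control_df["24h"].to_numpy() * folds * noise}, index=genes)
    return out


def simulate_qpcr(config: SimulationConfig | None = None,
                  seed: int | None = None,
                  reference_gene: str = "ef1a") -> pd.DataFrame:
    """Long-format Cq table with dilution series and full replicate structure.

    Cq = intercept + slope * log10(quantity) + Gaussian noise. The
    dilution series covers 3/9/27/81-fold; samples span every condition x
    timepoint with 3 biological x 2 technical replicates. The reference
    gene's quantity is constant across conditions; target quantities
    follow the planted fold changes at the stress timepoints.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    eff = config.qpcr_efficiency_pct / 100.0
    slope = -1.0 / np.log10(1.0 + eff)
    fold_truth = (config.fold_change_truth
                  if config.fold_change_truth is not None
                  else default_fold_truth(config))
    genes = [config.gene_name(i) for i in range(1, config.n_family_genes + 1)]
    rows = []
    for gi, gene in enumerate(genes + [reference_gene], start=1):
        intercept = float(rng.uniform(20.0, 26.0))
        for dilution in (3, 9, 27, 81):
            for tech in (1, 2):
                cq = intercept + slope * np.log10(1.0 / dilution)
                cq += rng.normal(0.0, config.qpcr_noise_sd)
                rows.append({"gene": gene, "condition": "", "timepoint": "",
                             "bio_rep": 1, "tech_rep": tech,
                             "cq": round(float(cq), 4), "standard": dilution})
        base_q = 0.05
        for cond in config.conditions:
            for tp in config.timepoints:
                if gene == reference_gene:
                    fold = 1.0
                else:
                    fold = 1.0 if tp == "0h" else fold_truth[gi]["" + cond]
                for bio in (1, 2, 3):
                    for tech in (1, 2):
                        q = base_q * fold
                        cq = intercept + slope * np.log10(q)
                        cq += rng.normal(0.0, config.qpcr_noise_sd)
                        rows.append({"gene": gene, "condition": cond,
                                     "timepoint": tp, "bio_rep": bio,
                                     "tech_rep": tech,
                                     "cq": round(float(cq), 4), "standard": 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# labeled sequence families for phylogeny tests


def simulate_labeled_family(
    n_subfamilies: int = 4,
    refs_per_subfamily: int = 2,
    queries_per_subfamily: int = 2,
    n_outgroup_queries: int = 3,
    seq_length: int = 300,
    between_divergence: float = 0.45,
    within_divergence: float = 0.05,
    outgroup_divergence: float = 0.55,
    seed: int = 0,
):
    """Reference-labeled subfamily sequences plus out-of-subfamily queries.

    Each subfamily descends from its own ancestor (mutated
    ``between_divergence`` from a global root). References form a serial
    ladder within the subfamily and each query descends from a specific
    reference, so in-subfamily query placements are strongly supported
    sister pairs. Outgroup queries are independent divergent lineages
    straight from the root — their attachment to any labeled clade
    carries no phylogenetic signal, mirroring family members too
    divergent to join a subfamily. Returns (records, reference_labels,
    query_truth).
    """
    if n_subfamilies < 2 and n_outgroup_queries:
        raise ValueError("outgroup queries need at least two subfamilies")
    rng = np.random.default_rng(seed)
    root = _random_protein(rng, seq_length)
    records, labels, truth = [], {}, {}
    # subfamilies descend pairwise from shared stem ancestors; a midpoint
    # on the root->stem path lets outgroup lineages branch strictly below
    # a pair of labeled clades (their nearest clade then mixes two labels)
    stems, mids = [], []
    for k in range(n_subfamilies):
        if k % 2 == 0:
            mids.append(_mutate_protein(rng, root, between_divergence / 4))
            stems.append(_mutate_protein(rng, mids[-1], between_divergence / 4))
        name = f"SF{k + 1}"
        lineage = _mutate_protein(rng, stems[-1], between_divergence / 2)
        ref_seqs = []
        for r in range(refs_per_subfamily):
            lineage = _mutate_protein(rng, lineage, within_divergence)
            rid = f"{name}_ref{r + 1}"
            records.append(SequenceRecord(rid, lineage))
            labels[rid] = name
            ref_seqs.append(lineage)
        for q in range(queries_per_subfamily):
            parent = ref_seqs[q % len(ref_seqs)]
            qid = f"{name}_query{q + 1}"
            records.append(
                SequenceRecord(qid, _mutate_protein(rng, parent,
                                                    within_divergence / 2)))
            truth[qid] = name
    # out-of-subfamily queries: lineages branching from a midpoint, basal
    # to a subfamily pair — their nearest reference-containing clade mixes
    # the pair's two labels
    full_mids = [m for i, m in enumerate(mids) if 2 * i + 1 < n_subfamilies]
    for q in range(n_outgroup_queries):
        qid = f"out_query{q + 1}"
        mid = full_mids[q % len(full_mids)]
        records.append(SequenceRecord(qid, _mutate_protein(rng, mid,
                                                           outgroup_divergence / 2)))
        truth[qid] = "UNCLASSIFIED"
    return records, labels, truth
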