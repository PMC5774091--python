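# familyscan

Genome-wide analysis of plant gene families defined by a conserved protein
domain — built around the small heat shock protein (Hsp20) family, whose
members carry the ~113-residue alpha-crystallin domain (ACD) and fall in
the 15–42 kDa range. The package turns the standard survey workflow into a
reusable, tested pipeline:

1. **Identification** — three-way candidate search (ACD log-odds profile
   scan, Smith–Waterman similarity search with Karlin–Altschul E-values,
   annotation keyword match), deduplication, confirmation by domain
   presence and the 15 ≤ MW ≤ 42 kDa window, and positional naming along
   chromosomes.
2. **Gene structure** — exon–intron structure from GFF3, donor-side intron
   phases (cumulative coding length mod 3), the three intron-pattern
   classes (0 / 1 / ≥2 introns), and occurrence scanning of the family's
   ten consensus protein motifs.
3. **Duplication** — tandem clusters (same chromosome, ≤5 intervening
   genes, 100-kb window per adjacent pair, plus the strict >70% coverage
   and >70% identity duplicate-pair criterion) and segmental pairs
   anchored in a collinearity-block table.
4. **Phylogeny** — progressive multiple alignment (UPGMA guide tree +
   profile–profile Needleman–Wunsch), Saitou–Nei neighbor joining on
   p-distances, column-resampling bootstrap, and subfamily assignment of
   queries to the smallest well-supported reference-labeled clade
   (CI–CVII, MI/MII, P, Po, ER).
5. **Promoters** — 1.5-kb upstream windows scanned on both strands for six
   stress-element classes (ABRE, DRE, HSE, LTRE, TC-rich, W-box) as exact
   IUPAC consensus matches.
6. **Expression** — grand-mean log2 FPKM heatmap transform, tissue
   expressed/silent calls, stress/control ratios, and qPCR standard-curve
   relative expression (Cq regressed on log10 quantity; fold changes
   normalized to a reference gene and the control sample) with response
   classes, including the >100-fold "extremely up-regulated" call.
7. **Synthetic data** — a generator that plants a 48-member family on 12
   chromosomes with controlled tandem clusters, one segmental pair,
   chosen intron phases, promoter elements at recorded positions, silent
   genes and true fold changes — so every stage is testable against known
   truth without downloads.

A transcription of the published 48-member potato family feature table
(name, locus, ORF/exon/AA counts, MW, pI) and the ten motif consensus
strings ship as packaged fixtures; every row satisfies ORF = 3 × (AA + 1).

## Worked example

```python
from familyscan import genome_io, structure, duplication, synthetic_data

# printed family table: intron classes and positional tandem candidates
rows = genome_io.load_family_table()
print(structure.summarize_intron_classes(rows))
#    pattern_class  count  percent
# 0              1     20     41.7
# 1              2     23     47.9
# 2              3      5     10.4

clusters = duplication.find_tandem_clusters(genome_io.family_table_models(rows))
print([(c.chromosome, len(c)) for c in clusters if c.chromosome == "6"])
# [('6', 5)]    <- the five-gene tandem block on chromosome 6

# synthetic genome with known truth, end to end
sim = synthetic_data.generate_genome(synthetic_data.SimulationConfig(seed=1))
fam = {k: sim.proteins[k] for k in sim.family_ids}
clusters = duplication.find_tandem_clusters(
    sim.family_models, full_annotation=sim.gene_models, proteins=fam)
print(duplication.duplication_summary(clusters, [], 48)["tandem_gene_pct"])
# 39.6          <- 19 of 48 genes in clusters of sizes 5/4/3/3/2/2
```

The first block says that 20 family genes (41.7%) are intronless, 23
(47.9%) carry one intron and 5 (10.4%) carry two or more, and that the
printed coordinates put five genes in one tandem block on chromosome 6.
The second block shows the detector recovering the planted 19-gene tandem
complement (39.6% of the family) on a synthetic genome.

The same stages are scriptable from the shell:

```sh
familyscan simulate --seed 1 --out sim/
familyscan structure --gff sim/annotation.gff3 --genome sim/genome.fa
familyscan run --config pipeline.yaml
```

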