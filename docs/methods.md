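# Methods

This note documents the models, conventions and numerical choices behind
familyscan, and what the synthetic-data generator does and does not
emulate.

## Coordinates and gene models

All genomic coordinates are 1-based inclusive internally (matching GFF3
and the packaged family table); BED output converts to 0-based half-open
at the boundary and the conversion is bijective. Gene models hold their
coding exons in transcription order, so minus-strand models list exons in
descending genomic coordinates and all downstream arithmetic (intron
phases, CDS assembly) is strand-free. Genes with several mRNAs keep the
transcript with the longest total CDS — one protein per gene, the
convention of family surveys. The packaged family table records ORF
lengths that include the stop codon, hence the invariant
ORF = 3 × (AA + 1), which is checked on load for every row; `translate_cds`
accordingly drops the terminal stop, and the initiator Met counts as a
residue (an ORF of 6 nt encodes the 1-residue peptide "M").

The printed table does not state strand, so table-derived models carry
strand "?" and support only positional operations; promoter extraction
and CDS assembly require GFF3 input.

## Domain profile and membership criteria

Family membership is defined by the alpha-crystallin domain. The scan
uses a per-column log-odds matrix (PSSM, bits against a uniform
background, pseudocount 0.5) built from a packaged seed alignment. The
seed (`acd_seed_synthetic.afa`) is synthetic: twenty sequences derived
from the family's 113-residue domain consensus motif at ~15% per-column
substitution, committed once as a fixture. The scan is glocal and
ungapped: the full profile slides along the protein and the best window
is kept when it clears the threshold.

The default threshold is 30 bits. For a >100-column profile the score
gap is enormous — genuine domain copies at 70–95% identity score in the
hundreds of bits while shuffled or unrelated proteins score far below
zero — so the empirical false-positive rate per scan is well under the
10⁻³ that the membership criterion targets (the test suite verifies ≤5%
of 100 shuffles, and in practice observes none). Proteins shorter than
the profile cannot carry the full domain and return no hit.

The similarity search is Smith–Waterman (BLOSUM62, gap open 11 /
extend 1) with a Karlin–Altschul E-value E = K·m·n·exp(−λS) using the
ungapped BLOSUM62 parameters λ = 0.267, K = 0.041. This is an
approximation — gapped statistics differ — but the membership criterion
is a coarse E ≤ 10⁻³ cutoff, not a fine statistic. Confirmation requires
a domain hit and an average-mass molecular weight inside the closed
interval [15, 42] kDa. MW and pI use the ExPASy conventions (average
residue masses plus one water; Bjellqvist pKa set with bisection to
0.01 pH), via Biopython's ProtParam.

Naming sorts confirmed genes by (numeric chromosome, start), ties broken
by gene id, and assigns prefix-1..N.

## Structure and motifs

Intron phase i is the cumulative coding length 5′ of intron i modulo 3
(donor-side convention; 0 = between codons). Pattern classes: 1 = no
intron, 2 = one intron, 3 = two or more. Motif occurrence scanning slides
each consensus string along the protein and scores windows by ungapped
BLOSUM62 similarity; windows scoring at least a fraction f = 0.5
(configurable) of the consensus self-score are reported. The threshold
is a design choice — the original motif discovery tools report sites by
E-value, which has no analogue for a fixed consensus string.

## Duplication

A duplicate pair requires, from a global (Needleman–Wunsch, BLOSUM62,
gap open 10 / extend 0.5) alignment: coverage > 70% (aligned columns
over the longer sequence's length) and identity > 70% (matches over
aligned columns), both strict. "Similarity" is interpreted as percent
identity, the convention of the criteria literature this rule descends
from. Tandem relations additionally require the same chromosome, at most
five intervening genes (counted in the full annotation when available,
else among family members with a warning), and a 100-kb window applied
per adjacent pair; clusters are connected components of the relation, so
a chain a–b–c is one cluster even if a–c fails pairwise. Note that on
the packaged table's coordinates the two chromosome-8 genes at ~34.4 Mb
are 179 kb apart and therefore are *not* positional candidates; the
positional candidate set is eight clusters of 21 genes, which the
sequence criterion reduces to the published 19. Segmental pairs are read
from a user-supplied MCScanX-like block table (the original analysis
performed a database lookup; computing whole-genome synteny is out of
scope), and the synthetic generator emits such a table.

## Phylogeny

The aligner is classical progressive alignment: pairwise global-alignment
distances (1 − identity), a UPGMA guide tree (deterministic smallest-index
tie-breaks), and profile–profile Needleman–Wunsch merges with expected
BLOSUM62 column scores (gap symbol scores 0, linear gap penalty −4 per
column, diagonal-first traceback). It is deterministic for a fixed input
order. Distances are p-distances with pairwise deletion; a Poisson
correction is available but off by default since the original analysis
does not state a distance model.

Neighbor joining is the Saitou–Nei algorithm with Q-matrix ties broken by
the smallest index pair and negative branch lengths clamped to zero; it
reconstructs any additive matrix exactly (property-tested against a
brute-force path-length oracle and cross-checked against an independent
implementation). Bootstrap resamples alignment columns with replacement;
support is the percentage of replicates containing each internal
bipartition of the point tree.

Divergent sequences are excluded before tree building when their mean
pairwise global-alignment identity falls below 0.40 or fewer than 30% of
alignment columns carry one of their residues, then the remainder is
realigned. The 0.40 figure is calibrated, not arbitrary: optimal global
alignment of *unrelated* proteins yields ~29% identity over aligned
columns (the aligner selects matching columns, so unrelated identity is
far above the naive 1/20), while family members sharing the domain sit
near or above 0.48; a threshold between the two separates cleanly.

Subfamily assignment anchors queries to labeled references: over both
sides of every tree edge (equivalently, every clade under any rooting),
the smallest side containing the query and at least one reference decides
the label, provided (a) all references in it share one label, (b) the
side's edge support meets the threshold (default 50; edges without a
bootstrap label count as supported), and (c) no equally small side
disagrees — conflicting ties stay UNCLASSIFIED. References keep their own
labels, and no label outside the reference set is ever assigned.

## Promoters

The promoter is the 1.5-kb window upstream of the translation start
(reverse-complemented for minus-strand genes), truncated and flagged at
contig edges; zero upstream bases means "promoter absent", mirroring how
published surveys report unscannable members. Scanning is exact IUPAC
matching on both strands; no mismatches, no position-weight scoring —
determinism over sensitivity, since the reference database's private
matrices are not reproducible. The default pattern table (ABRE ACGTG,
YACGTGGC; DRE RCCGAC; HSE NGAANNTTCN, AGAANNTTCT; LTRE CCGAAA; TC-rich
ATTTTCTTCA, GTTTTCTTAC; W-box TTGACY) follows the six element classes'
canonical consensus strings and is user-overridable as a TSV. Positions
are 1-based upstream distances of the match base nearest the ATG, so
position 1 is adjacent to the start codon and the mirror property holds:
reverse-complementing a promoter maps position p to L − p − w + 2 with
the strand flipped.

## Expression

The heatmap transform is log2((x + pc) / mean(x + pc)) with the *grand*
mean over the whole matrix (a per-gene option exists but is off by
default — the wording of the procedure this follows is global). The
pseudocount defaults to 0.01 to keep zero FPKM finite. "Expressed"
defaults to FPKM ≥ 1.

qPCR quantification uses the standard-curve method, not ΔΔCq: each
gene's dilution series (3-, 9-, 27-, 81-fold) is regressed as Cq on
log10(relative quantity); efficiency is (10^(−1/slope) − 1) × 100, so a
perfect-doubling chemistry gives slope −3.3219 and 100%. Per well,
quantity is interpolated from the gene's own curve, normalized by the
reference gene (ef1α), technical replicates averaged within each
biological replicate, folds taken against the control sample's mean, and
mean ± SD reported over the three biological replicates. Response
classes: up_extreme if any stress timepoint exceeds 100-fold, up at
≥2-fold, down at ≤0.5-fold, else no change (all configurable). Genes
without sample wells yield NA rows.

A statistical caveat the tests respect: with a 4-point dilution series
and Cq noise σ = 0.1, the fitted slope's ~2% standard error is amplified
exponentially over the 2.2-decade extrapolation to a 150-fold change,
giving ~10% fold error at one sigma. Recovery of planted folds within
15% is therefore asserted on the mean over seeded replicate experiments,
and the slope estimator is checked for unbiasedness with the spread
least-squares theory predicts — single noisy runs can and do stray
further, as they would on a real instrument.

## Synthetic data

The generator is a pure function of (config, seed) and emulates the
shape of a real survey: 48 members on 12 chromosomes (counts
4/2/4/5/1/5/2/5/9/3/2/6), tandem clusters of sizes 3/5/3/4/2/2 at 3-kb
spacing and 95% identity targets, one cross-chromosome segmental pair
anchored in an emitted 625-kb block, a 20/23/5 intron-class split with
the segmental pair sharing the conserved 1,2,0,0,0 phase run, two silent
genes, fourteen >100-fold heat responders, and six decoy genes that lack
the domain or violate the MW window. Introns are 200–2000 bp with GT..AG
boundaries at chosen codon phases; back-translation draws uniformly over
synonymous codons. Promoter backgrounds are scrubbed (re-randomized)
until the only element matches are those the planted instances produce,
with an independent brute-force IUPAC matcher — not the scanner under
test — building the truth table. Non-cluster genes sit 120 kb apart so
positional candidates are exactly the planted clusters.

What it does *not* emulate: realistic genome composition (repeats, GC
structure), UTRs and non-coding exons, alternative splicing, codon-usage
bias, read-level RNA-seq, or pseudogenes. Passing the recovery suites
therefore demonstrates correctness of the algorithms under the stated
criteria, not robustness to every artifact of real annotations.

The labeled-family simulator for subfamily tests builds a known tree:
subfamilies descend pairwise from stem ancestors (~45% between-subfamily
divergence, ~5% within), references form a serial ladder so internal
edges carry signal, each in-subfamily query descends from a specific
reference (a strongly supported sister pair), and out-of-subfamily
queries branch from a midpoint strictly below a subfamily pair — their
nearest reference-containing clade then mixes two labels, which is what
makes them structurally unclassifiable rather than merely poorly
supported. Naive alternatives (independent long branches) fail
instructively: long-branch attraction groups them with high bootstrap
support, a systematic artifact that column resampling reproduces.

## Problem sizes and determinism

Default test and acceptance runs use the 48-gene synthetic genome
(12 × 0.8 Mb chromosomes), 100 bootstrap replicates on 19-leaf labeled
trees, 8 seeded qPCR replicate experiments, and 1000-draw Monte Carlo
for the slope estimator — sizes chosen so the whole suite completes in
about a minute while keeping every recovery exact. All randomness flows
from explicit seeds; reruns are byte-identical.

## Known limitations

- The progressive aligner is a baseline implementation; for 48
  heterogeneous members it can misplace a domain in a worst-case row,
  which is why divergence flagging uses pairwise identities rather than
  MSA columns.
- E-values are ungapped approximations; borderline hits near 10⁻³
  should not be over-interpreted.
- Exact IUPAC promoter matching undercounts degenerate elements relative
  to matrix-based scanners; counts are comparable only within a pattern
  table.
- The duplicate-pair "similarity" is percent identity; a BLOSUM-positive
  rate option would classify borderline ancient duplicates differently.
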