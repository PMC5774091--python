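"""Family-membership identification.

Candidates are gathered three ways — a domain-profile scan, a BLASTP-like
local-alignment search against known family proteins, and an annotation
keyword search — then deduplicated and confirmed by requiring (i) a hit to
the family domain profile and (ii) a molecular weight inside the 15–42 kDa
window that defines small heat shock proteins. Confirmed genes are named
by chromosomal position.

The domain profile is a per-column log-odds matrix (PSSM) built from an
ungapped seed alignment of alpha-crystallin-domain (ACD) sequences; the
scan slides the full profile along the protein (glocal, no gaps) and keeps
the best-scoring window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .genome_io import GeneModel, SequenceRecord, load_acd_seed

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

GENETIC_CODE_STOPS = {"TAA", "TAG", "TGA"}

# Ungapped Karlin–Altschul parameters for BLOSUM62 (approximate; the
# membership criterion is a coarse E <= 1e-3 cutoff, not a fine statistic).
KA_LAMBDA = 0.267
KA_K = 0.041

MW_MIN_KDA = 15.0
MW_MAX_KDA = 42.0

DEFAULT_KEYWORDS = ("Hsp20", "small heat shock protein")


class CdsError(ValueError):
    """A CDS that cannot be translated as a clean ORF."""


def translate_cds(cds: str) -> str:
    """Translate an ATG..stop CDS with the standard code, dropping the stop.

    Rejects (with a reason) CDS that do not start with ATG, do not end in a
    stop codon, contain an internal stop, or whose length is not a multiple
    of three.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise CdsError(f"length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        raise CdsError(f"does not start with ATG (saw {cds[:3]})")
    if cds[-3:] not in GENETIC_CODE_STOPS:
        raise CdsError(f"does not end with a stop codon (saw {cds[-3:]})")
    from Bio.Seq import Seq

    protein = str(Seq(cds[:-3]).translate(table=1))
    if "*" in protein:
        raise CdsError(f"internal stop codon at codon {protein.index('*') + 1}")
    return protein


def compute_mw(protein: str) -> float:
    """Average-isotope molecular weight in Daltons (residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein")
    return ProteinAnalysis(protein).molecular_weight()


def compute_pi(protein: str) -> float:
    """Theoretical isoelectric point (Bjellqvist pKa set, bisection to 0.01 pH)."""
    if not protein:
        raise ValueError("empty protein")
    return ProteinAnalysis(protein).isoelectric_point()


# ---------------------------------------------------------------------------
# Domain profile scan


@dataclass
class DomainProfile:
    """Per-position log-odds scores (bits) for an ungapped domain model."""

    columns: np.ndarray  # shape (length, 20)
    score_threshold: float
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.columns.argmax(axis=1))

    def self_score(self) -> float:
        return float(self.columns.max(axis=1).sum())


@dataclass
class DomainHit:
    protein_id: str
    start: int  # 1-based on the protein
    end: int
    score: float


def build_profile(
    seed: list[SequenceRecord] | None = None,
    pseudocount: float = 0.5,
    score_threshold: float = 30.0,
) -> DomainProfile:
    """Build a log-odds PSSM from an ungapped, equal-width seed alignment.

    The default threshold (bits) is far above the score a shuffled protein
    reaches for a >100-column profile, keeping the empirical false-positive
    rate per scan below 1e-3, and far below the score of genuine domain
    copies at 70%+ identity.
    """
    if seed is None:
        seed = load_acd_seed()
    width = len(seed[0].residues)
    if any(len(s.residues) != width for s in seed):
        raise ValueError("seed alignment rows must have equal width")
    counts = np.full((width, 20), pseudocount)
    for rec in seed:
        for i, aa in enumerate(rec.residues):
            if aa in AA_INDEX:
                counts[i, AA_INDEX[aa]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    background = np.full(20, 1.0 / 20)
    columns = np.log2(freqs / background)
    return DomainProfile(columns=columns, score_threshold=score_threshold,
                         background=background)


def scan_domain(protein, profile: DomainProfile) -> DomainHit | None:
    """Best ungapped window of the profile along the protein, or None.

    Proteins shorter than the profile cannot carry the full domain and
    return None.
    """
    pid, seq = _as_id_seq(protein)
    L, W = len(seq), profile.length
    if L < W:
        return None
    idx = np.array([AA_INDEX.get(aa, -1) for aa in seq])
    best_score, best_start = -math.inf, 0
    cols = profile.columns
    for off in range(L - W + 1):
        window = idx[off:off + W]
        valid = window >= 0
        score = cols[np.arange(W)[valid], window[valid]].sum()
        if score > best_score:
            best_score, best_start = score, off
    if best_score < profile.score_threshold:
        return None
    return DomainHit(protein_id=pid, start=best_start + 1,
                     end=best_start + W, score=float(best_score))


# ---------------------------------------------------------------------------
# Local-alignment (BLASTP-like) search


@dataclass
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float  # raw Smith-Waterman score
    bit_score: float
    evalue: float
    identity_pct: float


def _as_id_seq(rec) -> tuple[str, str]:
    if isinstance(rec, SequenceRecord):
        return rec.id, rec.residues
    return "query", str(rec)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _alignment_identity(alignment) -> float:
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    return 100.0 * counts.identities / aligned if aligned else 0.0


def similarity_search(
    queries: list[SequenceRecord],
    database: list[SequenceRecord],
    evalue_max: float = 1e-3,
) -> list[SimilarityHit]:
    """Smith–Waterman search of every query against every database protein.

    Scores use BLOSUM62 with gap open 11 / extend 1; significance is a
    Karlin–Altschul E-value E = K·m·n·exp(−λS) against the total database
    length. Hits with E <= evalue_max are returned, best first.
    """
    if not database:
        return []
    aligner = _local_aligner()
    db_len = sum(len(s.residues) for s in database)
    hits = []
    for q in queries:
        for s in database:
            alns = aligner.align(q.residues, s.residues)
            if len(alns) == 0:
                continue
            aln = alns[0]
            raw = aln.score
            if raw <= 0:
                continue
            bit = (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)
            evalue = KA_K * len(q.residues) * db_len * math.exp(-KA_LAMBDA * raw)
            if evalue <= evalue_max:
                hits.append(SimilarityHit(q.id, s.id, float(raw), bit, evalue,
                                          _alignment_identity(aln)))
    hits.sort(key=lambda h: (h.evalue, h.query_id, h.subject_id))
    return hits


def keyword_search(annotations: dict[str, str],
                   keywords=DEFAULT_KEYWORDS) -> set[str]:
    """Ids whose description contains any keyword, case-insensitively."""
    lowered = [k.lower() for k in keywords]
    return {
        pid for pid, desc in annotations.items()
        if any(k in desc.lower() for k in lowered)
    }


# ---------------------------------------------------------------------------
# Candidate union and confirmation


@dataclass
class CandidateSet:
    """Union of candidate protein ids with per-id provenance flags."""

    provenance: dict[str, set] = field(default_factory=dict)

    def add(self, ids, source: str) -> None:
        for pid in ids:
            self.provenance.setdefault(pid, set()).add(source)

    @property
    def ids(self) -> set[str]:
        return set(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)


def gather_candidates(
    proteome: list[SequenceRecord],
    profile: DomainProfile,
    reference_family: list[SequenceRecord] | None = None,
    annotations: dict[str, str] | None = None,
    evalue_max: float = 1e-3,
    keywords=DEFAULT_KEYWORDS,
) -> CandidateSet:
    """Run the three-way search and union the results."""
    cands = CandidateSet()
    cands.add((p.id for p in proteome if scan_domain(p, profile)), "hmm_search")
    if reference_family:
        hits = similarity_search(reference_family, proteome, evalue_max)
        cands.add({h.subject_id for h in hits}, "blast_like")
    if annotations:
        cands.add(keyword_search(annotations, keywords), "keyword")
    return cands


def confirm_members(
    candidates: CandidateSet,
    proteins: dict[str, str],
    profile: DomainProfile,
    mw_min_kda: float = MW_MIN_KDA,
    mw_max_kda: float = MW_MAX_KDA,
) -> list[str]:
    """Keep candidates with a confirmed domain hit and an in-window MW.

    Both bounds are inclusive; the result is sorted and independent of
    candidate provenance or insertion order.
    """
    kept = []
    for pid in sorted(candidates.ids):
        seq = proteins.get(pid)
        if seq is None:
            continue
        if scan_domain(SequenceRecord(pid, seq), profile) is None:
            continue
        mw_kda = compute_mw(seq) / 1000.0
        if mw_min_kda <= mw_kda <= mw_max_kda:
            kept.append(pid)
    return kept


def _chromosome_key(chromosome) -> tuple:
    """Numeric chromosome sort where possible ('chr2' < 'chr10')."""
    text = str(chromosome)
    digits = "".join(c for c in text if c.isdigit())
    return (0, int(digits)) if digits else (1, text)


def assign_names(genes: list[GeneModel], prefix: str = "Gene") -> dict[str, str]:
    """Name genes prefix-1..N by (chromosome, start), ties by gene_id."""
    keys = [( _chromosome_key(g.chromosome), g.start, g.gene_id) for g in genes]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (chromosome, start, gene_id) among genes")
    order = sorted(genes, key=lambda g: (_chromosome_key(g.chromosome), g.start, g.gene_id))
    return {g.gene_id: f"{prefix}-{i + 1}" for i, g in enumerate(order)}


@dataclass
class ProteinStats:
    aa_count: int
    mw_da: float
    pi: float


def protein_stats(protein: str) -> ProteinStats:
    return ProteinStats(aa_count=len(protein), mw_da=compute_mw(protein),
                        pi=compute_pi(protein))
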