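"""Distance-based phylogeny: progressive alignment, neighbor joining,
bootstrap support and reference-anchored subfamily assignment.

The aligner is a classical progressive scheme: a UPGMA guide tree from
pairwise global-alignment distances, then profile–profile Needleman–
Wunsch merges up the guide tree. Trees are built with Saitou–Nei neighbor
joining on p-distances (Poisson correction optional) and carried as
dendropy trees; bootstrap resamples alignment columns and reports the
percentage of replicates containing each internal bipartition.

Subfamilies are assigned by anchoring queries to labeled reference
leaves: the smallest side of any tree edge containing the query and at
least one reference decides the label, provided all references in it
agree and the supporting edge meets the support threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

SUBFAMILY_LABELS = ("CI", "CII", "CIII", "CIV", "CV", "CVI", "CVII",
                    "MI", "MII", "P", "Po", "ER")
UNCLASSIFIED = "UNCLASSIFIED"

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA)}
_GAP = 20  # index of the gap symbol in profile columns

# 21x21 scoring matrix: BLOSUM62 over residues, 0 against gaps
_B62 = substitution_matrices.load("BLOSUM62")
_SCORE21 = np.zeros((21, 21))
for _i, _a in enumerate(_AA):
    for _j, _b in enumerate(_AA):
        _SCORE21[_i, _j] = _B62[_a, _b]

_GAP_PENALTY = -4.0  # linear, per profile column


@dataclass
class MultipleAlignment:
    rows: dict[str, str]  # id -> gapped sequence

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")


# ---------------------------------------------------------------------------
# progressive alignment


def _pairwise_distance_matrix(seqs) -> np.ndarray:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _B62
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            counts = aln.counts()
            aligned = counts.identities + counts.mismatches
            ident = counts.identities / aligned if aligned else 0.0
            d[i, j] = d[j, i] = 1.0 - ident
    return d


def _upgma_guide(d: np.ndarray):
    """UPGMA merge order as nested tuples of input indices (deterministic)."""
    n = d.shape[0]
    active = {i: (i,) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    nodes = {i: i for i in range(n)}
    next_id = n
    while len(active) > 1:
        keys = sorted(active)
        best = None
        for x, i in enumerate(keys):
            for j in keys[x + 1:]:
                dij = dist[(min(i, j), max(i, j))]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        _, i, j = best
        merged = (active[i], active[j])
        for k in keys:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(next_id, k), max(next_id, k))] = new
        active[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        del active[i], active[j]
        next_id += 1
    return next(iter(active.values()))


class _Profile:
    """A partial alignment: per-column symbol counts + its gapped rows."""

    def __init__(self, counts: np.ndarray, order: list[int], rows: list[str]):
        self.counts = counts  # (ncols, 21)
        self.order = order  # input sequence indices, row order
        self.rows = rows

    @classmethod
    def from_sequence(cls, seq: str, index: int) -> "_Profile":
        counts = np.zeros((len(seq), 21))
        for i, aa in enumerate(seq):
            counts[i, _AA_INDEX.get(aa, _GAP)] += 1
        return cls(counts, [index], [seq])


def _merge_profiles(a: _Profile, b: _Profile) -> _Profile:
    fa = a.counts / a.counts.sum(axis=1, keepdims=True)
    fb = b.counts / b.counts.sum(axis=1, keepdims=True)
    S = fa @ _SCORE21 @ fb.T  # (la, lb) expected column score
    la, lb = S.shape
    dp = np.zeros((la + 1, lb + 1))
    trace = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    dp[1:, 0] = _GAP_PENALTY * np.arange(1, la + 1)
    dp[0, 1:] = _GAP_PENALTY * np.arange(1, lb + 1)
    trace[1:, 0] = 1
    trace[0, 1:] = 2
    for i in range(1, la + 1):
        diag = dp[i - 1, :-1] + S[i - 1]
        row = dp[i - 1, 1:] + _GAP_PENALTY  # up
        prev = dp[i, 0]
        for j in range(1, lb + 1):
            left = prev + _GAP_PENALTY
            best, t = diag[j - 1], 0
            if row[j - 1] > best:
                best, t = row[j - 1], 1
            if left > best:
                best, t = left, 2
            dp[i, j] = prev = best
            trace[i, j] = t
    # traceback
    cols_a, cols_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        t = trace[i, j]
        if t == 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            i, j = i - 1, j - 1
        elif t == 1:
            cols_a.append(i - 1)
            cols_b.append(None)
            i -= 1
        else:
            cols_a.append(None)
            cols_b.append(j - 1)
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    ncols = len(cols_a)
    counts = np.zeros((ncols, 21))
    rows_a = [[] for _ in a.rows]
    rows_b = [[] for _ in b.rows]
    for k in range(ncols):
        ca, cb = cols_a[k], cols_b[k]
        if ca is not None:
            counts[k] += a.counts[ca]
            for r, row in enumerate(a.rows):
                rows_a[r].append(row[ca])
        else:
            counts[k, _GAP] += len(a.rows)
            for r in range(len(a.rows)):
                rows_a[r].append("-")
        if cb is not None:
            counts[k] += b.counts[cb]
            for r, row in enumerate(b.rows):
                rows_b[r].append(row[cb])
        else:
            counts[k, _GAP] += len(b.rows)
            for r in range(len(b.rows)):
                rows_b[r].append("-")
    return _Profile(counts,
                    a.order + b.order,
                    ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b])


def progressive_align(seqs) -> MultipleAlignment:
    """Progressive multiple alignment (guide tree + profile NW merges).

    Deterministic for a fixed input order: guide-tree ties and DP
    traceback ties are broken by smallest index / diagonal-first.
    """
    from .identification import _as_id_seq

    pairs = [_as_id_seq(s) for s in seqs]
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        ids = [f"{pid}_{i}" if ids.count(pid) > 1 else pid
               for i, pid in enumerate(ids)]
    sequences = [p[1] for p in pairs]
    if len(sequences) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    d = _pairwise_distance_matrix(sequences)
    guide = _upgma_guide(d)

    def build(node) -> _Profile:
        # guide leaves are 1-tuples of input indices; internal nodes are pairs
        if len(node) == 1:
            return _Profile.from_sequence(sequences[node[0]], node[0])
        return _merge_profiles(build(node[0]), build(node[1]))

    profile = build(guide)
    rows = {ids[idx]: row for idx, row in zip(profile.order, profile.rows)}
    return MultipleAlignment(rows={pid: rows[pid] for pid in ids})


# ---------------------------------------------------------------------------
# distances


def p_distance(msa: MultipleAlignment, poisson: bool = False) -> DistanceMatrix:
    """Pairwise-deletion p-distance (optionally Poisson-corrected)."""
    ids = msa.ids
    arr = np.array([list(msa.rows[i]) for i in ids])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != "-") & (arr[j] != "-")
            compared = int(both.sum())
            if compared == 0:
                warnings.warn(f"no comparable columns between {ids[i]} and {ids[j]}")
                dij = 1.0
            else:
                dij = float((arr[i][both] != arr[j][both]).sum()) / compared
            if poisson:
                dij = -math.log(max(1.0 - dij, 1e-10))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=ids, d=d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; unrooted tree with clamped branch lengths.

    Ties in the Q matrix are broken by the smallest (i, j) index pair, so
    the topology is deterministic.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(t)) for t in dm.ids]
    d = dm.d.copy()
    active = list(range(n))

    def clamp(x):
        return max(0.0, float(x))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        gi, gj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[gi].edge.length = clamp(li)
        nodes[gj].edge.length = clamp(lj)
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        # distances from the new node to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        gk = d.shape[0] - 1
        for k in range(m):
            if k in (i, j):
                continue
            gk2 = active[k]
            d[gk, gk2] = d[gk2, gk] = 0.5 * (sub[i, k] + sub[j, k] - dij)
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [gk]

    # join the last three nodes on a central (unrooted) vertex
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for g, ln in ((a, la), (b, lb), (c, lc)):
        nodes[g].edge.length = clamp(ln)
        root.add_child(nodes[g])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Internal bipartitions as canonical leaf-label frozensets.

    The canonical form of a split is the side NOT containing the
    lexicographically smallest leaf, so it is rooting-invariant.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = leaves[0]
    all_set = frozenset(leaves)
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(leaves) - 1:
            continue
        canon = below if anchor not in below else all_set - below
        out[canon] = node
    return out


def bootstrap_support(
    seqs,
    n_reps: int = 100,
    seed: int = 0,
    msa: MultipleAlignment | None = None,
    poisson: bool = False,
) -> dendropy.Tree:
    """Point NJ tree with bootstrap supports (% of column-resampled
    replicates containing each internal bipartition)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if msa is None:
        msa = progressive_align(seqs)
    tree = neighbor_joining(p_distance(msa, poisson=poisson))
    point = _bipartitions(tree)
    counts = {split: 0 for split in point}
    rng = np.random.default_rng(seed)
    ids = msa.ids
    arr = np.array([list(msa.rows[i]) for i in ids])
    ncols = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep = MultipleAlignment(
            rows={ids[i]: "".join(arr[i, cols]) for i in range(len(ids))}
        )
        rep_tree = neighbor_joining(p_distance(rep, poisson=poisson))
        rep_splits = set(_bipartitions(rep_tree))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in point.items():
        node.label = str(int(round(100.0 * counts[split] / n_reps)))
    return tree


# ---------------------------------------------------------------------------
# divergent-sequence exclusion


def flag_divergent(
    seqs,
    msa: MultipleAlignment,
    min_identity: float = 0.40,
    min_aligned_fraction: float = 0.30,
) -> tuple[list[str], MultipleAlignment]:
    """Exclude sequences too divergent to align; realign the remainder.

    A sequence is excluded when its mean pairwise global-alignment
    identity against the other sequences falls below ``min_identity``,
    or when fewer than ``min_aligned_fraction`` of the alignment columns
    carry one of its residues. The default threshold sits midway between
    the ~0.29 identity that optimal global alignment of unrelated
    proteins produces (an aligner chooses matching columns, so unrelated
    identity is far above the 1/20 naive rate) and the identity of
    genuine family members sharing a conserved domain.
    """
    ids = msa.ids
    arr = np.array([list(msa.rows[i]) for i in ids])
    ncols = arr.shape[1]
    # 1 - pairwise NW distance = identity over aligned columns
    ident = 1.0 - _pairwise_distance_matrix([msa.ungapped(i) for i in ids])
    excluded = []
    for i, pid in enumerate(ids):
        nongap = arr[i] != "-"
        if nongap.sum() / ncols < min_aligned_fraction:
            excluded.append(pid)
            continue
        others = [ident[i, j] for j in range(len(ids)) if j != i]
        if others and float(np.mean(others)) < min_identity:
            excluded.append(pid)
    if not excluded:
        return [], msa
    keep = [pid for pid in ids if pid not in excluded]
    from .genome_io import SequenceRecord

    remainder = [SequenceRecord(pid, msa.ungapped(pid)) for pid in keep]
    return excluded, progressive_align(remainder)


# ---------------------------------------------------------------------------
# subfamily assignment


def assign_subfamilies(
    tree: dendropy.Tree,
    reference_labels: dict[str, str],
    min_support: float = 50.0,
) -> dict[str, str]:
    """Anchor unlabeled leaves to the reference clades around them.

    For each query, the smallest edge-side (over both sides of every tree
    edge, i.e. every clade under any rooting) containing the query and at
    least one reference decides its label — provided all references in
    that side agree and the side's edge support meets ``min_support``
    (edges without a bootstrap label count as fully supported). Queries
    failing either condition are UNCLASSIFIED; references keep their own
    labels.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    all_set = frozenset(leaves)
    refs = set(reference_labels) & all_set

    sides: list[tuple[frozenset, float]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        support = 100.0
        if not node.is_leaf() and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                pass
        sides.append((below, support))
        sides.append((all_set - below, support))

    result = {}
    for leaf in leaves:
        if leaf in reference_labels:
            result[leaf] = reference_labels[leaf]
            continue
        if not refs:
            result[leaf] = UNCLASSIFIED
            continue
        candidates = [
            (len(side), side, support) for side, support in sides
            if leaf in side and side & refs
        ]
        if not candidates:
            result[leaf] = UNCLASSIFIED
            continue
        smallest = min(size for size, _, _ in candidates)
        minimal = [(side, support) for size, side, support in candidates
                   if size == smallest]
        # every minimal clade must agree on one well-supported label;
        # equally small clades with conflicting labels stay unassigned
        labels = set()
        supported = True
        for side, support in minimal:
            labels |= {reference_labels[r] for r in side & refs}
            supported = supported and support >= min_support
        if len(labels) == 1 and supported:
            result[leaf] = labels.pop()
        else:
            result[leaf] = UNCLASSIFIED
    return result
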