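"""Similarity search, RBH pairing, alignment trimming, distances and NJ trees.

Pairwise alignment is optimal Smith-Waterman with affine gaps
(``Bio.Align.PairwiseAligner``); homologs are kept when the aligned query
span exceeds a coverage fraction of the query (default 50%) and the raw
score clears a configurable threshold, standing in for a database e-value
filter.  Column trimming follows the gap-threshold / conservation-threshold
convention (defaults 25% / 50%).  Distances are scoredist or Poisson; trees
come from Saitou-Nei neighbor joining.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Phylo.BaseTree import Tree
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM

from .core_io import PhyexpError, ProteinSequence

__all__ = [
    "SearchParams",
    "Hit",
    "TrimParams",
    "DistanceMatrix",
    "local_align",
    "find_homologs",
    "rbh_pairs",
    "trim_alignment",
    "trim_columns",
    "distance_matrix",
    "nj_tree",
]

# calibration factor of the published scoredist formula (BLOSUM62)
SCOREDIST_CALIBRATION = 1.337
SCOREDIST_FLOOR = 0.01


@dataclass(frozen=True)
class SearchParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    q_cov: float = 0.5
    s_min: float = 50.0

    def __post_init__(self):
        if not 0 < self.q_cov <= 1:
            raise PhyexpError("q_cov must be in (0, 1]")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise PhyexpError("gap penalties must be positive")


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    score: float
    span: int
    coverage: float


@dataclass(frozen=True)
class TrimParams:
    """Column-keeping thresholds.

    ``gap_threshold``: minimum fraction of non-gap characters per kept
    column.  ``conservation_threshold``: minimum frequency of the modal
    non-gap residue per kept column.  ``super_alignment`` switches to the
    concatenated-alignment rule (keep columns with gaps in at most half the
    rows, no conservation test).
    """

    gap_threshold: float = 0.25
    conservation_threshold: float = 0.50
    super_alignment: bool = False

    def __post_init__(self):
        for v in (self.gap_threshold, self.conservation_threshold):
            if not 0 <= v <= 1:
                raise PhyexpError("trim thresholds must be in [0, 1]")


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=64)
def _aligner(name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _matrix(name)
    al.open_gap_score = -gap_open
    al.extend_gap_score = -gap_extend
    return al


def local_align(a: ProteinSequence, b: ProteinSequence, params: SearchParams | None = None) -> Hit:
    """Optimal Smith-Waterman local alignment of ``a`` (query) vs ``b``."""
    params = params or SearchParams()
    if not a.residues or not b.residues:
        raise PhyexpError("cannot align an empty sequence")
    al = _aligner(params.matrix, params.gap_open, params.gap_extend)
    result = al.align(a.residues, b.residues)
    best = result[0]
    qblocks = best.aligned[0]
    span = int(qblocks[-1][1] - qblocks[0][0]) if len(qblocks) else 0
    return Hit(a.gene_id, b.gene_id, float(best.score), span, span / len(a.residues))


def alignment_score(a: ProteinSequence, b: ProteinSequence, params: SearchParams | None = None) -> float:
    """Score-only Smith-Waterman (cheaper than a full traceback)."""
    params = params or SearchParams()
    al = _aligner(params.matrix, params.gap_open, params.gap_extend)
    return float(al.score(a.residues, b.residues))


def find_homologs(query: ProteinSequence, db, params: SearchParams | None = None) -> list[Hit]:
    """Hits of ``query`` against ``db`` passing the coverage and score
    filters, best first; a same-id record in the db is skipped."""
    params = params or SearchParams()
    if not db:
        raise PhyexpError("empty database")
    hits = []
    for subj in db:
        if subj.gene_id == query.gene_id:
            continue
        if alignment_score(query, subj, params) < params.s_min:
            continue
        hit = local_align(query, subj, params)
        if hit.coverage > params.q_cov and hit.score >= params.s_min:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def rbh_pairs(seqs, params: SearchParams | None = None) -> list[tuple[str, str]]:
    """Reciprocal-best-hit pairs within a sequence set.

    ``(i, j)`` is emitted iff each is the other's best filtered hit; best-hit
    score ties resolve toward the smaller gene id with a warning.  Pairs are
    returned sorted, each as a sorted tuple.
    """
    params = params or SearchParams()
    if len(seqs) < 2:
        raise PhyexpError("need at least 2 sequences for RBH")
    best: dict[str, str | None] = {}
    for query in seqs:
        hits = find_homologs(query, seqs, params)
        if not hits:
            best[query.gene_id] = None
            continue
        top = hits[0]
        ties = [h for h in hits if h.score == top.score]
        if len(ties) > 1:
            warnings.warn(
                f"best-hit tie for {query.gene_id!r}; keeping smallest subject id"
            )
        best[query.gene_id] = top.subject_id
    pairs = set()
    for g, b in best.items():
        if b is not None and best.get(b) == g:
            pairs.add(tuple(sorted((g, b))))
    return sorted(pairs)


def trim_columns(rows: list[str], params: TrimParams | None = None) -> list[int]:
    """Indices of alignment columns surviving the trimming thresholds."""
    params = params or TrimParams()
    if not rows:
        return []
    n = len(rows[0])
    if any(len(r) != n for r in rows):
        raise PhyexpError("alignment rows differ in length")
    if any("." in r for r in rows):
        raise PhyexpError("gap character must be '-', found '.'")
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), n)
    gap = arr == b"-"
    nongap_frac = 1.0 - gap.mean(axis=0)
    kept = []
    for j in range(n):
        if params.super_alignment:
            if gap[:, j].mean() <= 0.5:
                kept.append(j)
            continue
        if nongap_frac[j] < params.gap_threshold or nongap_frac[j] == 0:
            continue
        col = arr[~gap[:, j], j]
        _, counts = np.unique(col, return_counts=True)
        if counts.max() / col.size >= params.conservation_threshold:
            kept.append(j)
    return kept


def trim_alignment(aln, params: TrimParams | None = None):
    """Remove gappy / unconserved columns; row order preserved."""
    if not aln:
        return []
    kept = trim_columns([r.seq for r in aln], params)
    if not kept:
        warnings.warn("no alignment columns survive trimming")
    return [type(r)(r.gene_id, "".join(r.seq[j] for j in kept) or "-") for r in aln] if kept else []


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise PhyexpError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise PhyexpError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise PhyexpError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise PhyexpError("distances must be non-negative")
        self.values = v

    def __getitem__(self, pair):
        i, j = (self.ids.index(p) for p in pair)
        return self.values[i, j]


def _pair_distance(x: str, y: str, method: str, matrix) -> float:
    both = [(a, b) for a, b in zip(x, y) if a != "-" and b != "-"]
    if not both:
        raise PhyexpError("no overlapping non-gap columns")
    if method == "poisson":
        p = sum(a != b for a, b in both) / len(both)
        if p >= 1.0:
            return -math.log(1e-6)
        return -math.log(1.0 - p)
    # scoredist (Sonnhammer & Hollich): normalised BLOSUM62 alignment score
    score = sum(matrix[a, b] for a, b in both)
    xs = [a for a, _ in both]
    ys = [b for _, b in both]
    expected = sum(matrix[a, b] for a in xs for b in ys) / len(both)
    upper = (sum(matrix[a, a] for a in xs) + sum(matrix[b, b] for b in ys)) / 2
    denom = upper - expected
    sigma = (score - expected) / denom if denom > 0 else SCOREDIST_FLOOR
    sigma = max(sigma, SCOREDIST_FLOOR)
    return -math.log(sigma) * 100.0 * SCOREDIST_CALIBRATION


def distance_matrix(aln, method: str = "scoredist") -> DistanceMatrix:
    """Pairwise distances over an aligned set (rows with gaps allowed)."""
    if len(aln) < 2:
        raise PhyexpError("need at least 2 rows")
    if method not in ("scoredist", "poisson"):
        raise PhyexpError(f"unknown distance method {method!r}")
    matrix = _matrix("BLOSUM62") if method == "scoredist" else None
    ids = [r.gene_id for r in aln]
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = max(
                    0.0, _pair_distance(aln[i].seq, aln[j].seq, method, matrix)
                )
            except PhyexpError as exc:
                raise PhyexpError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
    return DistanceMatrix(ids, d)


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; arbitrarily rooted, flagged unrooted.

    Negative branch lengths produced by the agglomeration are clamped to
    zero with a warning.  Exact on additive matrices.
    """
    if len(d.ids) < 3:
        raise PhyexpError("NJ needs at least 3 taxa")
    lower = [[float(d.values[i, j]) for j in range(i + 1)] for i in range(len(d.ids))]
    bdm = _BioDM(list(d.ids), lower)
    tree = DistanceTreeConstructor().nj(bdm)
    clamped = False
    for clade in tree.find_clades():
        if not clade.is_terminal():
            clade.name = None  # drop InnerN labels
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    tree.rooted = False
    return tree
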