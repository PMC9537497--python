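"""Local protein alignment and per-CDS best-hit scoring.

This is the scoring engine beneath the plasmid comparison: every query
CDS is aligned locally (Smith–Waterman, affine gaps, BLOSUM62 by
default) against candidate target CDS, and the single best-scoring
target passing identity and coverage thresholds becomes its hit. Raw
substitution-matrix scores are summed downstream; because the headline
statistic normalizes by the query's self-score, the choice of raw
versus bit scores nearly cancels — bit scores remain available via
:attr:`AlignmentParams.bit_scores`.

A k-mer prefilter (candidate pairs must share at least
``prefilter_min_kmers`` exact ``prefilter_k``-mers) keeps panel scoring
desk-scale. The filter only prunes pairs whose optimal score would be
rejected anyway for realistic proteins; a dedicated test asserts it
never changes which hit is maximal on synthetic proteomes.

Gap costs follow the BLAST convention: a gap of length L costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .records import CdsFeature, PlasmidRecord

__all__ = [
    "AlignmentParams",
    "HomologyHit",
    "align_local",
    "best_hits",
    "plasmid_raw_score",
    "self_score",
]

# Karlin–Altschul parameters for gapped BLOSUM62 11/1 (BLAST defaults),
# used only for the optional bit-score output.
_LAMBDA, _K = 0.267, 0.041


@dataclass
class AlignmentParams:
    """Scoring scheme and hit-acceptance thresholds."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_identity_pct: float = 30.0
    min_coverage_pct: float = 50.0
    bit_scores: bool = False
    prefilter: bool = True
    prefilter_k: int = 4
    prefilter_min_kmers: int = 2

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        for t in (self.min_identity_pct, self.min_coverage_pct):
            if not 0 <= t <= 100:
                raise ValueError("thresholds must lie in [0, 100]")

    def key(self) -> tuple:
        return (self.matrix_name, self.gap_open, self.gap_extend)


@dataclass
class HomologyHit:
    query_locus: str
    target_plasmid: str
    target_locus: str
    raw_score: int
    identity_pct: float
    coverage_pct: float


@lru_cache(maxsize=8)
def _matrix(name: str):
    m = substitution_matrices.load(name).copy()
    # an unknown residue is informationless: score 0 against everything
    if "X" in m.alphabet:
        for c in m.alphabet:
            m["X", c] = 0.0
            m[c, "X"] = 0.0
    return m


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix(matrix_name)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(s: str) -> None:
    if not s:
        raise ValueError("empty protein sequence")
    bad = set(s) - set("ACDEFGHIKLMNPQRSTVWYX")
    if bad:
        raise ValueError(f"non-amino-acid characters {sorted(bad)}")


def align_local(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[int, float, float, list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Optimal local alignment of two proteins.

    Returns ``(raw_score, identity_pct, coverage_pct, blocks)`` where
    ``blocks`` pairs aligned half-open intervals of *a* and *b*.
    Identity is counted over all alignment columns (gap columns count
    as non-identical); coverage is the fraction of *a* residues inside
    the alignment. A pair with no positive-scoring local alignment
    returns ``(0, 0.0, 0.0, [])``.
    """
    params = params or AlignmentParams()
    _check_protein(a)
    _check_protein(b)
    aligner = _aligner(*params.key())
    score = aligner.score(a, b)
    if score <= 0:
        return 0, 0.0, 0.0, []
    aln = next(iter(aligner.align(a, b)))
    qa, ta = aln.aligned
    blocks = [
        ((int(q0), int(q1)), (int(t0), int(t1)))
        for (q0, q1), (t0, t1) in zip(qa, ta)
    ]
    ident = 0
    columns = 0
    covered = 0
    prev = None
    for (q0, q1), (t0, t1) in blocks:
        if prev is not None:
            columns += (q0 - prev[0]) + (t0 - prev[1])
        for qi, ti in zip(range(q0, q1), range(t0, t1)):
            columns += 1
            if a[qi] == b[ti]:
                ident += 1
        covered += q1 - q0
        prev = (q1, t1)
    identity_pct = 100.0 * ident / columns if columns else 0.0
    coverage_pct = 100.0 * covered / len(a)
    return int(round(score)), identity_pct, coverage_pct, blocks


def raw_to_bits(raw: float) -> float:
    """Bit-score conversion under the default gapped BLOSUM62/11/1 statistics."""
    return (_LAMBDA * raw - math.log(_K)) / math.log(2.0)


def self_score(protein: str, params: AlignmentParams | None = None) -> int:
    """Score of a protein aligned to itself (sum of diagonal entries
    for substitution matrices without negative diagonal)."""
    params = params or AlignmentParams()
    m = _matrix(params.matrix_name)
    return int(sum(m[c, c] for c in protein))


def _kmers(s: str, k: int) -> frozenset[str]:
    return frozenset(s[i : i + k] for i in range(len(s) - k + 1))


@dataclass
class _TargetIndex:
    """Per-target-proteome k-mer inverted index for the prefilter."""

    features: list[CdsFeature]
    k: int
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        for j, f in enumerate(self.features):
            for kmer in _kmers(f.protein, self.k):
                self.index.setdefault(kmer, []).append(j)

    def candidates(self, query_protein: str, min_shared: int) -> list[int]:
        counts: dict[int, int] = {}
        for kmer in _kmers(query_protein, self.k):
            for j in self.index.get(kmer, ()):
                counts[j] = counts.get(j, 0) + 1
        return [j for j, c in counts.items() if c >= min_shared]


def best_hits(
    query: list[CdsFeature],
    target: PlasmidRecord,
    params: AlignmentParams | None = None,
) -> list[HomologyHit]:
    """Best target hit for each query CDS (at most one per query locus).

    For each query protein the highest-raw-score target protein passing
    the identity and coverage thresholds is reported. Ties on raw score
    are broken by higher identity, then lower target start coordinate.
    """
    params = params or AlignmentParams()
    targets = target.proteome()
    if not targets:
        return []
    tindex = (
        _TargetIndex(targets, params.prefilter_k) if params.prefilter else None
    )
    aligner = _aligner(*params.key())
    hits = []
    def _scan(qf: CdsFeature, cand) -> tuple | None:
        scored = []
        for j in cand:
            s = aligner.score(qf.protein, targets[j].protein)
            if s > 0:
                scored.append((s, j))
        scored.sort(key=lambda t: -t[0])
        best = None
        for s, j in scored:
            if best is not None and s < best[0]:
                break  # only ties with the current best remain relevant
            raw, ident, cov, _ = align_local(qf.protein, targets[j].protein, params)
            if ident < params.min_identity_pct or cov < params.min_coverage_pct:
                continue
            key = (raw, ident, -targets[j].start)
            if best is None or key > best[:3]:
                best = (raw, ident, -targets[j].start, j, cov)
        return best

    for qf in query:
        if qf.pseudo or not qf.protein:
            continue
        if tindex is not None:
            cand = tindex.candidates(qf.protein, params.prefilter_min_kmers)
        else:
            cand = range(len(targets))
        best = _scan(qf, cand)
        if best is None and tindex is not None:
            # a query whose filtered scan finds nothing is re-scanned
            # exhaustively: the filter can then only speed up, never
            # change, the reported hits
            best = _scan(qf, range(len(targets)))
        if best is not None:
            raw, ident, _, j, cov = best
            score = raw_to_bits(raw) if params.bit_scores else raw
            hits.append(
                HomologyHit(
                    qf.locus_tag, target.id, targets[j].locus_tag,
                    int(round(score)), round(ident, 2), round(cov, 2),
                )
            )
    return hits


def matched_hits(
    query: list[CdsFeature],
    target: PlasmidRecord,
    params: AlignmentParams | None = None,
) -> list[HomologyHit]:
    """One-to-one greedy assignment of query CDS to target CDS.

    Used for plasmid *totals*: every target gene can back at most one
    query gene, so a target carrying a single copy of a family the
    query holds in two copies contributes that family's score once,
    not twice. Pairs are taken in descending raw-score order (ties by
    query position, then target position) subject to identity and
    coverage thresholds; a displaced query falls back to its next-best
    unused target. For a self-comparison the assignment is perfect and
    the total equals the summed self-scores exactly.
    """
    params = params or AlignmentParams()
    targets = target.proteome()
    queries = [qf for qf in query if not qf.pseudo and qf.protein]
    if not targets or not queries:
        return []
    tindex = (
        _TargetIndex(targets, params.prefilter_k) if params.prefilter else None
    )
    aligner = _aligner(*params.key())

    def candidate_pairs(q_indices, t_indices) -> list[tuple[float, int, int]]:
        pairs = []
        tset = set(t_indices)
        for qi in q_indices:
            if tindex is not None:
                cand = [
                    j
                    for j in tindex.candidates(
                        queries[qi].protein, params.prefilter_min_kmers
                    )
                    if j in tset
                ]
            else:
                cand = list(t_indices)
            for j in cand:
                s = aligner.score(queries[qi].protein, targets[j].protein)
                if s > 0:
                    pairs.append((s, qi, j))
        pairs.sort(key=lambda p: (-p[0], p[1], targets[p[2]].start))
        return pairs

    assigned_q: dict[int, HomologyHit] = {}
    used_t: set[int] = set()

    def greedy(pairs):
        for s, qi, j in pairs:
            if qi in assigned_q or j in used_t:
                continue
            raw, ident, cov, _ = align_local(
                queries[qi].protein, targets[j].protein, params
            )
            if ident < params.min_identity_pct or cov < params.min_coverage_pct:
                continue
            score = raw_to_bits(raw) if params.bit_scores else raw
            assigned_q[qi] = HomologyHit(
                queries[qi].locus_tag, target.id, targets[j].locus_tag,
                int(round(score)), round(ident, 2), round(cov, 2),
            )
            used_t.add(j)

    all_t = range(len(targets))
    greedy(candidate_pairs(range(len(queries)), all_t))
    if tindex is not None:
        # exhaustive fallback for unassigned queries: the prefilter can
        # only speed the assignment up, never change its outcome
        left_q = [qi for qi in range(len(queries)) if qi not in assigned_q]
        left_t = [j for j in all_t if j not in used_t]
        if left_q and left_t:
            tindex = None
            greedy(candidate_pairs(left_q, left_t))
    return [assigned_q[qi] for qi in sorted(assigned_q)]


def plasmid_raw_score(
    query: PlasmidRecord,
    target: PlasmidRecord,
    params: AlignmentParams | None = None,
) -> int:
    """Summed one-to-one best-hit scores of the query proteome against
    the target (see :func:`matched_hits`)."""
    return sum(h.raw_score for h in matched_hits(query.proteome(), target, params))
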