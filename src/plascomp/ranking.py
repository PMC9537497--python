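"""Relative-similarity scoring, panel ranking, ring matrix and
within-plasmid duplication census.

The headline statistic: the summed best-hit scores of every query CDS
against a target plasmid, divided by the query's score against itself,
times 100. The query's own entry is 100.00 by construction; unrelated
plasmids score 0.00. A panel of targets is ranked by this percentage,
and a "ring matrix" (one row per target, one cell per query CDS in
coordinate order, blank where no homologue was found) reproduces the
information content of a circular comparison plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentParams, align_local, best_hits, matched_hits, plasmid_raw_score
from .records import PlasmidRecord

__all__ = [
    "PlasmidScore",
    "RingMatrix",
    "DuplicationCensus",
    "relative_similarity",
    "rank_panel",
    "build_ring_matrix",
    "duplication_census",
]


@dataclass
class PlasmidScore:
    target_id: str
    raw_total: int
    relative_similarity_pct: float  # reported to 2 decimals
    n_hits: int
    rank: int = 0
    length_bp: int = 0


@dataclass
class RingMatrix:
    query_cds_order: list[str]
    rows: list[tuple[str, list[int | None]]]  # (target_id, cells), rank order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {tid: cells for tid, cells in self.rows},
            index=self.query_cds_order,
        ).T


@dataclass
class DuplicationCensus:
    n_genes: int
    n_single_copy: int
    n_duplicated: int
    families: list[set[str]] = field(default_factory=list)


def relative_similarity(
    query: PlasmidRecord,
    target: PlasmidRecord,
    params: AlignmentParams | None = None,
    self_total: int | None = None,
) -> PlasmidScore:
    """Similarity of ``target`` to ``query`` as a percentage of the
    query's self-score. ``self_total`` may be passed to reuse a cached
    query-vs-query total across a panel."""
    params = params or AlignmentParams()
    if not query.proteome():
        raise ValueError(f"{query.id}: no usable (non-pseudo) CDS")
    if self_total is None:
        self_total = plasmid_raw_score(query, query, params)
    hits = matched_hits(query.proteome(), target, params)
    raw_total = sum(h.raw_score for h in hits)
    pct = round(100.0 * raw_total / self_total, 2) if self_total else 0.0
    return PlasmidScore(target.id, raw_total, pct, len(hits), length_bp=target.length_bp)


def rank_panel(
    query: PlasmidRecord,
    panel: list[PlasmidRecord],
    params: AlignmentParams | None = None,
    top_n: int | None = None,
) -> list[PlasmidScore]:
    """Score every panel member against the query and rank descending.

    Ties are broken by raw total, then target id, for deterministic
    output. Truncated to ``top_n`` when given.
    """
    params = params or AlignmentParams()
    self_total = plasmid_raw_score(query, query, params)
    scores = [
        relative_similarity(query, t, params, self_total=self_total)
        for t in panel
    ]
    scores.sort(
        key=lambda s: (-s.relative_similarity_pct, -s.raw_total, s.target_id)
    )
    if top_n is not None:
        scores = scores[:top_n]
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores


def build_ring_matrix(
    query: PlasmidRecord,
    ranked: list[PlasmidScore],
    panel: list[PlasmidRecord],
    params: AlignmentParams | None = None,
) -> RingMatrix:
    """Per-CDS best-hit scores for each ranked target.

    A cell is blank (None) exactly when the target has no accepted hit
    for that query CDS; otherwise it carries the hit's raw score. Rows
    follow rank order, matching ring order in a circular plot.
    """
    params = params or AlignmentParams()
    by_id = {p.id: p for p in panel}
    order = [f.locus_tag for f in query.proteome()]
    rows = []
    for score in ranked:
        target = by_id[score.target_id]
        hits = {h.query_locus: h.raw_score for h in
                best_hits(query.proteome(), target, params)}
        rows.append((score.target_id, [hits.get(tag) for tag in order]))
    return RingMatrix(order, rows)


def duplication_census(
    record: PlasmidRecord,
    params: AlignmentParams | None = None,
    dup_identity_pct: float = 90.0,
    dup_coverage_pct: float = 90.0,
) -> DuplicationCensus:
    """Count single-copy versus duplicated genes within one plasmid.

    Two genes are duplicates when their local alignment reaches both
    the identity and the (mutual) coverage threshold; families are
    connected components of the resulting symmetric graph. Pseudo genes
    are excluded entirely.
    """
    params = params or AlignmentParams()
    feats = record.proteome()
    n = len(feats)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    from .align import _TargetIndex  # reuse the prefilter index

    tindex = _TargetIndex(feats, params.prefilter_k) if params.prefilter else None
    for i in range(n):
        cand = (
            tindex.candidates(feats[i].protein, params.prefilter_min_kmers)
            if tindex is not None
            else range(n)
        )
        for j in cand:
            if j <= i:
                continue
            a, b = feats[i].protein, feats[j].protein
            _, ident, cov_q, blocks = align_local(a, b, params)
            if not blocks:
                continue
            cov_t = 100.0 * sum(t1 - t0 for _, (t0, t1) in blocks) / len(b)
            if (
                ident >= dup_identity_pct
                and cov_q >= dup_coverage_pct
                and cov_t >= dup_coverage_pct
            ):
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(feats[i].locus_tag)
    families = sorted(
        (g for g in groups.values() if len(g) >= 2), key=lambda g: sorted(g)[0]
    )
    n_dup = sum(len(g) for g in families)
    return DuplicationCensus(
        n_genes=n, n_single_copy=n - n_dup, n_duplicated=n_dup, families=families
    )
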