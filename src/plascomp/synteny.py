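"""Order-consistent homologue chaining between a gene cluster and a
target replicon.

For a query cluster, best-hit homologues are found on the target; the
synteny chain is the longest strictly monotonic subsequence of those
homologue pairs in target coordinate order — computed for both
orientations (target order increasing = ``same``, decreasing =
``inverted``) with ties going to ``same``. The chain length is the
"shares synteny for N genes" count; no gap penalties are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentParams, best_hits
from .records import CdsFeature, PlasmidRecord

__all__ = ["SyntenyChain", "match_cluster", "synteny_report"]


@dataclass
class SyntenyChain:
    pairs: list[tuple[str, str]]  # (query_locus, target_locus), query order
    orientation: str  # same / inverted
    chain_len: int
    mean_identity_pct: float
    cluster_id: str = ""
    target_id: str = ""


def _longest_monotone(values: list[int], decreasing: bool) -> list[int]:
    """Indices of one longest strictly monotone subsequence (O(n^2) DP;
    chains here are tens of genes at most)."""
    v = [-x for x in values] if decreasing else values
    n = len(v)
    if n == 0:
        return []
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if v[j] < v[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -i))
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


def match_cluster(
    query_cluster: list[CdsFeature],
    target: PlasmidRecord,
    params: AlignmentParams | None = None,
) -> SyntenyChain:
    """Chain the cluster's homologues on the target.

    One homologue per query gene (its best hit) enters the chaining;
    the longer of the increasing and decreasing chains is reported,
    with ties resolved to ``same`` orientation.
    """
    if len(query_cluster) < 2:
        raise ValueError("a gene cluster needs >= 2 genes")
    params = params or AlignmentParams()
    hits = best_hits(query_cluster, target, params)
    t_start = {f.locus_tag: f.start for f in target.cds}
    # hits follow query order (best_hits preserves input order)
    coords = [t_start[h.target_locus] for h in hits]
    inc = _longest_monotone(coords, decreasing=False)
    dec = _longest_monotone(coords, decreasing=True)
    chosen, orientation = (
        (inc, "same") if len(inc) >= len(dec) else (dec, "inverted")
    )
    chain_hits = [hits[i] for i in chosen]
    mean_ident = (
        round(sum(h.identity_pct for h in chain_hits) / len(chain_hits), 2)
        if chain_hits
        else 0.0
    )
    return SyntenyChain(
        pairs=[(h.query_locus, h.target_locus) for h in chain_hits],
        orientation=orientation,
        chain_len=len(chain_hits),
        mean_identity_pct=mean_ident,
        target_id=target.id,
    )


def synteny_report(
    query_clusters: dict[str, list[CdsFeature]],
    targets: list[PlasmidRecord],
    params: AlignmentParams | None = None,
) -> list[SyntenyChain]:
    """One chain per (cluster, target), sorted by decreasing chain
    length (ties by cluster then target id). Chains of length 0 are
    retained so absent synteny is visible in the report."""
    if not query_clusters or not targets:
        raise ValueError("need at least one cluster and one target")
    rows = []
    for cid, cluster in query_clusters.items():
        for t in targets:
            chain = match_cluster(cluster, t, params)
            chain.cluster_id = cid
            rows.append(chain)
    rows.sort(key=lambda c: (-c.chain_len, c.cluster_id, c.target_id))
    return rows
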