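"""Relative similarity, panel ranking, ring matrix, duplication census."""

import numpy as np
import pytest

from plascomp.records import CdsFeature, PlasmidRecord
from plascomp.ranking import (
    build_ring_matrix,
    duplication_census,
    rank_panel,
    relative_similarity,
)
from plascomp.simulate import SimConfig, derive_target, generate_query

AA = "ACDEFGHIKLMNPQRSTVWY"


def _record_from_proteins(pid, proteins):
    feats = []
    pos = 0
    for i, p in enumerate(proteins):
        feats.append(
            CdsFeature(f"{pid}_{i:03d}", pos, pos + 3 * len(p) + 3, "+", protein=p)
        )
        pos += 3 * len(p) + 60
    return PlasmidRecord(pid, "A" * pos, "linear", feats)


def _protein(seed, n=110):
    rng = np.random.default_rng(seed)
    return "M" + "".join(rng.choice(list(AA), size=n - 1))


def test_self_similarity_is_exactly_100():
    for seed in range(20):
        rec, _ = generate_query(SimConfig(seed=seed, n_genes=5,
                                          protein_len=(60, 120)))
        assert relative_similarity(rec, rec).relative_similarity_pct == 100.00


def test_no_homologue_target_scores_zero(small_plasmid):
    query, _ = small_plasmid
    other, _ = generate_query(SimConfig(seed=999, n_genes=6))
    score = relative_similarity(query, other)
    assert score.relative_similarity_pct == 0.0 and score.n_hits == 0


def test_half_content_split_evenly():
    p = _protein(1)
    query = _record_from_proteins("q", [p, p])
    target = _record_from_proteins("t", [p])
    assert relative_similarity(query, target).relative_similarity_pct == 50.00


def test_query_without_usable_cds_rejected():
    empty = PlasmidRecord("e", "ACGT" * 100, "linear", [])
    other = _record_from_proteins("t", [_protein(2)])
    with pytest.raises(ValueError):
        relative_similarity(empty, other)


def test_rank_panel_orders_by_planted_divergence():
    query, _ = generate_query(SimConfig(seed=31, n_genes=12,
                                        protein_len=(70, 140)))
    shared = [1.0, 0.9, 0.75, 0.5, 0.1]
    panel = []
    for i, frac in enumerate(shared):
        t, _ = derive_target(query, [(frac, 100.0)], seed=400 + i,
                             target_id=f"t_{int(frac * 100):03d}")
        panel.append(t)
    ranked = rank_panel(query, panel, top_n=5)
    assert [s.target_id for s in ranked] == [
        "t_100", "t_090", "t_075", "t_050", "t_010",
    ]
    assert ranked[0].relative_similarity_pct == 100.00
    assert [s.rank for s in ranked] == [1, 2, 3, 4, 5]


def test_similarity_decreases_with_divergence_series():
    query, _ = generate_query(SimConfig(seed=8, n_genes=10,
                                        protein_len=(70, 140)))
    pcts = []
    for i, mutated in enumerate([0.0, 0.25, 0.5, 0.9]):
        t, _ = derive_target(query, [(1.0 - mutated, 100.0)], seed=600 + i)
        pcts.append(relative_similarity(query, t).relative_similarity_pct)
    assert all(a > b for a, b in zip(pcts, pcts[1:])), pcts


def test_ring_matrix_blanks_mirror_missing_hits():
    query, _ = generate_query(SimConfig(seed=41, n_genes=10,
                                        protein_len=(70, 140)))
    t6, _ = derive_target(query, [(0.6, 100.0)], seed=700, target_id="t6")
    ranked = rank_panel(query, [query, t6])
    matrix = build_ring_matrix(query, ranked, [query, t6])
    assert [tid for tid, _ in matrix.rows] == [s.target_id for s in ranked]
    self_row = dict(matrix.rows)[query.id]
    assert all(c is not None for c in self_row)
    t6_row = dict(matrix.rows)["t6"]
    assert sum(c is None for c in t6_row) == 4
    assert len(t6_row) == len(matrix.query_cds_order) == 10


def test_census_all_unique():
    rec = _record_from_proteins("u", [_protein(s) for s in range(8)])
    c = duplication_census(rec)
    assert (c.n_genes, c.n_single_copy, c.n_duplicated) == (8, 8, 0)
    assert c.families == []


def test_census_planted_family():
    p1, p2 = _protein(10), _protein(11)
    rec = _record_from_proteins("d", [p1, p1, p2])
    c = duplication_census(rec)
    assert (c.n_genes, c.n_single_copy, c.n_duplicated) == (3, 1, 2)
    assert [sorted(f) for f in c.families] == [["d_000", "d_001"]]


def test_census_partition_invariant():
    rng = np.random.default_rng(21)
    prots = [_protein(int(s)) for s in rng.integers(0, 50, size=12)]
    rec = _record_from_proteins("p", prots)
    c = duplication_census(rec)
    all_members = [m for f in c.families for m in f]
    assert len(all_members) == len(set(all_members)) == c.n_duplicated
    assert c.n_single_copy + c.n_duplicated == c.n_genes
    assert all(len(f) >= 2 for f in c.families)
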