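"""Local aligner against the enumeration oracle, plus hit selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plascomp.align import (
    AlignmentParams,
    align_local,
    best_hits,
    plasmid_raw_score,
    self_score,
)
from plascomp.records import CdsFeature, PlasmidRecord
from plascomp.simulate import SimConfig, derive_target, generate_query

from oracles import enumerate_local_score

AA = "ACDEFGHIKLMNPQRSTVWY"
REDUCED = "AGKW"  # 4-letter reduced alphabet for exhaustive enumeration


def _record_from_proteins(pid, proteins):
    feats = []
    pos = 0
    for i, p in enumerate(proteins):
        feats.append(
            CdsFeature(f"{pid}_{i:03d}", pos, pos + 3 * len(p) + 3, "+", protein=p)
        )
        pos += 3 * len(p) + 60
    return PlasmidRecord(pid, "A" * pos, "linear", feats)


def test_identical_tripeptide_scores_15():
    raw, ident, cov, blocks = align_local("MKT", "MKT")
    assert (raw, ident, cov) == (15, 100.0, 100.0)
    assert blocks == [((0, 3), (0, 3))]


@given(st.text(alphabet=AA, min_size=1, max_size=40))
@settings(max_examples=40, deadline=None)
def test_self_alignment_full_identity(s):
    raw, ident, cov, _ = align_local(s, s)
    assert ident == 100.0 and cov == 100.0
    assert raw == self_score(s)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_local("", "MKT")


def test_x_scores_zero_everywhere():
    raw, *_ = align_local("XXXX", "MKTA")
    assert raw == 0


def test_oracle_equivalence_exhaustive_short():
    """All pairs of length <= 3 over the reduced alphabet."""
    seqs = [a + b + c for a in REDUCED for b in REDUCED for c in REDUCED]
    seqs += [a + b for a in REDUCED for b in REDUCED] + list(REDUCED)
    for a in seqs[::3]:
        for b in seqs[::7]:
            expected = enumerate_local_score(a, b)
            got, *_ = align_local(a, b)
            assert got == expected, (a, b)


def test_oracle_equivalence_sampled_longer():
    """Seeded random pairs of length 4-8 over the reduced alphabet."""
    rng = np.random.default_rng(123)
    for _ in range(300):
        la, lb = rng.integers(4, 9, size=2)
        a = "".join(rng.choice(list(REDUCED), size=la))
        b = "".join(rng.choice(list(REDUCED), size=lb))
        assert align_local(a, b)[0] == enumerate_local_score(a, b), (a, b)


@given(
    st.text(alphabet=AA, min_size=1, max_size=25),
    st.text(alphabet=AA, min_size=1, max_size=25),
)
@settings(max_examples=60, deadline=None)
def test_score_bounded_by_self_scores(a, b):
    raw, *_ = align_local(a, b)
    assert raw <= min(self_score(a), self_score(b))


def test_mutation_rarely_raises_score():
    """Substituting residues in the target should not raise its score
    against the unchanged query (checked over many trials)."""
    rng = np.random.default_rng(77)
    violations = trials = 0
    for _ in range(120):
        n = int(rng.integers(30, 80))
        q = "".join(rng.choice(list(AA), size=n))
        t = list(q)
        k = int(rng.integers(1, max(2, n // 4)))
        for s in rng.choice(n, size=k, replace=False):
            t[s] = rng.choice([c for c in AA if c != t[s]])
        base = align_local(q, q)[0]
        mutated = align_local(q, "".join(t))[0]
        trials += 1
        if mutated > base:
            violations += 1
    assert violations / trials <= 0.01


def test_best_hits_exact_copy_and_disjoint():
    prots = ["M" + "".join(np.random.default_rng(i).choice(list(AA), size=120))
             for i in range(10)]
    q = _record_from_proteins("q", prots)
    t = _record_from_proteins("t", prots)
    hits = best_hits(q.cds, t)
    assert len(hits) == 10
    assert all(h.identity_pct == 100.0 for h in hits)
    assert {h.query_locus[-3:] for h in hits} == {h.target_locus[-3:] for h in hits}
    # proteome sharing no 4-mers: poly-K vs poly-W style sequences
    q2 = _record_from_proteins("q2", ["MKAKAKAKAKAKAKAKAKAKAKAKAKAKAK"])
    t2 = _record_from_proteins("t2", ["MWEWEWEWEWEWEWEWEWEWEWEWEWEWEW"])
    assert best_hits(q2.cds, t2) == []


def test_best_hits_recovers_planted_partners():
    query, _ = generate_query(SimConfig(seed=19, n_genes=10))
    target, truth = derive_target(query, [(0.6, 80.0)], seed=20)
    hits = best_hits(query.proteome(), target)
    planted = {v["partner"]: k for k, v in truth.homologs.items()}
    assert len(hits) == len(planted) == 6
    for h in hits:
        assert planted[h.query_locus] == h.target_locus
        assert h.identity_pct > 60.0


def test_prefilter_never_changes_best_hits():
    rng = np.random.default_rng(55)
    loud = AlignmentParams(prefilter=True)
    quiet = AlignmentParams(prefilter=False)
    for trial in range(50):
        seed = int(rng.integers(1, 2**20))
        q, _ = generate_query(SimConfig(seed=seed, n_genes=6,
                                        protein_len=(60, 120)))
        t, _ = derive_target(q, [(0.5, 75.0)], seed=seed + 1)
        a = best_hits(q.proteome(), t, loud)
        b = best_hits(q.proteome(), t, quiet)
        assert a == b, f"prefilter changed hits (seed {seed})"


def test_plasmid_raw_score_definition():
    prots = ["M" + "".join(np.random.default_rng(100 + i).choice(list(AA), size=100))
             for i in range(6)]
    q = _record_from_proteins("q", prots)
    assert plasmid_raw_score(q, q) == sum(self_score(p) for p in prots)
    half = _record_from_proteins("h", prots[:3])
    assert plasmid_raw_score(q, half) == sum(self_score(p) for p in prots[:3])
    unrelated = _record_from_proteins(
        "u", ["M" + "".join(np.random.default_rng(999 + i).choice(list(AA), size=100))
              for i in range(6)]
    )
    assert plasmid_raw_score(q, unrelated) == 0
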