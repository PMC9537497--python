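"""Iteron arrays, IR pairs (with brute-force oracle), TSD, element calls."""

import numpy as np
import pytest

from plascomp.records import revcomp
from plascomp.repeats import (
    ElementDescriptor,
    IrPair,
    delineate_elements,
    find_direct_repeats,
    find_ir_pairs,
    find_tsd,
    hamming,
    mask_low_complexity,
)
from plascomp.simulate import (
    IteronSpec,
    SimConfig,
    generate_query,
    plant_element,
)

from conftest import ITERON_SPACERS, ITERON_UNIT_A, ITERON_UNIT_B
from oracles import exhaustive_ir_pairs


def _random_dna(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------- direct repeats


def test_iteron_units_differ_by_one():
    assert hamming(ITERON_UNIT_A, ITERON_UNIT_B) == 1
    assert ITERON_UNIT_A[10] != ITERON_UNIT_B[10]


def test_iteron_array_recovered_from_assembled_sequence():
    seq = (
        _random_dna(1, 200)
        + ITERON_UNIT_A + ITERON_SPACERS[0]
        + ITERON_UNIT_B + ITERON_SPACERS[1]
        + ITERON_UNIT_A
        + _random_dna(2, 200)
    )
    arrays = find_direct_repeats(seq, (15, 20), max_spacer=10, max_mismatch=1)
    assert len(arrays) == 1
    a = arrays[0]
    assert (a.unit_len, a.n_copies) == (17, 3)
    assert a.spacer_lens == [7, 6]
    assert a.max_mismatch_to_first == 1
    assert a.units == [ITERON_UNIT_A, ITERON_UNIT_B, ITERON_UNIT_A]
    assert a.positions[0] == 200


def test_random_sequence_has_no_long_arrays():
    assert find_direct_repeats(_random_dna(99, 1000), (15, 20), 10, 1) == []


def test_array_maximality_brute_force():
    """No reported array can be extended by another qualifying copy."""
    seq = (
        _random_dna(5, 120)
        + ITERON_UNIT_A + "GTCAGCC" + ITERON_UNIT_A + "TACGGA" + ITERON_UNIT_B
        + _random_dna(6, 120)
    )
    arrays = find_direct_repeats(seq, (15, 20), 10, 1)
    assert len(arrays) == 1
    a = arrays[0]
    L, first = a.unit_len, a.units[0]
    end = a.positions[-1] + L
    for sp in range(0, 11):  # right extension
        j = end + sp
        if j + L <= len(seq):
            assert hamming(seq[j : j + L], first) > 1
    for sp in range(0, 11):  # left extension
        j = a.positions[0] - L - sp
        if j >= 0:
            assert hamming(seq[j : j + L], first) > 1


# ---------------------------------------------------------------- IR pairs


def test_planted_ir_pair_exact():
    ir = _random_dna(11, 25)
    seq = _random_dna(12, 300) + ir + _random_dna(13, 500) + revcomp(ir) + _random_dna(14, 300)
    pairs = find_ir_pairs(seq, min_len=20, max_len=30, max_mismatch=0)
    assert any(
        p.left == (300, 325) and p.right == (825, 850) and p.mismatches == 0
        for p in pairs
    )


def test_planted_39bp_ir_with_one_mismatch():
    ir = _random_dna(21, 39)
    right = list(revcomp(ir))
    right[17] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[17]]
    seq = _random_dna(22, 250) + ir + _random_dna(23, 700) + "".join(right) + _random_dna(24, 250)
    pairs = find_ir_pairs(seq, min_len=25, max_len=45, max_mismatch=2)
    # the reported maximal pair must cover the planted IR (it may absorb
    # chance-matching flank bases within the mismatch budget)
    hit = [
        p for p in pairs
        if p.left[0] <= 250 and p.left[1] >= 289
        and p.right[0] <= 989 and p.right[1] >= 1028
    ]
    assert hit and hit[0].ir_len >= 39 and 1 <= hit[0].mismatches <= 2


def test_poly_a_masked():
    assert find_ir_pairs("A" * 400, min_len=20) == []
    seq = _random_dna(31, 100) + "AT" * 60 + _random_dna(32, 100)
    assert all(
        not (100 <= p.left[0] < 220) for p in find_ir_pairs(seq, min_len=20)
    )


def test_reported_pairs_satisfy_revcomp_constraint():
    rng = np.random.default_rng(41)
    for trial in range(5):
        ir = "".join(rng.choice(list("ACGT"), size=int(rng.integers(22, 40))))
        seq = (
            _random_dna(100 + trial, 400) + ir
            + _random_dna(200 + trial, 300) + revcomp(ir)
            + _random_dna(300 + trial, 400)
        )
        for p in find_ir_pairs(seq, max_mismatch=2):
            assert hamming(p.left_seq, revcomp(p.right_seq)) == p.mismatches
            assert p.left[1] <= p.right[0]


def test_ir_oracle_equivalence_small_sequences():
    """Seed-and-extend equals the exhaustive per-diagonal scan on
    sequences <= 300 bp (masking off for a like-for-like comparison)."""
    rng = np.random.default_rng(71)
    for trial in range(8):
        n = int(rng.integers(120, 300))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        if trial % 2 == 0:  # plant an IR in half the trials
            ir = "".join(rng.choice(list("ACGT"), size=24))
            mid = n // 2
            seq = seq[:30] + ir + seq[30 + 24 : mid] + revcomp(ir) + seq[mid + 24 :]
        got = find_ir_pairs(seq, min_len=16, max_len=40, max_mismatch=2,
                            mask=False, merge=False)
        expected = exhaustive_ir_pairs(seq, min_len=16, max_len=40, max_mismatch=2)
        got_set = {(p.left, p.right, p.mismatches) for p in got}
        assert got_set == set(expected), f"trial {trial}"


# ---------------------------------------------------------------- TSD


def _ir_pair(seq, l0, l1, r0, r1):
    return IrPair((l0, l1), (r0, r1), l1 - l0, 0, seq[l0:l1], seq[r0:r1])


def test_tsd_found_and_max_length_preferred():
    ir = _random_dna(51, 25)
    tsd = "GATCC"
    seq = (
        _random_dna(52, 100) + tsd + ir + _random_dna(53, 200)
        + revcomp(ir) + tsd + _random_dna(54, 100)
    )
    pair = _ir_pair(seq, 105, 130, 330, 355)
    assert find_tsd(seq, pair, (4, 6)) == "GATCC"
    assert find_tsd(seq, pair, (4, 5)) == "GATCC"  # length 5 beats nested 4


def test_tsd_absent_returns_none():
    seq = _random_dna(55, 600)
    pair = _ir_pair(seq, 100, 125, 400, 425)
    assert find_tsd(seq, pair) is None


# ---------------------------------------------------------------- elements


def test_complete_element_recovered_exactly(descriptors):
    rec, truth = generate_query(SimConfig(seed=61, n_genes=6))
    rec, truth = plant_element(rec, truth, descriptors[1], seed=62, n_cargo=2)
    calls = delineate_elements(rec, descriptors)
    e = truth.elements[0]
    assert len(calls) == 1
    c = calls[0]
    assert c.span == tuple(e["span"])
    assert c.truncated_side == "none" and c.parent is None
    assert c.tsd == e["tsd"] and len(c.tsd) == 5
    assert sorted(c.cargo) == [f"{e['id']}_cargo0", f"{e['id']}_cargo1"]


def test_nested_insertion_with_truncated_parent(descriptors):
    rec, truth = generate_query(SimConfig(seed=63, n_genes=6))
    rec, truth = plant_element(rec, truth, descriptors[0], seed=64,
                               truncated="right")
    rec, truth = plant_element(rec, truth, descriptors[1], seed=65,
                               nested_into=0)
    calls = delineate_elements(rec, descriptors)
    assert len(calls) == 2
    parent = [c for c in calls if c.family_label == descriptors[0].family_label][0]
    child = [c for c in calls if c.family_label == descriptors[1].family_label][0]
    assert parent.truncated_side == "right"
    assert parent.span == tuple(truth.elements[0]["span"])
    assert child.span == tuple(truth.elements[1]["span"])
    assert calls[child.parent] is parent
    assert parent.span[0] < child.span[0] and child.span[1] < parent.span[1]


def test_descriptor_validation():
    with pytest.raises(ValueError):
        ElementDescriptor("x", "", {"tnpA": "MKT"})
    with pytest.raises(ValueError):
        ElementDescriptor("x", "ACGTACGT", {})


def test_low_complexity_mask_flags_runs():
    m = mask_low_complexity("G" * 5 + "A" * 15 + "CGTAGCTAGC")
    assert m[6] and m[12] and not m[0] and not m[25]
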