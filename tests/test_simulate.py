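"""Generator determinism, planted-truth consistency, identity control."""

import numpy as np
import pytest

from plascomp.align import align_local
from plascomp.io import read_genbank, write_genbank
from plascomp.repeats import hamming
from plascomp.simulate import (
    IteronSpec,
    SimConfig,
    derive_target,
    generate_query,
    plant_element,
    plant_iterons,
    validate_truth,
    write_bundle,
)

from conftest import ITERON_SPACERS, ITERON_UNIT_A, ITERON_UNIT_B


def test_same_config_gives_byte_identical_genbank(tmp_path):
    cfg = SimConfig(seed=11, n_genes=10)
    for name in ("a.gb", "b.gb"):
        rec, _ = generate_query(cfg)
        write_genbank(rec, tmp_path / name)
    assert (tmp_path / "a.gb").read_bytes() == (tmp_path / "b.gb").read_bytes()


def test_different_seeds_differ():
    a, _ = generate_query(SimConfig(seed=1, n_genes=5))
    b, _ = generate_query(SimConfig(seed=2, n_genes=5))
    assert a.sequence != b.sequence


def test_adding_genes_preserves_earlier_genes():
    small, _ = generate_query(SimConfig(seed=3, n_genes=5))
    big, _ = generate_query(SimConfig(seed=3, n_genes=9))
    assert [f.protein for f in big.cds][:5] != []
    small_prots = {f.locus_tag: f.protein for f in small.cds}
    big_prots = {f.locus_tag: f.protein for f in big.cds}
    for tag, p in small_prots.items():
        assert big_prots[tag] == p


def test_infeasible_packing_rejected():
    with pytest.raises(ValueError):
        generate_query(SimConfig(seed=4, n_genes=30, length_bp=1000))


def test_truth_validates_and_roundtrips(tmp_path):
    cfg = SimConfig(
        seed=5, n_genes=8,
        iterons=IteronSpec([ITERON_UNIT_A, ITERON_UNIT_B, ITERON_UNIT_A],
                           ITERON_SPACERS),
    )
    rec, truth = generate_query(cfg)
    validate_truth(rec, truth)  # explicit re-check
    write_genbank(rec, tmp_path / "q.gb")
    back = read_genbank(tmp_path / "q.gb")
    validate_truth(back, truth)  # truth still holds after a round trip


def test_derived_identity_within_two_points_of_plan():
    query, _ = generate_query(SimConfig(seed=6, n_genes=10))
    by_tag = {f.locus_tag: f for f in query.cds}
    for ident in (60.0, 80.0, 95.0):
        target, truth = derive_target(query, [(0.8, ident)], seed=1000)
        tgt = {f.locus_tag: f for f in target.cds}
        assert len(truth.homologs) == 8
        for tag, h in truth.homologs.items():
            assert abs(h["identity_pct"] - ident) <= 2.0
            planted = hamming(tgt[tag].protein, by_tag[h["partner"]].protein)
            n = len(tgt[tag].protein)
            assert abs(100.0 * (n - planted) / n - ident) <= 2.0
            # aligner-measured identity may run a little above the planted
            # value when low-scoring ends are clipped from the local alignment
            aligned_ident = align_local(by_tag[h["partner"]].protein,
                                        tgt[tag].protein)[1]
            assert -2.0 <= aligned_ident - ident <= 5.0


def test_plan_fractions_validated(small_plasmid):
    record, _ = small_plasmid
    with pytest.raises(ValueError):
        derive_target(record, [(0.7, 90.0), (0.6, 50.0)], seed=1)


def test_plant_iterons_at_position():
    rec, truth = generate_query(SimConfig(seed=8, n_genes=4))
    gap_pos = rec.cds[0].end + 500  # tail region
    gap_pos = rec.length_bp - 20
    rec2, truth2 = plant_iterons(
        rec, truth,
        IteronSpec([ITERON_UNIT_A, ITERON_UNIT_B], ["GATCCAT"]),
        at=rec.cds[-1].end + 30,
    )
    it = truth2.iterons[-1]
    p0 = it["positions"][0]
    assert rec2.sequence[p0 : p0 + 17] == ITERON_UNIT_A


def test_element_insertion_into_cds_rejected(descriptors):
    rec, truth = generate_query(SimConfig(seed=9, n_genes=4))
    inside_gene = rec.cds[0].start + 10
    with pytest.raises(ValueError):
        plant_element(rec, truth, descriptors[0], seed=10, at=inside_gene)


def test_overlapping_element_requires_nested_flag(descriptors):
    rec, truth = generate_query(SimConfig(seed=12, n_genes=4))
    rec, truth = plant_element(rec, truth, descriptors[1], seed=13)
    s0, s1 = truth.elements[0]["span"]
    mid = None
    # a position inside the element span that is intergenic (pad region)
    for at in range(s0 + 26, s1):
        if all(not (f.start < at < f.end) for f in rec.cds):
            mid = at
            break
    assert mid is not None
    with pytest.raises(ValueError):
        plant_element(rec, truth, descriptors[0], seed=14, at=mid)


def test_write_bundle_layout(tmp_path):
    out = write_bundle(
        tmp_path / "sim", SimConfig(seed=15, n_genes=6), targets=[(0.5, 90.0)]
    )
    assert (out / "query.gb").exists()
    assert list((out / "targets").glob("*.gb"))
    assert (out / "truth.json").exists()
    assert "seed = 15" in (out / "config.toml").read_text()
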