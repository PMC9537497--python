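"""Seeded synthetic plasmids with planted, machine-readable ground truth.

The generator emulates the statistical structure the analyses assume:
circular plasmids whose CDS fall in same-strand runs with bounded
intra-run gaps (operon geometry), proteomes at controlled divergence
from a query proteome (partial backbone sharing between plasmids),
tandem iteron arrays, and transposable elements delineated by terminal
inverted repeats and target-site duplications — including truncated and
nested configurations.

One integer seed governs everything; per-gene sub-streams are derived
by counter so that enlarging a simulation never perturbs earlier genes.
Proteins are mutated at the amino-acid level and back-translated with
uniformly drawn synonymous codons, so planted identities are exact;
indels are excluded so identity targets stay sharp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .records import CdsFeature, PlasmidRecord, revcomp, translate_cds
from .repeats import ElementDescriptor, hamming

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_query",
    "derive_target",
    "plant_element",
    "plant_iterons",
    "validate_truth",
    "write_bundle",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()


@dataclass
class IteronSpec:
    """Tandem direct-repeat array to plant: explicit unit sequences and
    spacers given either as explicit sequences or as lengths (random)."""

    units: list[str]  # first unit is the reference copy
    spacers: list  # str (explicit sequence) or int (random of that length)

    def __post_init__(self):
        if len(self.spacers) != len(self.units) - 1:
            raise ValueError("need one spacer per adjacent unit pair")

    def spacer_seq(self, i: int, rng) -> str:
        sp = self.spacers[i]
        return sp.upper() if isinstance(sp, str) else _random_dna(rng, sp)


@dataclass
class SimConfig:
    """Study conditions for one synthetic query plasmid."""

    seed: int = 0
    n_genes: int = 50
    length_bp: int | None = None  # auto-sized when None
    mean_genes_per_run: float = 3.0
    within_gap: tuple[int, int] = (0, 19)  # < operon max_gap
    between_gap: tuple[int, int] = (20, 150)  # >= operon max_gap
    protein_len: tuple[int, int] = (80, 200)
    run_sizes: list[int] | None = None  # explicit override of run geometry
    iterons: IteronSpec | None = None

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.within_gap[1] >= self.between_gap[0]:
            raise ValueError("within-run gaps must stay below between-run gaps")


@dataclass
class GroundTruth:
    """Everything planted in a synthetic record, re-checkable against it."""

    operons: list[list[str]] = field(default_factory=list)  # locus tags per run
    genes: dict = field(default_factory=dict)  # locus -> {start,end,strand,protein}
    homologs: dict = field(default_factory=dict)  # locus -> {partner, identity_pct}
    permutation: list[int] | None = None
    elements: list[dict] = field(default_factory=list)
    iterons: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _rng(seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *counters])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(AA20), size=length - 1))
    return "M" + body


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for i, aa in enumerate(protein):
        opts = _AA_TO_CODONS[aa]
        if i == 0:
            # avoid alternative start codons for a non-M first residue,
            # which would re-translate as M under bacterial CDS rules
            if aa == "M":
                opts = ["ATG"]
            else:
                non_start = [c for c in opts if c not in _TABLE.start_codons]
                opts = non_start or opts
        codons.append(opts[rng.integers(len(opts))])
    codons.append("TAA")
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_query(config: SimConfig) -> tuple[PlasmidRecord, GroundTruth]:
    """Build a circular plasmid whose CDS follow the configured strand-run
    geometry, plus optional iteron array in the tail region."""
    seed = config.seed
    layout_rng = _rng(seed, 0)
    # run sizes
    if config.run_sizes is not None:
        sizes = list(config.run_sizes)
        if sum(sizes) != config.n_genes:
            raise ValueError("run_sizes must sum to n_genes")
    else:
        sizes = []
        remaining = config.n_genes
        while remaining > 0:
            s = 1 + layout_rng.poisson(max(config.mean_genes_per_run - 1.0, 0.0))
            sizes.append(int(min(s, remaining)))
            remaining -= sizes[-1]
    # genes
    genes = []
    for g in range(config.n_genes):
        grng = _rng(seed, 1, g)
        plen = int(grng.integers(config.protein_len[0], config.protein_len[1] + 1))
        prot = _random_protein(grng, plen)
        genes.append((prot, _back_translate(grng, prot)))
    # layout
    chunks: list[str] = []
    cursor = 0

    def emit(s: str):
        nonlocal cursor
        chunks.append(s)
        cursor += len(s)

    emit(_random_dna(layout_rng, 100))
    feats: list[CdsFeature] = []
    operons: list[list[str]] = []
    gi = 0
    for size in sizes:
        strand = "+" if layout_rng.random() < 0.5 else "-"
        members = []
        for k in range(size):
            prot, nt = genes[gi]
            tag = f"SYN_{gi:04d}"
            start = cursor
            emit(nt if strand == "+" else revcomp(nt))
            feats.append(
                CdsFeature(tag, start, cursor, strand,
                           product="hypothetical protein", protein=prot)
            )
            members.append(tag)
            gi += 1
            if k < size - 1:
                emit(_random_dna(
                    layout_rng,
                    int(layout_rng.integers(config.within_gap[0],
                                            config.within_gap[1] + 1)),
                ))
        operons.append(members)
        emit(_random_dna(
            layout_rng,
            int(layout_rng.integers(config.between_gap[0],
                                    config.between_gap[1] + 1)),
        ))
    truth = GroundTruth(operons=operons)
    iteron_records = []
    if config.iterons is not None:
        it = config.iterons
        positions = []
        spacer_lens = []
        for i, unit in enumerate(it.units):
            positions.append(cursor)
            emit(unit.upper())
            if i < len(it.units) - 1:
                sp = it.spacer_seq(i, layout_rng)
                spacer_lens.append(len(sp))
                emit(sp)
        iteron_records.append(
            {
                "unit_len": len(it.units[0]),
                "positions": positions,
                "spacer_lens": spacer_lens,
                "units": [u.upper() for u in it.units],
            }
        )
        emit(_random_dna(layout_rng, 30))
    # tail padding: keeps the last run from joining the first across the origin
    tail = max(config.between_gap[0] + 10, 50)
    emit(_random_dna(layout_rng, tail))
    seq = "".join(chunks)
    if config.length_bp is not None:
        if config.length_bp < len(seq):
            raise ValueError(
                f"genes need {len(seq)} bp but length_bp={config.length_bp}"
            )
        seq += _random_dna(layout_rng, config.length_bp - len(seq))
    record = PlasmidRecord(f"synplasmid_{seed}", seq, "circular", feats,
                           {"organism": "synthetic construct"})
    truth.genes = {
        f.locus_tag: {
            "start": f.start, "end": f.end, "strand": f.strand, "protein": f.protein
        }
        for f in feats
    }
    truth.iterons = iteron_records
    validate_truth(record, truth)
    return record, truth


def _mutate_protein(
    rng: np.random.Generator, protein: str, identity_pct: float
) -> tuple[str, float]:
    """Substitute enough positions (never the initial M) to hit the
    requested identity; returns the mutant and its realized identity."""
    n = len(protein)
    k = int(round((1.0 - identity_pct / 100.0) * n))
    k = min(k, n - 1)
    sites = rng.choice(np.arange(1, n), size=k, replace=False) if k else []
    prot = list(protein)
    for s in sites:
        old = prot[s]
        choices = [a for a in AA20 if a != old]
        prot[s] = choices[rng.integers(len(choices))]
    realized = 100.0 * (n - k) / n
    return "".join(prot), realized


def derive_target(
    query: PlasmidRecord,
    divergence_plan: list[tuple[float, float]],
    seed: int,
    shuffle: bool = False,
    target_id: str | None = None,
) -> tuple[PlasmidRecord, GroundTruth]:
    """A target plasmid sharing part of the query's gene content.

    ``divergence_plan`` lists (fraction of query genes, target protein
    identity %); fractions must sum to <= 1. The listed fractions of
    query genes are copied at the stated identity; all remaining genes
    are replaced by unrelated random proteins. Gene order is optionally
    shuffled with the permutation recorded in the ground truth.
    """
    fracs = [f for f, _ in divergence_plan]
    if sum(fracs) > 1.0 + 1e-9:
        raise ValueError("divergence plan fractions must sum to <= 1")
    qry = query.proteome()
    n = len(qry)
    rng = _rng(seed, 100)
    order = rng.permutation(n)  # which query genes fall in which plan slice
    proteins: list[tuple[str, str, float | None]] = []  # (partner, protein, identity)
    idx = 0
    for frac, ident in divergence_plan:
        count = int(round(frac * n))
        for j in order[idx : idx + count]:
            grng = _rng(seed, 101, int(j))
            mutant, realized = _mutate_protein(grng, qry[j].protein, ident)
            proteins.append((qry[j].locus_tag, mutant, realized))
        idx += count
    for m, j in enumerate(order[idx:]):
        grng = _rng(seed, 102, int(j))
        plen = int(grng.integers(80, 201))
        proteins.append((None, _random_protein(grng, plen), None))
    proteins.sort(key=lambda t: (t[0] is None, t[0] or ""))
    perm = None
    if shuffle:
        perm = [int(x) for x in rng.permutation(len(proteins))]
        proteins = [proteins[i] for i in perm]
    feats = []
    chunks = []
    cursor = 0
    lrng = _rng(seed, 103)
    chunks.append(_random_dna(lrng, 100))
    cursor += 100
    truth = GroundTruth()
    for m, (partner, prot, ident) in enumerate(proteins):
        tag = f"TGT_{m:04d}"
        nt = _back_translate(_rng(seed, 104, m), prot)
        start = cursor
        chunks.append(nt)
        cursor += len(nt)
        feats.append(CdsFeature(tag, start, cursor, "+",
                                product="hypothetical protein", protein=prot))
        gap = _random_dna(lrng, 50)
        chunks.append(gap)
        cursor += len(gap)
        if partner is not None:
            truth.homologs[tag] = {"partner": partner, "identity_pct": ident}
    truth.permutation = perm
    rec = PlasmidRecord(
        target_id or f"target_{seed}", "".join(chunks), "circular", feats,
        {"organism": "synthetic construct"},
    )
    truth.genes = {
        f.locus_tag: {
            "start": f.start, "end": f.end, "strand": f.strand, "protein": f.protein
        }
        for f in feats
    }
    validate_truth(rec, truth)
    return rec, truth


def plant_iterons(
    record: PlasmidRecord,
    truth: GroundTruth,
    spec: IteronSpec,
    at: int,
) -> tuple[PlasmidRecord, GroundTruth]:
    """Insert a tandem iteron array at position ``at`` (intergenic)."""
    rng = _rng(len(record.sequence), 7)
    parts = []
    positions = []
    spacer_lens = []
    cursor = at
    for i, unit in enumerate(spec.units):
        positions.append(cursor)
        parts.append(unit.upper())
        cursor += len(unit)
        if i < len(spec.units) - 1:
            sp = spec.spacer_seq(i, rng)
            spacer_lens.append(len(sp))
            parts.append(sp)
            cursor += len(sp)
    insert = "".join(parts)
    rec2, truth2 = _insert(record, truth, at, insert)
    truth2.iterons.append(
        {
            "unit_len": len(spec.units[0]),
            "positions": positions,
            "spacer_lens": spacer_lens,
            "units": [u.upper() for u in spec.units],
        }
    )
    validate_truth(rec2, truth2)
    return rec2, truth2


def _shift(x: int, at: int, by: int) -> int:
    return x + by if x >= at else x


def _shift_end(x: int, at: int, by: int) -> int:
    # a half-open end exactly at the insertion point must not extend
    return x + by if x > at else x


def _insert(
    record: PlasmidRecord, truth: GroundTruth, at: int, insert: str
) -> tuple[PlasmidRecord, GroundTruth]:
    """Insert raw sequence at ``at``; shift features and truth coordinates."""
    for f in record.cds:
        if f.start < at < f.end:
            raise ValueError(f"insertion at {at} would split CDS {f.locus_tag}")
    by = len(insert)
    seq = record.sequence[:at] + insert + record.sequence[at:]
    feats = [
        CdsFeature(
            f.locus_tag, _shift(f.start, at, by), _shift_end(f.end, at, by),
            f.strand, f.product, f.protein, f.pseudo, f.wraps_origin,
        )
        for f in record.cds
    ]
    t2 = GroundTruth(
        operons=[list(m) for m in truth.operons],
        genes={
            tag: {
                **g,
                "start": _shift(g["start"], at, by),
                "end": _shift_end(g["end"], at, by),
            }
            for tag, g in truth.genes.items()
        },
        homologs=dict(truth.homologs),
        permutation=truth.permutation,
        elements=[],
        iterons=[],
    )
    for e in truth.elements:
        e2 = dict(e)
        s0, s1 = e["span"]
        if s0 < at < s1:
            e2["span"] = [s0, s1 + by]  # insertion inside: span widens
        else:
            e2["span"] = [_shift(s0, at, by), _shift_end(s1, at, by)]
        e2["ir_left"] = (
            [_shift(e["ir_left"][0], at, by), _shift_end(e["ir_left"][1], at, by)]
            if e["ir_left"] else None
        )
        e2["ir_right"] = (
            [_shift(e["ir_right"][0], at, by), _shift_end(e["ir_right"][1], at, by)]
            if e["ir_right"] else None
        )
        t2.elements.append(e2)
    for it in truth.iterons:
        i2 = dict(it)
        i2["positions"] = [_shift(p, at, by) for p in it["positions"]]
        t2.iterons.append(i2)
    return (
        PlasmidRecord(record.id, seq, record.topology, feats, dict(record.metadata)),
        t2,
    )


def plant_element(
    record: PlasmidRecord,
    truth: GroundTruth,
    descriptor: ElementDescriptor,
    seed: int,
    at: int | None = None,
    n_cargo: int = 1,
    truncated: str = "none",
    nested_into: int | None = None,
    ir_mismatches: int = 0,
    element_id: str | None = None,
) -> tuple[PlasmidRecord, GroundTruth]:
    """Insert a transposable element, creating a TSD at the target site.

    ``truncated`` omits one terminal IR ('left' or 'right'); a
    right-truncated element carries no cargo after its transposase, so
    its span ends at the transposase CDS (or, after a later nested
    insertion, at the child's right TSD copy). ``nested_into`` inserts
    inside an existing element (by index into ``truth.elements``),
    splitting it; inserting into an existing element without
    ``nested_into`` is an error.
    """
    rng = _rng(seed, 5)
    eid = element_id or f"EL{len(truth.elements)}"
    left_ir = descriptor.ir_seq.upper()
    right_ir = revcomp(left_ir)
    if ir_mismatches:
        ir = list(right_ir)
        sites = rng.choice(len(ir), size=ir_mismatches, replace=False)
        for s in sites:
            ir[s] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ir[s]]
        right_ir = "".join(ir)

    # element content
    parts: list[str] = []
    feats: list[tuple[str, int, int, str, str]] = []  # tag, start, end, product, prot
    cursor = 0

    def emit(s: str):
        nonlocal cursor
        parts.append(s)
        cursor += len(s)

    has_left = truncated != "left"
    has_right = truncated != "right"
    ir_left_span = None
    ir_right_span = None
    if has_left:
        ir_left_span = (cursor, cursor + len(left_ir))
        emit(left_ir)
        emit(_random_dna(rng, 30))
    tnp_name, tnp_prot = sorted(descriptor.proteins.items())[0]
    nt = _back_translate(_rng(seed, 6), tnp_prot)
    feats.append((f"{eid}_tnpA", cursor, cursor + len(nt),
                  f"{descriptor.family_label} transposase", tnp_prot))
    emit(nt)
    if truncated != "right":
        for c in range(n_cargo):
            emit(_random_dna(rng, 25))
            crng = _rng(seed, 7, c)
            prot = _random_protein(crng, int(crng.integers(80, 151)))
            nt = _back_translate(crng, prot)
            feats.append((f"{eid}_cargo{c}", cursor, cursor + len(nt),
                          "hypothetical protein", prot))
            emit(nt)
        emit(_random_dna(rng, 30))
    if has_right:
        ir_right_span = (cursor, cursor + len(right_ir))
        emit(right_ir)
    content = "".join(parts)
    tsd_len = descriptor.tsd_len if (has_left and has_right) else 0

    # insertion point
    n = record.length_bp
    spans = [tuple(e["span"]) for e in truth.elements]
    if at is None:
        if nested_into is not None:
            s0, s1 = truth.elements[nested_into]["span"]
            parent = truth.elements[nested_into]
            if parent.get("truncated_side") == "right":
                at = s1  # insert at the truncation point
            else:
                # inside the parent, just before its right IR
                at = parent["ir_right"][0] - 5
        else:
            # first intergenic position clear of genes and elements
            at = None
            prev_end = 0
            occupied = sorted(
                [(f.start, f.end) for f in record.cds] + [tuple(s) for s in spans]
            )
            for s0, s1 in occupied:
                if s0 - prev_end > 10:
                    at = prev_end + 5
                    break
                prev_end = max(prev_end, s1)
            if at is None:
                if n - prev_end > 10:
                    at = prev_end + 5
                else:
                    raise ValueError("no intergenic room for the element")
    inside = [
        i for i, (s0, s1) in enumerate(spans) if s0 < at < s1
    ]
    if nested_into is None and inside:
        raise ValueError(
            "insertion would fall inside an existing element; pass nested_into"
        )

    if tsd_len:
        tsd = record.sequence[at : at + tsd_len]
        insert = tsd + content
        span0 = at + tsd_len
    else:
        tsd = None
        insert = content
        span0 = at
    rec2, t2 = _insert(record, truth, at, insert)
    # nested parent span widening is handled by _insert; but an insertion at
    # a right-truncated parent's end must extend that parent explicitly
    if nested_into is not None:
        parent = t2.elements[nested_into]
        if parent.get("truncated_side") == "right":
            parent["span"] = [parent["span"][0], span0 + len(content) + (tsd_len or 0)]
    off = span0
    cds = list(rec2.cds)
    for tag, s, e, product, prot in feats:
        cds.append(CdsFeature(tag, off + s, off + e, "+", product, prot))
    rec2 = PlasmidRecord(rec2.id, rec2.sequence, rec2.topology, cds, rec2.metadata)
    element = {
        "id": eid,
        "family": descriptor.family_label,
        "span": [span0, span0 + len(content)],
        "ir_left": [off + ir_left_span[0], off + ir_left_span[1]] if ir_left_span else None,
        "ir_right": [off + ir_right_span[0], off + ir_right_span[1]] if ir_right_span else None,
        "tsd": tsd,
        "truncated_side": truncated,
        "parent": nested_into,
        "ir_mismatches": ir_mismatches,
        "machinery": [f"{eid}_tnpA"],
        "cargo": [t for t, *_ in feats if "cargo" in t],
    }
    t2.elements.append(element)
    t2.genes.update(
        {
            tag: {"start": off + s, "end": off + e, "strand": "+", "protein": prot}
            for tag, s, e, _, prot in feats
        }
    )
    validate_truth(rec2, t2)
    return rec2, t2


def validate_truth(record: PlasmidRecord, truth: GroundTruth) -> None:
    """Independent re-check of every ground-truth assertion against the
    emitted record; raises AssertionError on any inconsistency."""
    by_tag = {f.locus_tag: f for f in record.cds}
    for tag, g in truth.genes.items():
        f = by_tag[tag]
        assert (f.start, f.end, f.strand) == (g["start"], g["end"], g["strand"]), tag
        assert translate_cds(f.nt_span(record.sequence)) == g["protein"], tag
    for members in truth.operons:
        strands = {by_tag[m].strand for m in members}
        assert len(strands) == 1, f"operon {members} mixes strands"
        run = [by_tag[m] for m in members]
        for a, b in zip(run, run[1:]):
            assert 0 <= b.start - a.end < 20, f"gap {b.start - a.end} in {members}"
    for it in truth.iterons:
        L = it["unit_len"]
        first = record.sequence[it["positions"][0] : it["positions"][0] + L]
        for p, u in zip(it["positions"], it["units"]):
            got = record.sequence[p : p + L]
            assert got == u, f"iteron unit at {p}: {got} != {u}"
            assert hamming(got, first) <= 1
    for e in truth.elements:
        s0, s1 = e["span"]
        if e["ir_left"]:
            a0, a1 = e["ir_left"]
            assert a0 == s0, e["id"]
        if e["ir_right"] and e.get("truncated_side") == "none" and e["parent"] is None:
            pass
        if e["ir_left"] and e["ir_right"]:
            la = record.sequence[e["ir_left"][0] : e["ir_left"][1]]
            ra = record.sequence[e["ir_right"][0] : e["ir_right"][1]]
            assert hamming(la, revcomp(ra)) <= e["ir_mismatches"], e["id"]
            if e["tsd"]:
                t = len(e["tsd"])
                assert (
                    record.sequence[s0 - t : s0]
                    == record.sequence[e["ir_right"][1] : e["ir_right"][1] + t]
                    == e["tsd"]
                ), e["id"]
        if e["parent"] is not None:
            p0, p1 = truth.elements[e["parent"]]["span"]
            assert p0 < s0 and s1 < p1, f"{e['id']} not strictly inside parent"


def write_bundle(
    out_dir,
    config: SimConfig,
    targets: list[tuple[float, float]] | None = None,
    shuffle: bool = False,
) -> Path:
    """Write query.gb, targets/*.gb, truth.json and a config echo."""
    from .io import write_genbank

    out = Path(out_dir)
    (out / "targets").mkdir(parents=True, exist_ok=True)
    record, truth = generate_query(config)
    write_genbank(record, out / "query.gb")
    truths = {"query": json.loads(truth.to_json())}
    for i, (frac, ident) in enumerate(targets or []):
        trec, ttruth = derive_target(
            record, [(frac, ident)], seed=config.seed + 1 + i,
            shuffle=shuffle, target_id=f"target_{i}_f{int(frac * 100)}",
        )
        write_genbank(trec, out / "targets" / f"{trec.id}.gb")
        truths[trec.id] = json.loads(ttruth.to_json())
    (out / "truth.json").write_text(json.dumps(truths, indent=1, sort_keys=True))
    lines = ["[simulation]"]
    for k, v in (
        ("seed", config.seed),
        ("n_genes", config.n_genes),
        ("mean_genes_per_run", config.mean_genes_per_run),
    ):
        lines.append(f"{k} = {v}")
    (out / "config.toml").write_text("\n".join(lines) + "\n")
    return out
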