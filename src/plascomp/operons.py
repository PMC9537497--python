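"""Operon calling by strand and intergenic distance.

An operon, in the operational sense used throughout this package, is a
maximal run of same-strand genes in which each intergenic gap is
strictly below ``max_gap`` (default 20 bp). Gaps are measured between
half-open intervals (``start(next) - end(prev)``), so abutting genes
have gap 0 and overlapping genes a negative gap — both always join.
Any opposite-strand gene breaks a run. On circular records the first
and last CDS join across the origin when they satisfy the same rule,
so calls are invariant under rotation of the coordinate origin.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import CdsFeature, PlasmidRecord

__all__ = [
    "OperonCluster",
    "call_operons",
    "label_clusters",
    "write_operons_gff3",
    "DEFAULT_KEYWORD_TABLE",
]


@dataclass
class OperonCluster:
    cluster_id: int
    strand: str
    members: list[str]  # locus tags in run order
    start: int  # start of the first member
    end: int  # end of the last member; may be < start for origin-wrapping runs
    label: str | None = None


def _joined(prev: CdsFeature, nxt: CdsFeature, gap: int, max_gap: int) -> bool:
    return prev.strand == nxt.strand and (gap < max_gap or gap <= 0)


def call_operons(record: PlasmidRecord, max_gap: int = 20) -> list[OperonCluster]:
    """Partition all CDS (pseudo included) into maximal same-strand runs."""
    feats = record.cds
    if not feats:
        return []
    runs: list[list[CdsFeature]] = [[feats[0]]]
    for f in feats[1:]:
        prev = runs[-1][-1]
        gap = f.start - prev.end
        if _joined(prev, f, gap, max_gap):
            runs[-1].append(f)
        else:
            runs.append([f])
    if record.topology == "circular" and len(runs) > 1:
        first, last = runs[0][0], runs[-1][-1]
        gap = first.start + record.length_bp - last.end
        if _joined(last, first, gap, max_gap):
            runs[0] = runs.pop() + runs[0]
    elif record.topology == "circular" and len(runs) == 1 and len(feats) > 1:
        pass  # a single run never merges with itself
    clusters = []
    for i, run in enumerate(runs, start=1):
        clusters.append(
            OperonCluster(
                cluster_id=i,
                strand=run[0].strand,
                members=[f.locus_tag for f in run],
                start=run[0].start,
                end=run[-1].end % record.length_bp
                if run[-1].end > record.length_bp
                else run[-1].end,
            )
        )
    return clusters


# Keyword -> functional category, matched in order against product strings.
# A convenience classification, deliberately coarse; first match wins.
DEFAULT_KEYWORD_TABLE: dict[str, str] = {
    "styrene": "aromatic degradation",
    "phenylprop": "aromatic degradation",
    "phenylacet": "aromatic degradation",
    "monooxygenase": "aromatic degradation",
    "dioxygenase": "aromatic degradation",
    "mercur": "heavy-metal resistance",
    "tellurite": "heavy-metal resistance",
    "tellurium": "heavy-metal resistance",
    "chromate": "heavy-metal resistance",
    "arsen": "heavy-metal resistance",
    "copper": "heavy-metal resistance",
    "czc": "heavy-metal resistance",
    "efflux": "efflux",
    "rnd": "efflux",
    "outer membrane channel": "efflux",
    "conjugal": "conjugation/T4SS",
    "type iv secretion": "conjugation/T4SS",
    "t4ss": "conjugation/T4SS",
    "trb": "conjugation/T4SS",
    "relaxase": "conjugation/T4SS",
    "coupling protein": "conjugation/T4SS",
    "pilus": "conjugation/T4SS",
    "replication": "replication/partitioning",
    "partition": "replication/partitioning",
    "para": "replication/partitioning",
    "parb": "replication/partitioning",
    "repa": "replication/partitioning",
    "transposase": "mobile element",
    "integrase": "mobile element",
    "resolvase": "mobile element",
    "insertion sequence": "mobile element",
    "recombinase": "mobile element",
    "chaperone": "stress response",
    "heat shock": "stress response",
    "cold shock": "stress response",
    "universal stress": "stress response",
    "toxin": "stress response",
    "regulator": "regulation",
    "repressor": "regulation",
    "activator": "regulation",
    "sigma": "regulation",
    "transporter": "transport",
    "permease": "transport",
    "abc ": "transport",
}

UNLABELED = "hypothetical/unknown"


def label_clusters(
    clusters: list[OperonCluster],
    record: PlasmidRecord,
    keyword_table: dict[str, str] | None = None,
) -> list[OperonCluster]:
    """Attach a functional category to each cluster by product keywords.

    The label is the category of the first keyword (in table order)
    found in any member's product string; clusters with no match get
    ``hypothetical/unknown``.
    """
    table = keyword_table if keyword_table is not None else DEFAULT_KEYWORD_TABLE
    if not table:
        raise ValueError("keyword table must be non-empty")
    products = {f.locus_tag: f.product.lower() for f in record.cds}
    for cl in clusters:
        text = " | ".join(products.get(tag, "") for tag in cl.members)
        cl.label = next(
            (cat for kw, cat in table.items() if kw in text), UNLABELED
        )
    return clusters


def write_operons_gff3(
    clusters: list[OperonCluster], record: PlasmidRecord, path
) -> None:
    """Clusters as GFF3 ``operon`` features (1-based inclusive spans)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {record.length_bp}\n")
        for c in clusters:
            end = c.end if c.end > c.start else record.length_bp  # wrap shown to origin
            attrs = f"ID=operon{c.cluster_id};genes={','.join(c.members)}"
            if c.label:
                attrs += f";function={c.label}"
            fh.write(
                f"{record.id}\tplascomp\toperon\t{c.start + 1}\t{end}\t.\t"
                f"{c.strand}\t.\t{attrs}\n"
            )
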