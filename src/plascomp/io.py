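"""GenBank / FASTA / TSV input and output for plasmid records.

The GenBank reader keeps only what the downstream analyses need: the
sequence, circular/linear topology (from the LOCUS line; absent means
linear) and CDS features with locus tag, product and protein. CDS
without a ``/translation`` qualifier are translated from the sequence;
CDS that translate with an internal stop are flagged pseudo and carry
no protein.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import (
    CdsFeature,
    InternalStopError,
    PlasmidRecord,
    PrimerPair,
    translate_cds,
)

__all__ = [
    "FileFormatError",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "write_cds_table",
    "read_primer_table",
    "write_primer_table",
]

# fixed LOCUS date so identical records serialize byte-identically
_GB_DATE = "01-JAN-1980"


class FileFormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


def _cds_from_feature(feat, sequence: str, index: int) -> CdsFeature:
    loc = feat.location
    n = len(sequence)
    wraps = False
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join(x..n, 1..y) on a circular record
        if (
            len(parts) == 2
            and int(parts[-1].end) == n
            and int(parts[0].start) == 0
        ):
            start = int(parts[-1].start)
            end = n + int(parts[0].end)
            wraps = True
        else:
            start, end = int(loc.start), int(loc.end)
    else:
        start, end = int(loc.start), int(loc.end)
    strand = "-" if loc.strand == -1 else "+"
    q = feat.qualifiers
    tag = q.get("locus_tag", q.get("gene", [f"CDS_{index:04d}"]))[0]
    product = q.get("product", [""])[0]
    pseudo = "pseudo" in q or "pseudogene" in q
    protein = q.get("translation", [""])[0]
    f = CdsFeature(tag, start, end, strand, product, protein, pseudo, wraps)
    if not protein and not pseudo:
        try:
            f.protein = translate_cds(f.nt_span(sequence))
        except InternalStopError:
            f.pseudo = True
            f.protein = ""
    return f


def read_genbank(path) -> PlasmidRecord:
    """Read a single-record GenBank flat file into a :class:`PlasmidRecord`."""
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FileFormatError(f"{path}: not a single-record GenBank file ({exc})")
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 10:
        raise FileFormatError(f"{path}: record has no sequence")
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    cds = [
        _cds_from_feature(f, seq, i)
        for i, f in enumerate(rec.features)
        if f.type == "CDS"
    ]
    meta = {
        k: rec.annotations[k]
        for k in ("organism", "source")
        if k in rec.annotations
    }
    return PlasmidRecord(rec.id or path.stem, seq, topology, cds, meta)


def _feature_for(f: CdsFeature, n: int) -> SeqFeature:
    strand = -1 if f.strand == "-" else 1
    if f.wraps_origin:
        loc = CompoundLocation(
            [
                SimpleLocation(f.start, n, strand),
                SimpleLocation(0, f.end % n, strand),
            ]
        )
    else:
        loc = SimpleLocation(f.start, f.end, strand)
    q = {"locus_tag": [f.locus_tag]}
    if f.product:
        q["product"] = [f.product]
    if f.pseudo:
        q["pseudo"] = [""]
    elif f.protein:
        q["translation"] = [f.protein]
    return SeqFeature(loc, type="CDS", qualifiers=q)


def write_genbank(record: PlasmidRecord, path) -> None:
    """Write a :class:`PlasmidRecord` as a GenBank flat file (deterministic)."""
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description=record.metadata.get("organism", "synthetic plasmid"),
        annotations={
            "molecule_type": "DNA",
            "topology": record.topology,
            "date": _GB_DATE,
            "data_file_division": "BCT",
        },
    )
    rec.features = [
        SeqFeature(SimpleLocation(0, record.length_bp), type="source")
    ] + [_feature_for(f, record.length_bp) for f in record.cds]
    SeqIO.write(rec, str(path), "genbank")


def read_fasta(path) -> PlasmidRecord:
    """Read the first sequence of a FASTA file as an unannotated record."""
    path = Path(path)
    try:
        rec = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise FileFormatError(f"{path}: empty FASTA file")
    return PlasmidRecord(rec.id, str(rec.seq).upper(), "linear", [])


def write_fasta(record: PlasmidRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n")
        for i in range(0, record.length_bp, 70):
            fh.write(record.sequence[i : i + 70] + "\n")


def write_cds_table(record: PlasmidRecord, path) -> None:
    """CDS table as TSV: locus_tag, start, end, strand, product, pseudo."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["locus_tag", "start", "end", "strand", "product", "pseudo"])
        for f in record.cds:
            w.writerow(
                [f.locus_tag, f.start, f.end, f.strand, f.product, int(f.pseudo)]
            )


def read_primer_table(path) -> list[PrimerPair]:
    """Primer pairs from TSV with header name_fw, seq_fw, name_rv, seq_rv."""
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name_fw", "seq_fw", "name_rv", "seq_rv"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FileFormatError(
                f"{path}: primer table must have columns {sorted(required)}"
            )
        for row in reader:
            pairs.append(
                PrimerPair(
                    row["name_fw"], row["seq_fw"], row["name_rv"], row["seq_rv"]
                )
            )
    return pairs


def write_primer_table(pairs: list[PrimerPair], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name_fw", "seq_fw", "name_rv", "seq_rv"])
        for p in pairs:
            w.writerow([p.name_fw, p.seq_fw, p.name_rv, p.seq_rv])
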