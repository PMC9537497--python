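"""Core domain types: annotated plasmid records, CDS features and primers.

All coordinates are 0-based, half-open, on the plus strand. GenBank's
1-based inclusive positions are converted at the I/O boundary only
(:mod:`plascomp.io`). Features crossing the origin of a circular record
carry ``wraps_origin=True`` and a *virtual* end greater than the record
length; positions are normalized modulo the length on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


class InternalStopError(ValueError):
    """A coding sequence translates with a stop codon before its end.

    Carries the translated protein (stops as ``*``) in ``partial``.
    """

    def __init__(self, partial: str):
        super().__init__("internal stop codon in CDS translation")
        self.partial = partial


def translate_cds(nt: str, table: int = 11) -> str:
    """Translate a strand-oriented coding sequence.

    Bacterial-style translation: the first codon is rendered as M when it
    is an annotated start codon of the table, codons containing N (or any
    non-ACGT base) become X, an incomplete tail codon is trimmed, and the
    terminal stop is stripped. An internal stop raises
    :class:`InternalStopError`.
    """
    if not nt:
        raise ValueError("empty coding sequence")
    nt = nt.upper()
    ct = CodonTable.unambiguous_dna_by_id[table]
    codons = [nt[i : i + 3] for i in range(0, len(nt) - len(nt) % 3, 3)]
    if not codons:
        raise ValueError("coding sequence shorter than one codon")
    aa = []
    for i, codon in enumerate(codons):
        if any(b not in "ACGT" for b in codon):
            aa.append("X")
        elif codon in ct.stop_codons:
            aa.append("*")
        elif i == 0 and codon in ct.start_codons:
            aa.append("M")
        else:
            aa.append(ct.forward_table[codon])
    prot = "".join(aa)
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise InternalStopError(prot)
    return prot


@dataclass
class CdsFeature:
    """One protein-coding feature on the plus-strand coordinate system."""

    locus_tag: str
    start: int
    end: int  # exclusive; > record length only when wraps_origin
    strand: str  # '+' or '-'
    product: str = ""
    protein: str = ""
    pseudo: bool = False
    wraps_origin: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.locus_tag}: start {self.start} must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def nt_span(self, sequence: str) -> str:
        """Strand-oriented nucleotide sequence of the feature."""
        n = len(sequence)
        if self.wraps_origin:
            nt = sequence[self.start :] + sequence[: self.end % n]
        else:
            nt = sequence[self.start : self.end]
        return revcomp(nt) if self.strand == "-" else nt


@dataclass
class PlasmidRecord:
    """An annotated (usually circular) plasmid: sequence + ordered CDS."""

    id: str
    sequence: str
    topology: str = "circular"  # or "linear"
    cds: list[CdsFeature] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-ACGTN bases {sorted(bad)}")
        self.cds = sorted(self.cds, key=lambda f: (f.start, f.end))
        n = len(self.sequence)
        for f in self.cds:
            limit = 2 * n if f.wraps_origin else n
            if not (0 <= f.start < n and f.end <= limit):
                raise ValueError(
                    f"{self.id}/{f.locus_tag}: interval [{f.start},{f.end}) "
                    f"outside record of length {n}"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def proteome(self) -> list[CdsFeature]:
        """Non-pseudo CDS with a usable protein, in coordinate order."""
        return [f for f in self.cds if not f.pseudo and f.protein]

    def rotated(self, offset: int) -> "PlasmidRecord":
        """Circular permutation moving position ``offset`` to position 0.

        Features are re-coordinated; a feature cut by the new origin is
        flagged ``wraps_origin`` with a virtual end beyond the length.
        """
        if self.topology != "circular":
            raise ValueError("can only rotate circular records")
        n = self.length_bp
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.cds:
            start = (f.start - offset) % n
            end = start + f.length
            feats.append(
                CdsFeature(
                    f.locus_tag, start, end, f.strand, f.product,
                    f.protein, f.pseudo, wraps_origin=end > n,
                )
            )
        return PlasmidRecord(self.id, seq, self.topology, feats, dict(self.metadata))


@dataclass
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    name_fw: str
    seq_fw: str
    name_rv: str
    seq_rv: str

    def __post_init__(self):
        self.seq_fw = self.seq_fw.upper()
        self.seq_rv = self.seq_rv.upper()
        for name, seq in ((self.name_fw, self.seq_fw), (self.name_rv, self.seq_rv)):
            if len(seq) < 15:
                raise ValueError(f"primer {name}: length {len(seq)} < 15")
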