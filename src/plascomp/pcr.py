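"""In-silico PCR: predict amplicons of a primer pair on a plasmid.

Primer binding allows up to ``max_mismatch`` substitutions (no indels)
but demands an exact match over the three 3'-terminal bases — the
standard polymerase-extension clamp. Amplicon length is measured from
the 5' end of the forward binding site to the 5' end of the reverse
binding site on the opposite strand, inclusive of both primers. On
circular records products may span the origin; products above
``max_product`` (default 20 kb) are suppressed as unamplifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import PlasmidRecord, PrimerPair, revcomp

__all__ = ["Amplicon", "in_silico_pcr"]


@dataclass(frozen=True)
class Amplicon:
    start: int  # 5' end of forward primer site, plus-strand coordinate
    end: int  # position after the 5' end of the reverse primer site
    length_bp: int


def _binding_sites(seq: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where the primer (already oriented to the plus
    strand) binds with <= max_mismatch substitutions and a perfect
    3-base clamp at its 3' end (the right end of the given string)."""
    m = len(primer)
    hits = []
    clamp = primer[-3:]
    for i in range(len(seq) - m + 1):
        if seq[i + m - 3 : i + m] != clamp:
            continue
        mm = 0
        for a, b in zip(seq[i : i + m - 3], primer[:-3]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            hits.append(i)
    return hits


def in_silico_pcr(
    record: PlasmidRecord,
    pair: PrimerPair,
    max_mismatch: int = 2,
    max_product: int = 20_000,
) -> list[Amplicon]:
    """All products the primer pair would amplify from the record.

    Returns an empty list (not an error) when either primer has no
    binding site. Both primer orientations are considered, i.e. the
    pair also reports products where the "reverse" primer sits on the
    plus strand upstream of the "forward" one on the minus strand.
    """
    n = record.length_bp
    circular = record.topology == "circular"
    # search on a doubled sequence so origin-spanning sites/products appear
    search = record.sequence + (record.sequence if circular else "")

    def sites(primer: str, plus: bool) -> list[tuple[int, int]]:
        """(5'-end plus-strand position, site span start) for one primer
        on one strand. For a plus-strand site the 5' end is the leftmost
        base; for a minus-strand site it is the rightmost base."""
        m = len(primer)
        out = []
        oriented = primer if plus else revcomp(primer)
        for i in _binding_sites(search, oriented, max_mismatch):
            if i >= n:  # canonical copy only
                continue
            out.append((i if plus else i + m - 1, i))
        return out

    products: set[tuple[int, int, int]] = set()
    for fw, rv in ((pair.seq_fw, pair.seq_rv), (pair.seq_rv, pair.seq_fw)):
        for f5, _ in sites(fw, plus=True):
            for r5, _ in sites(rv, plus=False):
                end = r5 + 1
                if end <= f5:
                    if not circular:
                        continue
                    end += n
                length = end - f5
                if len(fw) + len(rv) <= length <= max_product:
                    products.add((f5, end, length))
    return [Amplicon(*p) for p in sorted(products)]
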