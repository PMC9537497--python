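"""Direct repeats (iterons), inverted-repeat pairs, target-site
duplications, and delineation of Tn3-family transposable elements.

Coordinate conventions match the rest of the package (0-based,
half-open, plus strand). The three detectors are independent
primitives:

* :func:`find_direct_repeats` — tandem arrays of a short unit (iterons:
  17-mers with 6–7 nt spacers near a replication origin), each copy
  within a Hamming budget of the first copy.
* :func:`find_ir_pairs` — de-novo inverted-repeat pairs by seed-and-
  extend along reverse-complement anti-diagonals, after low-complexity
  masking.
* :func:`find_tsd` — the short exact duplication flanking an element,
  created at insertion (5 bp for Tn5053-type elements).

:func:`delineate_elements` assembles element calls: descriptor
transposases are anchored on the record's CDS by best-hit protein
alignment, terminal IRs are matched near each anchor (bounded Hamming
distance, forward orientation left of the anchor, reverse complement
right of it), and truncation/nesting is resolved from which IRs are
found and how spans contain one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentParams, best_hits
from .records import CdsFeature, PlasmidRecord, revcomp

__all__ = [
    "DirectRepeatArray",
    "IrPair",
    "ElementDescriptor",
    "ElementCall",
    "find_direct_repeats",
    "find_ir_pairs",
    "find_tsd",
    "delineate_elements",
    "mask_low_complexity",
    "load_descriptors",
    "write_elements_gff3",
    "hamming",
]


@dataclass
class DirectRepeatArray:
    unit_len: int
    n_copies: int
    positions: list[int]  # start of each copy, strictly increasing
    spacer_lens: list[int]  # between consecutive copies (n_copies - 1)
    max_mismatch_to_first: int
    units: list[str]


@dataclass
class IrPair:
    left: tuple[int, int]
    right: tuple[int, int]
    ir_len: int
    mismatches: int
    left_seq: str
    right_seq: str


@dataclass
class ElementDescriptor:
    """Reference description of a transposable-element family: one
    terminal IR sequence, >= 1 transposase protein, and the TSD length
    the family creates on insertion."""

    family_label: str
    ir_seq: str
    proteins: dict[str, str]
    tsd_len: int = 5

    def __post_init__(self):
        if not self.ir_seq:
            raise ValueError(f"{self.family_label}: descriptor needs an IR sequence")
        if not self.proteins:
            raise ValueError(f"{self.family_label}: descriptor needs >= 1 protein")


@dataclass
class ElementCall:
    family_label: str
    span: tuple[int, int]
    ir: IrPair | None
    tsd: str | None
    truncated_side: str = "none"  # none / left / right
    parent: int | None = None  # index into the returned call list
    cargo: list[str] = field(default_factory=list)
    anchor_locus: str = ""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------- direct repeats


def find_direct_repeats(
    seq: str,
    unit_len_range: tuple[int, int] = (15, 20),
    max_spacer: int = 10,
    max_mismatch: int = 1,
) -> list[DirectRepeatArray]:
    """Maximal tandem direct-repeat arrays.

    Scans unit lengths from longest to shortest; every copy must lie
    within ``max_mismatch`` Hamming distance of the *first* copy and
    start at most ``max_spacer`` bases after the previous copy ends.
    Arrays are maximal (not extendable by another qualifying copy on
    either side); each genomic span is reported once, at the longest
    qualifying unit length. Quadratic-ish in sequence length: meant for
    replicon regions (an origin neighbourhood), not whole chromosomes.
    """
    seq = seq.upper()
    n = len(seq)
    lo, hi = unit_len_range
    if lo < 2:
        raise ValueError("unit length must be >= 2")
    if n < 2 * lo:
        return []
    out: list[DirectRepeatArray] = []
    covered: list[tuple[int, int]] = []
    for L in range(min(hi, n // 2), lo - 1, -1):
        i = 0
        while i <= n - 2 * L:
            unit = seq[i : i + L]
            left_ok = True  # left-maximal: no qualifying copy just before
            for sp in range(0, max_spacer + 1):
                j = i - L - sp
                if j >= 0 and hamming(seq[j : j + L], unit) <= max_mismatch:
                    left_ok = False
                    break
            if not left_ok:
                i += 1
                continue
            positions = [i]
            spacers: list[int] = []
            end = i + L
            while True:
                nxt = None
                for sp in range(0, max_spacer + 1):
                    j = end + sp
                    if j + L <= n and hamming(seq[j : j + L], unit) <= max_mismatch:
                        nxt = (j, sp)
                        break
                if nxt is None:
                    break
                positions.append(nxt[0])
                spacers.append(nxt[1])
                end = nxt[0] + L
            if len(positions) >= 2:
                span = (positions[0], end)
                if not any(c0 <= span[0] and span[1] <= c1 for c0, c1 in covered):
                    units = [seq[p : p + L] for p in positions]
                    out.append(
                        DirectRepeatArray(
                            unit_len=L,
                            n_copies=len(positions),
                            positions=positions,
                            spacer_lens=spacers,
                            max_mismatch_to_first=max(
                                hamming(u, units[0]) for u in units
                            ),
                            units=units,
                        )
                    )
                    covered.append(span)
                i = end
            else:
                i += 1
    out.sort(key=lambda a: a.positions[0])
    return out


# ---------------------------------------------------------------- IR pairs

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def mask_low_complexity(
    seq: str, homopolymer: int = 12, dinucleotide: int = 16
) -> np.ndarray:
    """Boolean mask (True = masked) over homopolymer runs of length >=
    ``homopolymer`` and period-2 dinucleotide runs of length >=
    ``dinucleotide``. IR seeding skips masked positions; AT-rich
    spacers otherwise flood the search with degenerate palindromes."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= homopolymer:
            mask[i:j] = True
        i = j
    i = 0
    while i + 1 < n:
        j = i + 2
        while j < n and seq[j] == seq[j - 2]:
            j += 1
        if j - i >= dinucleotide and seq[i] != seq[i + 1]:
            mask[i:j] = True
            i = j - 1
        else:
            i += 1
    return mask


def _maximal_on_diagonal(
    match: np.ndarray,
    p_lo: int,
    p_hi: int,
    D: int,
    min_len: int,
    max_len: int,
    max_mismatch: int,
    max_span: int | None,
) -> list[tuple[int, int, int]]:
    """Maximal ``(a, L, mismatches)`` intervals on anti-diagonal ``D``.

    ``match[p]`` (a full-length boolean array) says whether ``seq[p]``
    pairs with ``seq[D - p]``; admissible left positions run over
    ``[p_lo, p_hi)``. An interval is valid when its length lies in
    ``[min_len, max_len]``, its mismatch count within budget, the right
    copy starts at or after the left copy's end, and the overall span
    respects ``max_span``. Maximal = contained in no other valid
    interval on this diagonal.
    """

    def ok(a: int, L: int) -> bool:
        if L < min_len or L > max_len:
            return False
        if a < p_lo or a + L > p_hi:
            return False
        if D - a - L + 1 < a + L:  # right copy must not cross the left copy
            return False
        if max_span is not None and (D - a + 1) - a > max_span:
            return False
        return int(match[a : a + L].sum()) >= L - max_mismatch

    res = []
    for a in range(p_lo, p_hi):
        best_L = 0
        L = min_len
        while ok(a, L):
            best_L = L
            L += 1
        if best_L:
            res.append((a, best_L, best_L - int(match[a : a + best_L].sum())))
    maximal = []
    for a, L, mm in res:
        if not any(
            a2 <= a and a + L <= a2 + L2 and (a2, L2) != (a, L)
            for a2, L2, _ in res
        ):
            maximal.append((a, L, mm))
    return maximal


def _merge_ir_pairs(pairs: list[IrPair]) -> list[IrPair]:
    """Merge overlapping reports to the longest (then fewest mismatches,
    then leftmost) representative."""

    def overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
        return x[0] < y[1] and y[0] < x[1]

    pairs = sorted(
        pairs, key=lambda p: (-p.ir_len, p.mismatches, p.left[0], p.right[0])
    )
    kept: list[IrPair] = []
    for p in pairs:
        if not any(
            overlap(p.left, k.left) and overlap(p.right, k.right) for k in kept
        ):
            kept.append(p)
    kept.sort(key=lambda p: (p.left[0], p.right[0]))
    return kept


def find_ir_pairs(
    seq: str,
    min_len: int = 20,
    max_len: int = 48,
    max_mismatch: int = 2,
    max_span: int | None = None,
    mask: bool = True,
    merge: bool = True,
) -> list[IrPair]:
    """Inverted-repeat pairs by seeded anti-diagonal scanning.

    A pair (left, right) of common length L satisfies
    ``revcomp(right_seq)`` within ``max_mismatch`` Hamming distance of
    ``left_seq``; every base pairing of such a pair lies on one
    anti-diagonal ``D = left.start + right.end - 1`` of the
    sequence-versus-reverse-complement dot plot. Exact k-mer seeds
    nominate diagonals — k is chosen as
    ``(min_len - max_mismatch) // (max_mismatch + 1)`` (capped to
    [4, 10]) so that, by pigeonhole, no qualifying pair can lack a
    seed — and each nominated diagonal is scanned around its seeds for
    maximal mismatch-bounded runs. Overlapping reports are merged to
    the longest.
    """
    seq = seq.upper()
    n = len(seq)
    if n <= 2 * min_len:
        return []
    k = max(4, min(10, (min_len - max_mismatch) // (max_mismatch + 1)))
    masked = mask_low_complexity(seq) if mask else np.zeros(n, dtype=bool)

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        if masked[i : i + k].any():
            continue
        index.setdefault(seq[i : i + k], []).append(i)

    # diagonal -> seed left-positions
    diagonals: dict[int, list[int]] = {}
    for i in range(n - k + 1):
        if masked[i : i + k].any():
            continue
        for j in index.get(revcomp(seq[i : i + k]), ()):
            if j >= i + k:
                diagonals.setdefault(i + j + k - 1, []).append(i)

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in _COMP.items():
        comp[ord(a)] = ord(b)

    pairs: list[IrPair] = []
    pad = max_len + 1
    for D, seeds in sorted(diagonals.items()):
        d_lo = max(0, D - n + 1)
        d_hi = min(n, D // 2 + 1)
        # scan only windows around seeds; any qualifying pair contains a
        # seed, so nothing valid escapes the windows
        seeds = sorted(set(seeds))
        windows: list[tuple[int, int]] = []
        for s in seeds:
            w = (max(d_lo, s - pad), min(d_hi, s + k + pad))
            if windows and w[0] <= windows[-1][1]:
                windows[-1] = (windows[-1][0], max(windows[-1][1], w[1]))
            else:
                windows.append(w)
        for w_lo, w_hi in windows:
            if w_hi <= w_lo:
                continue
            ps = np.arange(w_lo, w_hi)
            match = np.zeros(n, dtype=bool)
            match[ps] = comp[arr[ps]] == arr[D - ps]
            for a, L, mm in _maximal_on_diagonal(
                match, w_lo, w_hi, D, min_len, max_len, max_mismatch, max_span
            ):
                b0, b1 = D - a - L + 1, D - a + 1
                pairs.append(
                    IrPair(
                        left=(a, a + L),
                        right=(b0, b1),
                        ir_len=L,
                        mismatches=mm,
                        left_seq=seq[a : a + L],
                        right_seq=seq[b0:b1],
                    )
                )
    uniq = sorted(
        {(p.left, p.right): p for p in pairs}.values(),
        key=lambda p: (p.left, p.right),
    )
    return _merge_ir_pairs(uniq) if merge else uniq


# ---------------------------------------------------------------- TSD


def find_tsd(
    seq: str, ir: IrPair, tsd_len_range: tuple[int, int] = (4, 6)
) -> str | None:
    """Target-site duplication flanking an IR pair, if any.

    Tests lengths from the longest down: the bases immediately left of
    the left IR must equal, exactly, the bases immediately right of the
    right IR. A duplication is created by a single insertion event, so
    no mismatches are allowed.
    """
    seq = seq.upper()
    lo, hi = tsd_len_range
    for t in range(hi, lo - 1, -1):
        a = ir.left[0] - t
        b = ir.right[1]
        if a < 0 or b + t > len(seq):
            continue
        if seq[a : a + t] == seq[b : b + t]:
            return seq[a : a + t]
    return None


# ---------------------------------------------------------------- elements


def _ir_matches(seq: str, ir: str, max_mismatch: int) -> list[tuple[int, int, str]]:
    """``(start, mismatches, orientation)`` for Hamming matches of the
    IR probe in forward ('F') and reverse-complement ('R') orientation."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = []
    for orient, probe in (("F", ir.upper()), ("R", revcomp(ir.upper()))):
        q = np.frombuffer(probe.encode(), dtype=np.uint8)
        L = len(q)
        if len(arr) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, L)
        mm = (win != q).sum(axis=1)
        for i in np.nonzero(mm <= max_mismatch)[0]:
            out.append((int(i), int(mm[i]), orient))
    return out


# gap allowed between a right-truncated element's anchor CDS and the
# interrupting child element (a TSD plus a little slack)
_CHILD_GAP = 200


def delineate_elements(
    record: PlasmidRecord,
    descriptors: list[ElementDescriptor],
    params: AlignmentParams | None = None,
    ir_max_mismatch: int = 2,
    window: int = 100_000,
) -> list[ElementCall]:
    """Call transposable elements on a record from family descriptors.

    For each descriptor, its transposase proteins are anchored on the
    record's CDS by best-hit alignment; element boundaries are the
    descriptor-IR matches nearest each anchor within ``window`` bases.
    If only one IR side is found the call is flagged truncated on the
    other side; a right-truncated span is extended over an immediately
    following nested element to that element's right TSD copy,
    reflecting insertional truncation, and otherwise ends at the anchor
    CDS. A span contained in another becomes that call's child
    (``parent`` set). Cargo lists CDS strictly inside the span,
    excluding the element's own machinery and any nested element's
    genes. When two IR candidates are equidistant from an anchor the
    one with fewer mismatches wins.
    """
    params = params or AlignmentParams()
    seq = record.sequence
    by_locus = {f.locus_tag: f for f in record.cds}
    calls: list[ElementCall] = []
    machinery: list[set[str]] = []
    for desc in descriptors:
        qfeats = [
            CdsFeature(name, 0, 3 * len(prot) + 3, "+", protein=prot)
            for name, prot in desc.proteins.items()
        ]
        hits = best_hits(qfeats, record, params)
        if not hits:
            continue
        anchor_tags = {h.target_locus for h in hits}
        matches = _ir_matches(seq, desc.ir_seq, ir_max_mismatch)
        lefts = [(i, mm) for i, mm, o in matches if o == "F"]
        rights = [(i, mm) for i, mm, o in matches if o == "R"]
        L = len(desc.ir_seq)
        seen_spans: set[tuple[int, int]] = set()
        for tag in sorted(anchor_tags, key=lambda t: by_locus[t].start):
            anchor = by_locus[tag]
            lc = sorted(
                (
                    (i, mm)
                    for i, mm in lefts
                    if i + L <= anchor.start and anchor.start - i <= window
                ),
                key=lambda t: (anchor.start - t[0], t[1]),
            )
            rc = sorted(
                (
                    (i, mm)
                    for i, mm in rights
                    if i >= anchor.end and i + L - anchor.end <= window
                ),
                key=lambda t: (t[0] - anchor.end, t[1]),
            )
            left = lc[0] if lc else None
            right = rc[0] if rc else None
            if left is None and right is None:
                continue
            if left is not None and right is not None:
                span = (left[0], right[0] + L)
                ir = IrPair(
                    left=(left[0], left[0] + L),
                    right=(right[0], right[0] + L),
                    ir_len=L,
                    mismatches=max(left[1], right[1]),
                    left_seq=seq[left[0] : left[0] + L],
                    right_seq=seq[right[0] : right[0] + L],
                )
                tsd = find_tsd(seq, ir, (desc.tsd_len, desc.tsd_len))
                call = ElementCall(
                    desc.family_label, span, ir, tsd, "none", anchor_locus=tag
                )
            elif left is not None:
                span = (left[0], anchor.end)
                ir = IrPair(
                    (left[0], left[0] + L), (-1, -1), L, left[1],
                    seq[left[0] : left[0] + L], "",
                )
                call = ElementCall(
                    desc.family_label, span, ir, None, "right", anchor_locus=tag
                )
            else:
                span = (anchor.start, right[0] + L)
                ir = IrPair(
                    (-1, -1), (right[0], right[0] + L), L, right[1],
                    "", seq[right[0] : right[0] + L],
                )
                call = ElementCall(
                    desc.family_label, span, ir, None, "left", anchor_locus=tag
                )
            if span in seen_spans:  # second anchor (tnpR) of the same element
                continue
            seen_spans.add(span)
            calls.append(call)
            machinery.append(set(anchor_tags))

    # extend right-truncated spans over an immediately following child
    for c in calls:
        if c.truncated_side == "right":
            children = [
                o
                for o in calls
                if o is not c
                and c.span[1] <= o.span[0] <= c.span[1] + _CHILD_GAP
                and o.span[1] > c.span[1]
            ]
            if children:
                child = min(children, key=lambda o: o.span[0])
                c.span = (c.span[0], child.span[1] + len(child.tsd or ""))

    # parent = smallest strictly containing span
    for c in calls:
        containing = [
            o
            for o in calls
            if o is not c
            and o.span[0] <= c.span[0]
            and c.span[1] <= o.span[1]
            and o.span != c.span
        ]
        if containing:
            c.parent = min(containing, key=lambda o: o.span[1] - o.span[0])  # ref

    for c, own in zip(calls, machinery):
        child_spans = [o.span for o in calls if o.parent is c]
        c.cargo = [
            f.locus_tag
            for f in record.cds
            if c.span[0] < f.start
            and f.end < c.span[1]
            and f.locus_tag not in own
            and not any(s0 <= f.start and f.end <= s1 for s0, s1 in child_spans)
        ]

    order = sorted(range(len(calls)), key=lambda i: calls[i].span)
    calls = [calls[i] for i in order]
    index_of = {id(c): i for i, c in enumerate(calls)}
    for c in calls:
        if c.parent is not None:
            c.parent = index_of[id(c.parent)]
    return calls


def load_descriptors(path) -> list[ElementDescriptor]:
    """Read element descriptors from a TOML bundle.

    Schema: one table per family with keys ``ir``, ``tsd_len`` and a
    ``proteins`` sub-table mapping name -> amino-acid sequence.
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    out = []
    for label, entry in doc.items():
        out.append(
            ElementDescriptor(
                family_label=label,
                ir_seq=entry["ir"],
                proteins=dict(entry.get("proteins", {})),
                tsd_len=int(entry.get("tsd_len", 5)),
            )
        )
    return out


def write_elements_gff3(
    calls: list[ElementCall], record: PlasmidRecord, path
) -> None:
    """Element calls as GFF3 ``mobile_genetic_element`` features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {record.length_bp}\n")
        for i, c in enumerate(calls):
            attrs = [f"ID=element{i}", f"Name={c.family_label}"]
            if c.parent is not None:
                attrs.append(f"Parent=element{c.parent}")
            if c.tsd:
                attrs.append(f"tsd={c.tsd}")
            if c.truncated_side != "none":
                attrs.append(f"truncated={c.truncated_side}")
            fh.write(
                f"{record.id}\tplascomp\tmobile_genetic_element\t"
                f"{c.span[0] + 1}\t{c.span[1]}\t.\t+\t.\t{';'.join(attrs)}\n"
            )
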