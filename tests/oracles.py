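"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming / seeded
search paths: local alignment is scored by exhaustive enumeration of
monotone matchings, inverted repeats by an exhaustive per-diagonal
scan, and synteny chains by enumeration of all subsequences.
"""

from __future__ import annotations

from itertools import combinations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sub_score(x: str, y: str) -> float:
    if x == "X" or y == "X":
        return 0.0
    return float(_B62[x, y])


def enumerate_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score by exhaustive enumeration.

    A local alignment is determined by its set of matched columns
    (i1 < i2 < ... ; j1 < j2 < ...). Unmatched residues between
    consecutive matched columns are placed in one gap run per sequence
    (any other arrangement costs more gap openings); leading and
    trailing residues are free. The best over all monotone matchings,
    floored at 0, is the Smith-Waterman score.
    """
    m, n = len(a), len(b)
    best = 0.0
    gap = lambda d: gap_open + gap_extend * d if d > 0 else 0.0
    for k in range(1, min(m, n) + 1):
        for qs in combinations(range(m), k):
            for ts in combinations(range(n), k):
                s = sub_score(a[qs[0]], b[ts[0]])
                for t in range(1, k):
                    s += sub_score(a[qs[t]], b[ts[t]])
                    s -= gap(qs[t] - qs[t - 1] - 1)
                    s -= gap(ts[t] - ts[t - 1] - 1)
                best = max(best, s)
    return int(best)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def exhaustive_ir_pairs(
    seq: str,
    min_len: int = 20,
    max_len: int = 48,
    max_mismatch: int = 2,
    max_span: int | None = None,
) -> list[tuple[tuple[int, int], tuple[int, int], int]]:
    """All maximal IR pairs by exhaustive per-diagonal prefix-sum scan.

    Returns ``(left, right, mismatches)`` tuples. Maximality: a valid
    pair not contained (on its anti-diagonal) in a longer valid pair.
    """
    seq = seq.upper()
    n = len(seq)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": None}
    results = []
    for D in range(2 * min_len - 1, 2 * n - 1):
        p_lo = max(0, D - n + 1)
        p_hi = min(n, D // 2 + 1)
        if p_hi <= p_lo:
            continue
        ps = list(range(p_lo, p_hi))
        match = [comp.get(seq[p]) == seq[D - p] for p in ps]
        pref = [0]
        for v in match:
            pref.append(pref[-1] + (1 if v else 0))

        def mism(a: int, L: int) -> int:
            i0 = a - p_lo
            return L - (pref[i0 + L] - pref[i0])

        def valid(a: int, L: int) -> bool:
            if not (min_len <= L <= max_len):
                return False
            if a < p_lo or a + L > p_hi:
                return False
            if D - a - L + 1 < a + L:
                return False
            if max_span is not None and (D - a + 1) - a > max_span:
                return False
            return mism(a, L) <= max_mismatch

        cands = []
        for a in ps:
            best_L = 0
            L = min_len
            while valid(a, L):
                best_L = L
                L += 1
            if best_L:
                cands.append((a, best_L))
        for a, L in cands:
            if any(
                a2 <= a and a + L <= a2 + L2 and (a2, L2) != (a, L)
                for a2, L2 in cands
            ):
                continue
            results.append(((a, a + L), (D - a - L + 1, D - a + 1), mism(a, L)))
    return sorted(results)


def brute_force_longest_monotone(values: list[int]) -> int:
    """Length of the longest strictly monotone (either direction)
    subsequence, by enumeration over all subsequences."""
    n = len(values)
    best = 0
    for r in range(1, n + 1):
        for idx in combinations(range(n), r):
            sub = [values[i] for i in idx]
            if all(x < y for x, y in zip(sub, sub[1:])) or all(
                x > y for x, y in zip(sub, sub[1:])
            ):
                best = max(best, r)
    return best
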