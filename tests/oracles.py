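"""Independent brute-force oracles used to validate the package.

Everything here is written from the operation contracts alone, in the most
direct way possible, and deliberately shares no code with the package
internals it checks.
"""

from __future__ import annotations

import numpy as np

BLOSUM62_ROWS = None  # populated lazily from biopython (reference data only)

STOPS = {"TAA", "TAG", "TGA"}

CODON_TABLE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_aas):
    CODON_TABLE[_bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]] = _a

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def translate_simple(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


def brute_force_orfs(seq: str, min_aa: int = 50):
    """Enumerate ORFs in all six frames by direct scanning.

    Returns tuples (start, end, strand, frame, aa, partial5, partial3) in
    forward-strand 0-based half-open coordinates, end including the stop.
    """
    n = len(seq)
    found = []

    def scan(s: str, strand: str):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            # segment boundaries between stops
            stops = [ci for ci, c in enumerate(codons) if c in STOPS]
            segments = []  # (first codon idx, last codon idx exclusive, has_stop, at5, at3)
            prev = 0
            for si in stops:
                segments.append((prev, si, True, prev == 0, False))
                prev = si + 1
            if prev < len(codons):
                segments.append((prev, len(codons), False, prev == 0, True))
            for c0, c1, has_stop, at5, at3 in segments:
                if c1 <= c0:
                    continue
                coding = codons[c0:c1]
                atg = next((k for k, c in enumerate(coding) if c == "ATG"), None)
                emitted = False
                if atg is not None:
                    aa = "".join(CODON_TABLE.get(c, "X") for c in coding[atg:])
                    if len(aa) >= min_aa:
                        start = frame + 3 * (c0 + atg)
                        end = frame + 3 * c1 + (3 if has_stop else 0)
                        yield_tuple(found, s, strand, start, end, frame, aa,
                                    False, at3, n)
                        emitted = True
                if not emitted and at5:
                    aa = "".join(CODON_TABLE.get(c, "X") for c in coding)
                    if len(aa) >= min_aa:
                        start = frame + 3 * c0
                        end = frame + 3 * c1 + (3 if has_stop else 0)
                        yield_tuple(found, s, strand, start, end, frame, aa,
                                    True, at3, n)

    scan(seq, "+")
    scan(rc(seq), "-")
    return sorted(found)


def yield_tuple(found, s, strand, start, end, frame, aa, p5, p3, n):
    if strand == "+":
        found.append((start, end, "+", frame, aa, p5, p3))
    else:
        found.append((n - end, n - start, "-", frame, aa, p5, p3))


def gotoh_local(a: str, b: str, matrix_lookup, gap_open: float, gap_extend: float
                ) -> float:
    """Plain quadratic affine-gap Smith-Waterman score (Gotoh recurrences).

    ``matrix_lookup(x, y)`` returns the substitution score. A gap of length
    g costs gap_open + g * gap_extend.
    """
    m, n = len(a), len(b)
    NEG = -1e18
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in a (left moves)
    F = np.full((m + 1, n + 1), NEG)  # gap in b (up moves)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + matrix_lookup(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def nw_global_score(a: str, b: str, matrix_lookup, gap: float) -> float:
    """Plain global alignment score with a linear gap penalty."""
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1))
    H[0, :] = gap * np.arange(n + 1)
    H[:, 0] = gap * np.arange(m + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            H[i][j] = max(
                H[i - 1][j - 1] + matrix_lookup(a[i - 1], b[j - 1]),
                H[i - 1][j] + gap,
                H[i][j - 1] + gap,
            )
    return float(H[m][n])


def brute_trim(seq: str, qual: list[int], qmin: int):
    """Longest run after removing the maximal low-quality prefix/suffix."""
    lo = 0
    while lo < len(qual) and qual[lo] < qmin:
        lo += 1
    hi = len(qual)
    while hi > lo and qual[hi - 1] < qmin:
        hi -= 1
    return seq[lo:hi], qual[lo:hi]


def brute_n50(lengths) -> int:
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    for candidate in lengths:
        if sum(x for x in lengths if x >= candidate) * 2 >= total:
            return candidate
    raise AssertionError("unreachable")


def exhaustive_best_selection(intervals, max_overlap):
    """Maximum-total-length subset of intervals with bounded pairwise
    overlap, by exhaustive search (instances <= ~12)."""
    from itertools import combinations

    best_len, best = -1, ()
    idx = range(len(intervals))
    for r in range(len(intervals), 0, -1):
        for combo in combinations(idx, r):
            ok = True
            for x, y in combinations(combo, 2):
                a, b = intervals[x], intervals[y]
                if min(a[1], b[1]) - max(a[0], b[0]) > max_overlap:
                    ok = False
                    break
            if ok:
                total = sum(iv[1] - iv[0] for iv in (intervals[i] for i in combo))
                if total > best_len:
                    best_len, best = total, combo
    return best_len, best
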