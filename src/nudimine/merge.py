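"""Redundancy depletion and joining of candidate viral contigs.

A greedy overlap-layout merger stands in for a full assembler: exact k-mer
anchors (k = 16) propose a relative offset between two contigs (either
orientation), the implied overlap is verified base-by-base, and qualifying
overlaps (length >= min_len, identity >= min_identity) are merged longest
first. At disagreeing overlap positions the base of the longer contig wins.
Contained contigs are absorbed. The procedure is deterministic and
idempotent: its output has no remaining qualifying overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .records import SequenceRecord, revcomp

ANCHOR_K = 16


@dataclass
class OverlapEdge:
    id_a: str
    id_b: str
    orientation: str  # "+" if B joins forward, "-" if reverse-complemented
    offset: int  # position of B's first base in A coordinates
    overlap_len: int
    identity: float


@dataclass
class MergeReport:
    merges: list[OverlapEdge] = field(default_factory=list)
    conflicts: list[OverlapEdge] = field(default_factory=list)


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def _overlap_identity(a: str, b: str, offset: int) -> tuple[int, int, float]:
    """(start_in_A, overlap_len, identity) of B placed at ``offset`` in A."""
    start = max(0, offset)
    end = min(len(a), offset + len(b))
    if end <= start:
        return start, 0, 0.0
    xa = np.frombuffer(a[start:end].encode(), dtype=np.uint8)
    xb = np.frombuffer(b[start - offset : end - offset].encode(), dtype=np.uint8)
    ident = float((xa == xb).mean())
    return start, end - start, ident


def _best_overlap(a: SequenceRecord, b: SequenceRecord, min_len: int,
                  min_identity: float) -> tuple[OverlapEdge | None, list[OverlapEdge]]:
    """Best qualifying overlap between two contigs, trying both orientations
    of B. Also returns anchored-but-failing overlaps (potential conflicts)."""
    index_a = _kmer_positions(a.seq, ANCHOR_K)
    best: OverlapEdge | None = None
    failed: list[OverlapEdge] = []
    for orient, bseq in (("+", b.seq), ("-", revcomp(b.seq))):
        votes: dict[int, int] = {}
        for j in range(len(bseq) - ANCHOR_K + 1):
            for i in index_a.get(bseq[j : j + ANCHOR_K], ()):
                d = i - j
                votes[d] = votes.get(d, 0) + 1
        # examine the best-supported offsets only
        for d, _ in sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:5]:
            start, olen, ident = _overlap_identity(a.seq, bseq, d)
            edge = OverlapEdge(a.id, b.id, orient, d, olen, ident)
            if olen < min_len:
                continue
            if ident < min_identity:
                failed.append(edge)
                continue
            if best is None or (olen, ident) > (best.overlap_len, best.identity):
                best = edge
    return best, failed


def _merge_pair(a: SequenceRecord, b: SequenceRecord, edge: OverlapEdge
                ) -> SequenceRecord:
    """Merge B into A at the verified offset; longer contig wins disagreements."""
    bseq = b.seq if edge.orientation == "+" else revcomp(b.seq)
    shift = -min(0, edge.offset)
    total = max(len(a.seq), edge.offset + len(bseq)) + shift
    arr = np.zeros(total, dtype=np.uint8)
    first, fpos, second, spos = (
        (bseq, edge.offset + shift, a.seq, shift)
        if len(a.seq) >= len(bseq)
        else (a.seq, shift, bseq, edge.offset + shift)
    )
    arr[fpos : fpos + len(first)] = np.frombuffer(first.encode(), dtype=np.uint8)
    arr[spos : spos + len(second)] = np.frombuffer(second.encode(), dtype=np.uint8)
    keep = a if len(a.seq) >= len(bseq) else b
    return SequenceRecord(keep.id, arr.tobytes().decode(),
                          description="merged", alphabet="dna")


def merge_contigs(contigs: list[SequenceRecord], min_len: int = 40,
                  min_identity: float = 0.95
                  ) -> tuple[list[SequenceRecord], MergeReport]:
    """Greedily merge overlapping/contained contigs into unique fragments.

    Returns the depleted fragment set (sorted longest first, ties by id) and
    a report of merges performed and anchored overlaps that failed identity
    verification (left unmerged).
    """
    pool = sorted(contigs, key=lambda r: (-len(r.seq), r.id))
    report = MergeReport()
    while True:
        best_edge = None
        best_pair = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                edge, failed = _best_overlap(pool[i], pool[j], min_len, min_identity)
                for f in failed:
                    if all(
                        (c.id_a, c.id_b, c.orientation, c.offset)
                        != (f.id_a, f.id_b, f.orientation, f.offset)
                        for c in report.conflicts
                    ):
                        report.conflicts.append(f)
                if edge is None:
                    continue
                key = (edge.overlap_len, edge.identity, edge.id_a, edge.id_b)
                if best_edge is None or key > (
                    best_edge.overlap_len, best_edge.identity,
                    best_edge.id_a, best_edge.id_b,
                ):
                    best_edge, best_pair = edge, (i, j)
        if best_edge is None:
            break
        i, j = best_pair
        merged = _merge_pair(pool[i], pool[j], best_edge)
        report.merges.append(best_edge)
        pool = [rec for k, rec in enumerate(pool) if k not in (i, j)]
        pool.append(merged)
        pool.sort(key=lambda r: (-len(r.seq), r.id))
    return pool, report


def fold_reduction(n_before: int, n_after: int) -> float:
    """Contig-count reduction ratio, rounded half-up to one decimal."""
    if n_after < 1:
        raise ValueError("n_after must be >= 1")
    ratio = Decimal(n_before) / Decimal(n_after)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
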