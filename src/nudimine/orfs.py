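"""Six-frame ORF prediction with the discovery protocol's rules.

ORFs of >= 50 aa (translated length, excluding the stop) are retained;
complete ORFs begin at the first in-frame ATG after the previous stop and end
at a stop codon. ORFs truncated by a contig edge may lack the start (5'
partial) or the stop (3' partial). Overlap between retained ORFs is limited
by a greedy longest-first selection. ORFs are named by linear order within
each genome fragment ("<prefix>_F<i>_ORF<j>").
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .records import SequenceRecord, revcomp, translate

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class Orf:
    """A predicted coding region, in forward-strand 0-based half-open
    coordinates. ``end - start`` includes the stop codon when present;
    ``aa_seq`` excludes the stop. ``frame`` is the offset (0-2) on the ORF's
    own strand."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_seq: str
    partial5: bool = False
    partial3: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid ORF span [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


def _scan_strand(seq: str, min_aa: int, require_start: bool,
                 allow_edge_partials: bool) -> list[tuple[int, int, int, str, bool, bool]]:
    """ORFs on one strand of ``seq`` as (start, end, frame, aa, p5, p3),
    coordinates relative to that strand."""
    n = len(seq)
    found = []
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        seg_start = frame  # start of current inter-stop segment
        at_edge = True  # the first segment of each frame touches the 5' edge
        for i in codon_starts:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                found.extend(
                    _emit(seq, seg_start, i + 3, frame, at_edge, False,
                          min_aa, require_start, allow_edge_partials)
                )
                seg_start = i + 3
                at_edge = False
        # trailing segment runs off the 3' edge (no stop codon)
        last = n - (n - frame) % 3
        if seg_start < last:
            found.extend(
                _emit(seq, seg_start, last, frame, at_edge, True,
                      min_aa, require_start, allow_edge_partials)
            )
    return found


def _emit(seq, seg_start, seg_end, frame, edge5, edge3,
          min_aa, require_start, allow_edge_partials):
    """Yield the ORF (if any) for one stop-free segment.

    ``seg_end`` includes the terminal stop codon unless ``edge3``.
    """
    out = []
    if edge3 and not allow_edge_partials:
        return out  # no stop codon -> only ever a 3' partial
    coding_end = seg_end - (0 if edge3 else 3)

    def aa_of(start):
        return translate(seq[start:coding_end])

    if require_start:
        start = None
        for i in range(seg_start, coding_end, 3):
            if seq[i : i + 3] == "ATG":
                start = i
                break
        if start is not None:
            aa = aa_of(start)
            if len(aa) >= min_aa:
                out.append((start, seg_end, frame, aa, False, edge3))
                return out
        # no qualifying complete ORF; a 5'-edge segment may still be partial
        if allow_edge_partials and edge5:
            aa = aa_of(seg_start)
            if len(aa) >= min_aa:
                out.append((seg_start, seg_end, frame, aa, True, edge3))
        return out
    aa = aa_of(seg_start)
    if len(aa) >= min_aa:
        out.append((seg_start, seg_end, frame, aa, edge5, edge3))
    return out


def six_frame_orfs(contig: SequenceRecord | str, min_aa: int = 50,
                   require_start: bool = True,
                   allow_edge_partials: bool = True) -> list[Orf]:
    """Predict ORFs in all six reading frames of a contig.

    Returns ORFs sorted by (start, end, strand). Ambiguous bases translate to
    X and never count as stops. Contigs shorter than ``3 * min_aa`` return
    an empty list.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if isinstance(contig, str):
        contig = SequenceRecord("contig", contig)
    seq = contig.seq
    n = len(seq)
    if n < 3 * min_aa:
        return []
    orfs: list[Orf] = []
    for start, end, frame, aa, p5, p3 in _scan_strand(
        seq, min_aa, require_start, allow_edge_partials
    ):
        orfs.append(Orf(contig.id, start, end, "+", frame, aa, p5, p3))
    rc = revcomp(seq)
    for start, end, frame, aa, p5, p3 in _scan_strand(
        rc, min_aa, require_start, allow_edge_partials
    ):
        orfs.append(Orf(contig.id, n - end, n - start, "-", frame, aa, p5, p3))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def resolve_overlaps(orfs: list[Orf], max_overlap_nt: int = 60) -> list[Orf]:
    """Greedy longest-first ORF selection with bounded pairwise overlap.

    No retained pair overlaps by more than ``max_overlap_nt`` genomic bases.
    Ties in length break by leftmost start, then '+' strand — deterministic.
    """
    contigs = {o.contig_id for o in orfs}
    if len(contigs) > 1:
        raise ValueError("resolve_overlaps expects ORFs from a single contig")
    ranked = sorted(orfs, key=lambda o: (-o.span, o.start, 0 if o.strand == "+" else 1))
    kept: list[Orf] = []
    for orf in ranked:
        ok = True
        for other in kept:
            overlap = min(orf.end, other.end) - max(orf.start, other.start)
            if overlap > max_overlap_nt:
                ok = False
                break
        if ok:
            kept.append(orf)
    kept.sort(key=lambda o: (o.start, o.end, o.strand))
    return kept


def name_orfs(fragments: list[SequenceRecord], orfs: list[Orf],
              prefix: str) -> list[Orf]:
    """Name ORFs "<prefix>_<fragment>_ORF<j>" by start coordinate within each
    fragment, in fragment order. Renaming is idempotent."""
    by_contig: dict[str, list[Orf]] = {}
    for orf in orfs:
        by_contig.setdefault(orf.contig_id, []).append(orf)
    named: list[Orf] = []
    for frag in fragments:
        group = sorted(by_contig.get(frag.id, []),
                       key=lambda o: (o.start, o.end, o.strand))
        for j, orf in enumerate(group, 1):
            named.append(replace(orf, name=f"{prefix}_{frag.id}_ORF{j}"))
    return named
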