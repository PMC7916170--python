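"""Progressive multiple protein alignment and core-gene supermatrix assembly.

The aligner is deliberately classical: pairwise global alignments under
BLOSUM62 with a linear gap penalty, a single-linkage guide tree on k-mer
distances, and profile-profile merging. Per-gene alignments are concatenated
into a supermatrix with all-gap fill for taxa missing a gene, the standard
treatment for patchy gene sampling (endogenous viral elements retain only a
subset of the core genes yet must be placed on the same tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ALPHABET, scoring_matrix
from .records import SequenceRecord

GAP = "-"
DEFAULT_GAP_PENALTY = -8.0

_SYM_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}


@dataclass
class MultipleAlignment:
    """Aligned rows of equal length over amino acids + gap."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)].replace(GAP, "")


def _profile(rows: list[str]) -> np.ndarray:
    """(n_columns, 21) symbol frequencies; gaps contribute nothing."""
    n = len(rows)
    ncol = len(rows[0]) if rows else 0
    prof = np.zeros((ncol, 21))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                prof[j, _SYM_INDEX.get(ch, 20)] += 1.0
    return prof / max(n, 1)


def _nw_profile(pa: np.ndarray, pb: np.ndarray, gap: float
                ) -> tuple[list[int], list[int]]:
    """Global DP between two profiles; returns per-side gap masks as column
    index lists (-1 marks an inserted gap column)."""
    matrix = scoring_matrix("BLOSUM62").astype(float)
    S = pa @ matrix @ pb.T  # (m, n) column-vs-column scores
    m, n = S.shape
    H = np.empty((m + 1, n + 1))
    H[0, :] = gap * np.arange(n + 1)
    H[:, 0] = gap * np.arange(m + 1)
    jj = np.arange(n + 1)
    for i in range(1, m + 1):
        cand = np.empty(n + 1)
        cand[0] = H[i, 0]
        cand[1:] = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] + gap)
        H[i, :] = np.maximum.accumulate(cand - gap * jj) + gap * jj
    # traceback (diag preferred, then up, then left)
    out_a: list[int] = []
    out_b: list[int] = []
    i, j = m, n
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) < eps:
            out_a.append(i - 1)
            out_b.append(j - 1)
            i -= 1
            j -= 1
        elif i > 0 and abs(H[i, j] - (H[i - 1, j] + gap)) < eps:
            out_a.append(i - 1)
            out_b.append(-1)
            i -= 1
        else:
            out_a.append(-1)
            out_b.append(j - 1)
            j -= 1
    return out_a[::-1], out_b[::-1]


def _merge(a: MultipleAlignment, b: MultipleAlignment, gap: float
           ) -> MultipleAlignment:
    path_a, path_b = _nw_profile(_profile(a.rows), _profile(b.rows), gap)

    def expand(rows, path):
        return [
            "".join(GAP if k < 0 else row[k] for k in path) for row in rows
        ]

    return MultipleAlignment(
        a.ids + b.ids, expand(a.rows, path_a) + expand(b.rows, path_b)
    )


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(max(len(a) - k + 1, 0))}
    kb = {b[i : i + k] for i in range(max(len(b) - k + 1, 0))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / len(ka | kb)


def align_gene(proteins: list[SequenceRecord],
               gap_penalty: float = DEFAULT_GAP_PENALTY) -> MultipleAlignment:
    """Progressively align one gene's proteins across taxa.

    Guide order is single-linkage agglomeration on pairwise k-mer Jaccard
    distances with lexicographic tie-breaking; alignments merge by
    profile-profile global DP. Deterministic. A single sequence aligns
    trivially to itself.
    """
    if not proteins:
        raise ValueError("align_gene requires >= 1 sequence")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon in gene alignment input")
    if len(proteins) == 1:
        return MultipleAlignment([proteins[0].id], [proteins[0].seq])

    dist: dict[frozenset, float] = {}
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            dist[frozenset((ids[i], ids[j]))] = _kmer_distance(
                proteins[i].seq, proteins[j].seq
            )
    clusters: dict[str, MultipleAlignment] = {
        p.id: MultipleAlignment([p.id], [p.seq]) for p in proteins
    }
    link = dict(dist)  # single-linkage cluster distances, keyed by label pair
    labels = sorted(clusters)
    while len(labels) > 1:
        best = min(
            (
                (link[frozenset((la, lb))], la, lb)
                for ai, la in enumerate(labels)
                for lb in labels[ai + 1 :]
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, la, lb = best
        merged = _merge(clusters[la], clusters[lb], gap_penalty)
        for other in labels:
            if other in (la, lb):
                continue
            link[frozenset((la, other))] = min(
                link[frozenset((la, other))], link[frozenset((lb, other))]
            )
        del clusters[lb]
        clusters[la] = merged
        labels.remove(lb)
    return clusters[labels[0]]


@dataclass
class Supermatrix:
    """Concatenated per-gene alignments over a shared taxon set."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, tuple[int, int]]]  # (gene, [start, end))
    missing: dict[str, set] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.partitions[-1][1][1] if self.partitions else 0

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(
            [SequenceRecord(t, self.rows[t], alphabet="protein") for t in self.taxa],
            path,
        )

    def partition_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gene": g, "start": s, "end": e}
                for g, (s, e) in self.partitions
            ]
        )


def build_supermatrix(per_gene_alignments: dict[str, MultipleAlignment],
                      taxa: list[str]) -> Supermatrix:
    """Concatenate per-gene alignments; taxa missing a gene get all-gap fill.

    Raises ``ValueError`` for a duplicate taxon inside one gene or a gene
    taxon not in ``taxa``.
    """
    rows = {t: [] for t in taxa}
    partitions = []
    missing: dict[str, set] = {t: set() for t in taxa}
    pos = 0
    for gene in sorted(per_gene_alignments):
        aln = per_gene_alignments[gene]
        if len(set(aln.ids)) != len(aln.ids):
            raise ValueError(f"duplicate taxon in gene {gene!r}")
        unknown = set(aln.ids) - set(taxa)
        if unknown:
            raise ValueError(f"gene {gene!r} has unknown taxa {sorted(unknown)}")
        ncol = aln.n_columns
        present = dict(zip(aln.ids, aln.rows))
        for t in taxa:
            if t in present:
                rows[t].append(present[t])
            else:
                rows[t].append(GAP * ncol)
                missing[t].add(gene)
        partitions.append((gene, (pos, pos + ncol)))
        pos += ncol
    return Supermatrix(
        list(taxa), {t: "".join(parts) for t, parts in rows.items()},
        partitions, missing,
    )


def distance_matrix(sm: Supermatrix, max_distance: float = 10.0) -> pd.DataFrame:
    """Corrected pairwise distances from the supermatrix.

    p is the mismatch fraction over columns where both taxa are non-gap;
    the correction d = -ln(1 - p - 0.2 p^2) compensates multiple hits
    (scoredist-style) and is capped at ``max_distance``. A pair with zero
    comparable columns raises ``ValueError`` naming the pair.
    """
    if len(sm.taxa) < 3:
        raise ValueError("distance matrix needs >= 3 taxa")
    enc = {
        t: np.frombuffer(sm.rows[t].encode(), dtype=np.uint8) for t in sm.taxa
    }
    gap_byte = ord(GAP)
    n = len(sm.taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[sm.taxa[i]], enc[sm.taxa[j]]
            both = (a != gap_byte) & (b != gap_byte)
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {sm.taxa[i]!r} and {sm.taxa[j]!r}"
                )
            p = float((a[both] != b[both]).mean())
            arg = 1.0 - p - 0.2 * p * p
            d = max_distance if arg <= 0 else min(-np.log(arg), max_distance)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=sm.taxa, columns=sm.taxa)
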