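"""Seeded protein homology search, the viral-contig screen, ORF annotation,
and homolog-sharing statistics between viral proteomes.

The engine mirrors a word-seeded BLASTp: subjects sharing at least one exact
k-mer with the query are screened with an exact best-ungapped-diagonal filter
and the survivors get a full affine Smith-Waterman alignment; hits are kept
at E <= evalue_max. A translated (six-frame) variant screens nucleotide
contigs against the viral protein database, the step that pulls candidate
virus contigs out of a host shotgun assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import (
    SearchParams,
    best_ungapped_segment,
    encode,
    evalue,
    scoring_matrix,
    sw_align,
)
from .io import ProteinDatabase
from .orfs import Orf
from .records import SequenceRecord, revcomp, translate

_SENTINEL = 21  # inter-subject boundary index in the padded matrix


@dataclass
class Hit:
    """A scored local alignment between a query and a database protein."""

    query_id: str
    subject_id: str
    score: float
    evalue: float
    pct_identity: float
    query_cov: float
    subject_cov: float
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    frame: int = 0  # signed reading frame for translated searches; 0 = protein query


@dataclass
class Annotation:
    """Best-hit annotation of a called ORF (or an explicit no-hit)."""

    orf: Orf
    hit: Hit | None
    partial_by_coverage: bool = False
    gene_name: str = ""
    genome_id: str = ""
    gene_order_index: int | None = None
    ref_strand: str = "+"

    @property
    def orf_name(self) -> str:
        return self.orf.name


@dataclass
class CandidateContig:
    """A contig flagged by the viral screen, with its supporting hits."""

    contig: SequenceRecord
    hits: list[Hit]


class DatabaseIndex:
    """k-mer index plus concatenated encoding of a protein database."""

    def __init__(self, records: list[SequenceRecord], k: int, matrix_name: str):
        self.records = records
        self.k = k
        self.ids = [r.id for r in records]
        self.seqs = [r.seq for r in records]
        self.encoded = [encode(s) for s in self.seqs]
        self.total_residues = sum(len(s) for s in self.seqs)
        self.kmer_to_subjects: dict[str, set[int]] = {}
        for si, seq in enumerate(self.seqs):
            for i in range(len(seq) - k + 1):
                self.kmer_to_subjects.setdefault(seq[i : i + k], set()).add(si)
        base = scoring_matrix(matrix_name)
        padded = np.full((22, 22), -1e9)
        padded[:21, :21] = base
        self.padded_matrix = padded

    def candidates(self, query: str) -> list[int]:
        found: set[int] = set()
        for i in range(len(query) - self.k + 1):
            found |= self.kmer_to_subjects.get(query[i : i + self.k], set())
        return sorted(found)


def build_index(db, params: SearchParams) -> DatabaseIndex:
    """Build (or reuse) the k-mer index for a database.

    ``db`` may be a :class:`DatabaseIndex` (used as-is), a
    :class:`ProteinDatabase` (index cached on the object) or a plain list of
    protein :class:`SequenceRecord`.
    """
    if isinstance(db, DatabaseIndex):
        return db
    if isinstance(db, ProteinDatabase):
        cached = db._index
        if cached is not None and cached.k == params.k:
            return cached
        index = DatabaseIndex(db.records, params.k, params.matrix)
        db._index = index
        return index
    return DatabaseIndex(list(db), params.k, params.matrix)


def _extension_trigger(m: int, n: int, params: SearchParams) -> float:
    """Ungapped score whose E-value is ``seed_slack`` looser than the final
    cutoff; subjects below it cannot plausibly reach evalue_max."""
    target = params.evalue_max * params.seed_slack
    return math.log(params.kappa * max(m, 1) * max(n, 1) / target) / params.lam


def seeded_search(query, db, params: SearchParams | None = None,
                  early_stop: bool = False, query_id: str = "query",
                  frame: int = 0) -> list[Hit]:
    """Search one protein query against a database.

    Hits with E > ``params.evalue_max`` are dropped; the rest are sorted by
    ascending E-value, ties broken by subject id. With ``early_stop`` the
    scan returns after the first passing hit (existence queries).
    """
    params = params or SearchParams()
    if isinstance(query, SequenceRecord):
        query_id, query = query.id, query.seq
    index = build_index(db, params)
    if not index.records or len(query) < index.k:
        return []
    cand = index.candidates(query)
    if not cand:
        return []
    m = len(query)
    n_total = index.total_residues
    trigger = _extension_trigger(m, n_total, params)

    # exact ungapped prefilter over all candidate subjects at once
    qidx = encode(query)
    pieces, bounds, pos = [], [], 0
    for si in cand:
        pieces.append(index.encoded[si])
        bounds.append((pos, pos + len(index.encoded[si])))
        pos += len(index.encoded[si]) + 1
        pieces.append(np.array([_SENTINEL], dtype=np.int8))
    concat = np.concatenate(pieces[:-1]) if pieces else np.empty(0, dtype=np.int8)
    colmax = best_ungapped_segment(qidx, concat, index.padded_matrix)
    ungapped = np.array([colmax[lo:hi].max() if hi > lo else 0.0 for lo, hi in bounds])

    order = np.argsort(-ungapped, kind="stable")
    hits: list[Hit] = []
    for rank in order:
        if ungapped[rank] < trigger:
            break
        si = cand[rank]
        aln = sw_align(query, index.seqs[si], params)
        e = evalue(aln.score, m, n_total, params)
        if e <= params.evalue_max:
            hits.append(
                Hit(
                    query_id=query_id,
                    subject_id=index.ids[si],
                    score=aln.score,
                    evalue=e,
                    pct_identity=aln.pct_identity,
                    query_cov=aln.query_cov,
                    subject_cov=aln.subject_cov,
                    query_range=aln.query_range,
                    subject_range=aln.subject_range,
                    frame=frame,
                )
            )
            if early_stop:
                return hits
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


def six_frame_queries(contig: SequenceRecord) -> list[tuple[int, str]]:
    """(signed frame, translated protein) for all six reading frames."""
    out = []
    for offset in range(3):
        out.append((offset + 1, translate(contig.seq[offset:])))
    rc = revcomp(contig.seq)
    for offset in range(3):
        out.append((-(offset + 1), translate(rc[offset:])))
    return out


def screen_viral_contigs(contigs, viral_db, params: SearchParams | None = None
                         ) -> list[CandidateContig]:
    """Flag contigs with >= 1 translated hit to the viral protein database.

    Each contig is searched as six independent protein queries (one per
    reading frame); a contig is a candidate iff any frame produces a hit at
    E <= evalue_max. Supporting hits are attached, best first.
    """
    params = params or SearchParams()
    out: list[CandidateContig] = []
    for contig in contigs:
        hits: list[Hit] = []
        for frame, protein in six_frame_queries(contig):
            if not protein:
                continue
            hits.extend(
                seeded_search(protein, viral_db, params,
                              query_id=contig.id, frame=frame)
            )
        if hits:
            hits.sort(key=lambda h: (h.evalue, h.subject_id, h.frame))
            out.append(CandidateContig(contig, hits))
    return out


def annotate_orfs(orfs: list[Orf], db, params: SearchParams | None = None,
                  partial_cov_threshold: float = 0.8) -> list[Annotation]:
    """Record the best database hit per ORF, or an explicit no-hit.

    An ORF whose alignment covers less than ``partial_cov_threshold`` of its
    matched database protein is flagged ``partial_by_coverage`` — the signal
    that the ORF is a truncated fragment of a full-length gene.
    """
    params = params or SearchParams()
    annotations: list[Annotation] = []
    is_meta_db = isinstance(db, ProteinDatabase)
    for orf in orfs:
        hits = seeded_search(orf.aa_seq, db, params,
                             query_id=orf.name or orf.contig_id)
        if not hits:
            annotations.append(Annotation(orf, None))
            continue
        best = min(hits, key=lambda h: (h.evalue, -h.score, h.subject_id))
        ann = Annotation(
            orf,
            best,
            partial_by_coverage=best.subject_cov < partial_cov_threshold,
        )
        if is_meta_db:
            ann.gene_name = db.gene_name(best.subject_id)
            ann.genome_id = db.genome_of(best.subject_id)
            ann.gene_order_index = db.gene_order_index(best.subject_id)
            ann.ref_strand = db.gene_strand(best.subject_id)
        annotations.append(ann)
    return annotations


@dataclass
class HomologMatrix:
    """counts.loc[i, j] = number of proteins of genome i with >= 1 hit in
    genome j at the homolog E-value threshold (one-directional, ordered)."""

    counts: pd.DataFrame
    group_labels: dict[str, str]

    def group_means(self) -> pd.DataFrame:
        """Mean shared-homolog count over ordered genome pairs, within and
        between groups; the diagonal is excluded. A single-genome group has
        no within-group pairs and reports NaN."""
        labels = sorted(set(self.group_labels.values()))
        out = pd.DataFrame(np.nan, index=labels, columns=labels)
        for la in labels:
            for lb in labels:
                vals = [
                    self.counts.at[gi, gj]
                    for gi in self.counts.index
                    for gj in self.counts.columns
                    if gi != gj
                    and self.group_labels[gi] == la
                    and self.group_labels[gj] == lb
                ]
                if vals:
                    out.at[la, lb] = float(np.mean(vals))
        return out


def homolog_share_counts(proteomes: dict[str, list[SequenceRecord]],
                         group_labels: dict[str, str],
                         homolog_evalue: float = 1e-4,
                         params: SearchParams | None = None) -> HomologMatrix:
    """Count, for every ordered genome pair, how many proteins of the first
    genome have a homolog in the second at E <= ``homolog_evalue``."""
    if len(proteomes) < 2:
        raise ValueError("homolog counting needs >= 2 proteomes")
    params = params or SearchParams()
    params = SearchParams(
        matrix=params.matrix, gap_open=params.gap_open,
        gap_extend=params.gap_extend, k=params.k,
        seed_slack=params.seed_slack, lam=params.lam, kappa=params.kappa,
        evalue_max=homolog_evalue,
    )
    genomes = sorted(proteomes)
    indexes = {g: DatabaseIndex(proteomes[g], params.k, params.matrix) for g in genomes}
    counts = pd.DataFrame(0, index=genomes, columns=genomes, dtype=int)
    for gi in genomes:
        for gj in genomes:
            n = 0
            for rec in proteomes[gi]:
                if seeded_search(rec.seq, indexes[gj], params,
                                 early_stop=True, query_id=rec.id):
                    n += 1
            counts.at[gi, gj] = n
    return HomologMatrix(counts, dict(group_labels))
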