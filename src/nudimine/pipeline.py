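"""End-to-end orchestration of the virus-discovery stages.

Stage order: trim -> length filter -> viral screen -> redundancy merge ->
ORF calling -> annotation -> scaffolding -> summaries -> phylogeny. Every
stage logs its in/out counts, all outputs are written under the configured
output directory, and the run is deterministic for a fixed config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import io as nio
from .align import SearchParams
from .config import PipelineConfig
from .merge import fold_reduction, merge_contigs
from .msa import build_supermatrix, align_gene
from .orfs import name_orfs, resolve_overlaps, six_frame_orfs
from .records import SequenceRecord
from .scaffold import ScaffoldLayout, build_gene_maps, scaffold_fragments
from .search import annotate_orfs, screen_viral_contigs
from .summary import (
    core_gene_checklist,
    coverage_table,
    filter_contigs_by_length,
    gc_summary,
    map_reads,
    n50,
)
from .tree import bootstrap_support

logger = logging.getLogger("nudimine")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class ResultBundle:
    candidates: list = field(default_factory=list)
    fragments: list = field(default_factory=list)
    orfs: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    layout: ScaffoldLayout | None = None
    coverage: object = None
    gc_per_fragment: dict = field(default_factory=dict)
    gc_mean: float | None = None
    n50: int | None = None
    fold_reduction: float | None = None
    checklist: object = None
    tree_newick: str | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def annotations_frame(annotations) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        rows.append(
            {
                "orf": ann.orf.name,
                "contig": ann.orf.contig_id,
                "start": ann.orf.start,
                "end": ann.orf.end,
                "strand": ann.orf.strand,
                "aa_len": len(ann.orf.aa_seq),
                "partial5": int(ann.orf.partial5),
                "partial3": int(ann.orf.partial3),
                "best_hit": ann.hit.subject_id if ann.hit else "no hit",
                "gene": ann.gene_name or "",
                "evalue": ann.hit.evalue if ann.hit else None,
                "pct_identity": ann.hit.pct_identity if ann.hit else None,
                "subject_cov": ann.hit.subject_cov if ann.hit else None,
                "partial_by_coverage": int(ann.partial_by_coverage),
            }
        )
    return pd.DataFrame(rows)


def layout_frame(layout: ScaffoldLayout) -> pd.DataFrame:
    rows = []
    for i, (fid, orient) in enumerate(layout.order):
        j = layout.junctions[i] if i < len(layout.junctions) else None
        rows.append(
            {
                "position": i + 1,
                "fragment": fid,
                "orientation": orient,
                "junction_to": j.dst if j else "",
                "evidence": j.evidence if j else "",
                "score": j.score if j else None,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, contigs=None, reads=None, db=None
                 ) -> ResultBundle:
    """Run the full discovery pipeline.

    Inputs are taken from the config paths unless passed directly. Returns a
    :class:`ResultBundle`; all tables and sequence outputs are also written
    under ``config.outdir``.
    """
    out = ResultBundle()
    params = SearchParams(evalue_max=config.screen_evalue)

    if contigs is None:
        contigs = nio.read_fasta(config.contigs) if config.contigs else []
    if reads is None:
        reads = nio.read_fastq(config.reads) if config.reads else []
    if db is None and config.db_fasta:
        db = nio.ProteinDatabase.load(config.db_fasta, config.db_meta)
    if db is None:
        raise StageError("stage 'setup' failed: no protein database provided")

    logger.info("input: %d contigs, %d reads, %d db proteins",
                len(contigs), len(reads), len(db))

    reads = _stage("trim")(nio.trim_reads)(reads, config.qmin)
    logger.info("trim: %d reads retained", len(reads))

    kept = _stage("filter")(filter_contigs_by_length)(contigs, config.min_contig_len)
    logger.info("filter: %d/%d contigs >= %d bp", len(kept), len(contigs),
                config.min_contig_len)

    candidates = _stage("screen")(screen_viral_contigs)(kept, db, params)
    out.candidates = candidates
    logger.info("screen: %d candidate viral contigs", len(candidates))
    nio.write_fasta([c.contig for c in candidates],
                    config.outpath("candidates.fasta"))

    merged, report = _stage("merge")(merge_contigs)(
        [c.contig for c in candidates], config.merge_min_len,
        config.merge_min_identity,
    )
    if candidates:
        out.fold_reduction = fold_reduction(len(candidates), len(merged))
    # label fragments F1..Fn (longest first) as assembly fragments
    merged = sorted(merged, key=lambda r: (-len(r.seq), r.id))
    fragments = [
        SequenceRecord(f"F{i + 1}", rec.seq, description=f"from {rec.id}")
        for i, rec in enumerate(merged)
    ]
    out.fragments = fragments
    logger.info("merge: %d fragments from %d candidates (%d merges)",
                len(fragments), len(candidates), len(report.merges))
    nio.write_fasta(fragments, config.outpath("fragments.fasta"))

    all_orfs = []
    for frag in fragments:
        orfs = _stage("orfcall")(six_frame_orfs)(frag, config.min_orf_aa)
        orfs = resolve_overlaps(orfs, config.max_overlap_nt)
        all_orfs.extend(orfs)
    all_orfs = name_orfs(fragments, all_orfs, config.orf_prefix)
    out.orfs = all_orfs
    logger.info("orfcall: %d ORFs >= %d aa", len(all_orfs), config.min_orf_aa)

    annotations = _stage("annotate")(annotate_orfs)(
        all_orfs, db, params, config.partial_coverage_threshold
    )
    out.annotations = annotations
    ann_df = annotations_frame(annotations)
    ann_df.to_csv(config.outpath("annotations.tsv"), sep="\t", index=False)
    nio.write_annotation_gff(
        all_orfs, {a.orf.name: a for a in annotations},
        config.outpath("orfs.gff3"),
        contig_lengths={f.id: len(f.seq) for f in fragments},
    )
    nio.write_fasta(
        [SequenceRecord(o.name, o.aa_seq, alphabet="protein")
         for o in all_orfs if o.aa_seq],
        config.outpath("orfs.faa"),
    )

    if len(fragments) >= 2:
        ref_genome = _reference_genome(annotations, db)
        ref_n = sum(
            1 for pid in db.meta["protein_id"] if db.genome_of(pid) == ref_genome
        )
        maps = build_gene_maps(fragments, annotations)
        out.layout = _stage("scaffold")(scaffold_fragments)(maps, max(ref_n, 1))
        layout_frame(out.layout).to_csv(config.outpath("layout.tsv"),
                                        sep="\t", index=False)
    elif fragments:
        out.layout = ScaffoldLayout([(fragments[0].id, "+")])

    out.gc_per_fragment, out.gc_mean = gc_summary(fragments)
    if fragments:
        out.n50 = n50([len(f.seq) for f in fragments])
    if reads and fragments:
        counts, unmapped = _stage("summarize")(map_reads)(
            reads, fragments, config.max_mismatch
        )
        n_cds = {}
        for orf in all_orfs:
            n_cds[orf.contig_id] = n_cds.get(orf.contig_id, 0) + 1
        out.coverage = coverage_table(
            counts, {f.id: len(f.seq) for f in fragments},
            config.read_length, n_cds,
        )
        out.coverage.to_tsv(config.outpath("coverage.tsv"))
        logger.info("summarize: %d reads mapped, %d unmapped",
                    out.coverage.total_reads, unmapped)

    core_genes = sorted(
        db.meta.loc[db.meta["is_core"] == 1, "gene_name"].dropna().unique()
    ) if "is_core" in db.meta.columns else []
    if core_genes:
        out.checklist = core_gene_checklist(annotations, core_genes)
        out.checklist.to_tsv(config.outpath("core_genes.tsv"))
        logger.info("core genes: %d/%d present", out.checklist.n_present,
                    len(core_genes))

    out.tree_newick = _stage("phylo")(_phylo_stage)(
        annotations, db, config
    )
    if out.tree_newick:
        config.outpath("tree.nwk").write_text(out.tree_newick + "\n")
    return out


def _reference_genome(annotations, db) -> str:
    votes: dict[str, int] = {}
    for ann in annotations:
        if ann.genome_id:
            votes[ann.genome_id] = votes.get(ann.genome_id, 0) + 1
    if votes:
        return max(sorted(votes), key=lambda g: votes[g])
    genomes = sorted(set(db.meta["genome_id"]))
    return genomes[0] if genomes else ""


def _phylo_stage(annotations, db, config: PipelineConfig) -> str | None:
    """Core-gene supermatrix NJ tree over the database genomes plus the
    newly annotated virus; None when fewer than 3 taxa share core genes."""
    if "is_core" not in db.meta.columns:
        return None
    core = db.meta[db.meta["is_core"] == 1]
    novel_taxon = config.orf_prefix
    by_gene: dict[str, dict[str, str]] = {}
    seqs = {r.id: r.seq for r in db.records}
    for _, row in core.iterrows():
        gene = row["gene_name"]
        by_gene.setdefault(gene, {})[row["genome_id"]] = seqs[row["protein_id"]]
    for ann in annotations:
        if ann.hit and ann.gene_name in by_gene and not ann.partial_by_coverage:
            by_gene[ann.gene_name].setdefault(novel_taxon, ann.orf.aa_seq)
    taxa = sorted({t for g in by_gene.values() for t in g})
    if len(taxa) < 3:
        return None
    alignments = {}
    for gene, members in sorted(by_gene.items()):
        if len(members) < 2:
            continue
        recs = [SequenceRecord(t, s, alphabet="protein")
                for t, s in sorted(members.items())]
        alignments[gene] = align_gene(recs)
    if not alignments:
        return None
    sm = build_supermatrix(alignments, taxa)
    tree = bootstrap_support(sm, config.bootstrap_reps, seed=config.seed)
    return tree.newick()
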