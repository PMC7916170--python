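"""Synthetic circular nudivirus-like genomes with known ground truth.

Every downstream stage is testable without downloads: the generator builds a
fully annotated reference virus (the ordering reference), evolves a "novel"
virus from it at a controlled protein divergence, fragments the novel genome
into contigs separated by sequencing gaps, mixes in host background contigs,
and samples fixed-length single-end reads — emitting truth tables for ORFs,
homology, fragment layout and read origin.

Default generation parameters reflect the regime the pipeline targets: a
circular dsDNA genome of ~130 kb carrying ~100 protein-coding genes (a
conserved core subset plus accessory genes), ~40% amino-acid divergence from
the reference, five fragments, ~18.5x coverage of 100-nt reads, and an
AT-rich base composition (GC ~0.28).

Coding sequences are generated codon-by-codon with bases drawn i.i.d. at the
target GC (stop codons rejected), so both the base composition and the
amino-acid composition of the genes follow the target composition naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .orfs import STOP_CODONS
from .records import Read, SequenceRecord, revcomp, translate
from .scaffold import FragmentGeneMap, MappedOrf, ScaffoldLayout
from .io import ProteinDatabase

import pandas as pd

_BASES = np.array(list("ACGT"))

# codon table for back-translation: aa -> list of codons
_CODONS: dict[str, list[str]] = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _codon = _b1 + _b2 + _b3
            if _codon in STOP_CODONS:
                continue
            _CODONS.setdefault(translate(_codon), []).append(_codon)

_AA_LIST = sorted(a for a in _CODONS if a not in "X*")


class ParameterError(ValueError):
    """Generation parameters are infeasible."""


@dataclass
class GeneModel:
    gene_id: str
    start: int
    end: int  # 0-based half-open, includes the stop codon
    strand: str
    protein: str
    is_core: bool
    order_index: int


@dataclass
class ReferenceVirusModel:
    """A fully annotated circular reference virus."""

    genome: str
    genes: list[GeneModel]
    gc: float
    circular: bool = True

    @property
    def genome_length(self) -> int:
        return len(self.genome)

    def protein_db(self, genome_id: str = "RefNV") -> ProteinDatabase:
        records = [
            SequenceRecord(g.gene_id, g.protein, alphabet="protein")
            for g in self.genes
        ]
        meta = pd.DataFrame(
            {
                "protein_id": [g.gene_id for g in self.genes],
                "genome_id": genome_id,
                "gene_order_index": [g.order_index for g in self.genes],
                "is_core": [int(g.is_core) for g in self.genes],
                "gene_name": [g.gene_id for g in self.genes],
                "gene_strand": [g.strand for g in self.genes],
            }
        )
        return ProteinDatabase(records, meta)

    def core_gene_names(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.is_core]


def _random_bases(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


_STOP_INTS = {16 * "ACGT".index(s[0]) + 4 * "ACGT".index(s[1]) + "ACGT".index(s[2])
              for s in STOP_CODONS}


def _random_cds(rng, n_aa: int, gc: float) -> str:
    """ATG + (n_aa - 1) random non-stop codons + a stop codon, with bases
    at the target GC."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    need = n_aa - 1
    codons: list[str] = []
    while len(codons) < need:
        draw = rng.choice(4, size=(need - len(codons) + 8, 3), p=p)
        ints = draw @ np.array([16, 4, 1])
        for row, ci in zip(draw, ints):
            if ci not in _STOP_INTS:
                codons.append("".join(_BASES[row]))
                if len(codons) == need:
                    break
    stops = sorted(STOP_CODONS)
    w = np.array([np.prod([p["ACGT".index(b)] for b in s]) for s in stops])
    stop = stops[int(rng.choice(3, p=w / w.sum()))]
    return "ATG" + "".join(codons) + stop


def build_reference_model(n_genes: int = 100, genome_length: int = 130_000,
                          core_fraction: float = 0.2, gc: float = 0.28,
                          seed: int = 0) -> ReferenceVirusModel:
    """Construct a reference virus with ``n_genes`` ordered genes on a
    circle of ``genome_length`` bp. Deterministic for a fixed seed."""
    if n_genes < 4:
        raise ParameterError("n_genes must be >= 4")
    rng = np.random.default_rng(seed)
    # protein lengths (aa incl. start M): lognormal, clipped to a realistic range
    lengths = np.clip(
        rng.lognormal(mean=np.log(260), sigma=0.55, size=n_genes), 60, 1400
    ).astype(int)
    nt_needed = int((3 * lengths + 3).sum())
    min_gap = 10
    if nt_needed + n_genes * min_gap > genome_length:
        raise ParameterError(
            f"{n_genes} genes need {nt_needed} bp coding + gaps; "
            f"genome_length {genome_length} too small"
        )
    spare = genome_length - nt_needed - n_genes * min_gap
    gap_extra = rng.multinomial(spare, np.full(n_genes, 1 / n_genes))
    core = np.zeros(n_genes, dtype=bool)
    core[rng.choice(n_genes, size=max(1, round(core_fraction * n_genes)),
                    replace=False)] = True

    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    for i in range(n_genes):
        gap = min_gap + int(gap_extra[i])
        parts.append(_random_bases(rng, gap, gc))
        pos += gap
        cds = _random_cds(rng, int(lengths[i]), gc)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = cds if strand == "+" else revcomp(cds)
        protein = translate(cds)[:-1]  # drop the stop
        genes.append(
            GeneModel(f"gene{i:03d}", pos, pos + len(cds), strand, protein,
                      bool(core[i]), i)
        )
        parts.append(placed)
        pos += len(cds)
    return ReferenceVirusModel("".join(parts), genes, gc)


@dataclass
class TruthGene:
    """A gene of the evolved (novel) genome with its reference homology."""

    gene_id: str
    ref_gene_id: str
    start: int
    end: int
    strand: str
    protein: str
    identity_to_ref: float
    is_core: bool
    order_index: int


_AA_INDEX = {a: i for i, a in enumerate(_AA_LIST)}
_AA_ARRAY = np.array(_AA_LIST)


def _mutate_protein(rng, protein: str, divergence: float) -> str:
    """i.i.d. residue substitution (uniform over the 19 alternatives) at the
    given rate; the initial M is preserved so the gene stays callable."""
    if len(protein) <= 1 or divergence == 0:
        return protein
    idx = np.array([_AA_INDEX.get(a, 0) for a in protein])
    mask = rng.random(len(idx)) < divergence
    mask[0] = False  # keep the start methionine
    # adding 1..19 mod 20 is uniform over the 19 alternatives
    idx[mask] = (idx[mask] + rng.integers(1, 20, size=int(mask.sum()))) % 20
    return "".join(_AA_ARRAY[idx])


def _back_translate(rng, protein: str) -> str:
    u = rng.random(len(protein))
    codons = [
        _CODONS[a][int(x * len(_CODONS[a]))] for a, x in zip(protein, u)
    ]
    stops = sorted(STOP_CODONS)
    codons.append(stops[int(rng.integers(3))])
    return "".join(codons)


def evolve_virus(model: ReferenceVirusModel, aa_divergence: float = 0.4,
                 gene_loss_rate: float = 0.05, seed: int = 0
                 ) -> tuple[str, list[TruthGene], dict[str, str]]:
    """Evolve a novel virus from the reference.

    Retained genes keep the reference order and coordinates on the circle
    (substitution-only evolution, no indels); lost genes are replaced by
    background sequence. Returns (novel genome, truth genes, homology map
    novel gene id -> reference gene id; lost genes map to "").
    """
    if not 0 <= aa_divergence < 1:
        raise ValueError("aa_divergence must be in [0, 1)")
    if not 0 <= gene_loss_rate < 1:
        raise ValueError("gene_loss_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genome = list(model.genome)
    truth: list[TruthGene] = []
    homology: dict[str, str] = {}
    order = 0
    for g in model.genes:
        if rng.random() < gene_loss_rate:
            homology[g.gene_id] = ""
            genome[g.start : g.end] = list(
                _random_bases(rng, g.end - g.start, model.gc)
            )
            continue
        protein = _mutate_protein(rng, g.protein, aa_divergence)
        identity = sum(1 for a, b in zip(protein, g.protein) if a == b) / len(protein)
        cds = _back_translate(rng, protein)
        placed = cds if g.strand == "+" else revcomp(cds)
        genome[g.start : g.end] = list(placed)
        novel_id = g.gene_id.replace("gene", "nv")
        truth.append(
            TruthGene(novel_id, g.gene_id, g.start, g.end, g.strand, protein,
                      identity, g.is_core, order)
        )
        homology[novel_id] = g.gene_id
        order += 1
    return "".join(genome), truth, homology


@dataclass
class FragmentTruth:
    fragment_id: str
    start: int  # genome coordinate of the fragment's first base (pre-flip)
    end: int  # may exceed genome length for a wrapping fragment
    orientation: str  # "-" when the emitted sequence is reverse-complemented


def _circular_slice(genome: str, start: int, length: int) -> str:
    n = len(genome)
    start %= n
    if start + length <= n:
        return genome[start : start + length]
    return genome[start:] + genome[: start + length - n]


def fragment_genome(genome: str, n_fragments: int = 5, min_gap: int = 50,
                    seed: int = 0, min_fragment_len: int = 300
                    ) -> tuple[list[SequenceRecord], list[FragmentTruth]]:
    """Cut a circular genome into fragments separated by gaps >= min_gap.

    Fragments tile the circle in order F1..Fn (starting from the fragment
    following the gap nearest the origin); each fragment is independently
    reverse-complemented with probability 0.5 (recorded in the truth).
    Fragment + gap lengths sum exactly to the genome length. Gap lengths are
    uniform in [min_gap, 3*min_gap].
    """
    n = len(genome)
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    min_gap = max(1, min_gap)
    rng = np.random.default_rng(seed)
    gap_lengths = rng.integers(min_gap, 3 * min_gap + 1, size=n_fragments)
    if int(gap_lengths.sum()) + n_fragments * min_fragment_len > n:
        raise ParameterError("genome too small for requested gaps/fragments")
    # gap start anchors: random circle positions leaving room for fragments
    for _ in range(1000):
        anchors = np.sort(rng.choice(n, size=n_fragments, replace=False))
        spans = np.diff(np.append(anchors, anchors[0] + n))
        if np.all(spans >= gap_lengths + min_fragment_len):
            break
    else:
        raise ParameterError("could not place fragment gaps; relax parameters")
    fragments: list[SequenceRecord] = []
    truths: list[FragmentTruth] = []
    for i in range(n_fragments):
        frag_start = int(anchors[i] + gap_lengths[i])
        frag_len = int(spans[i] - gap_lengths[i])
        seq = _circular_slice(genome, frag_start, frag_len)
        orientation = "-" if rng.random() < 0.5 else "+"
        fid = f"F{i + 1}"
        fragments.append(
            SequenceRecord(fid, seq if orientation == "+" else revcomp(seq))
        )
        truths.append(FragmentTruth(fid, frag_start, frag_start + frag_len, orientation))
    return fragments, truths


def truth_layout(truths: list[FragmentTruth]) -> ScaffoldLayout:
    # fragments already tile the circle in emission order
    return ScaffoldLayout([(t.fragment_id, t.orientation) for t in truths])


def truth_gene_maps(truth_genes: list[TruthGene],
                    fragment_truths: list[FragmentTruth], genome_length: int,
                    min_piece_nt: int = 90) -> list[FragmentGeneMap]:
    """Per-fragment gene maps derived from the simulation truth.

    Genes cut by a fragment edge are included when the retained piece is at
    least ``min_piece_nt`` bp, with the appropriate partial flags. ORF order
    and strand follow the emitted (possibly flipped) fragment sequence;
    strands are relative to the reference gene strand, so an unflipped
    fragment shows '+' ORFs.
    """
    maps = []
    for ft in fragment_truths:
        flen = ft.end - ft.start
        entries = []  # (pos_in_fragment, MappedOrf)
        for g in truth_genes:
            for shift in (0, genome_length):
                gs, ge = g.start + shift, g.end + shift
                lo, hi = max(gs, ft.start), min(ge, ft.end)
                if hi - lo < min_piece_nt:
                    continue
                cut5 = lo > gs  # gene 5'-side truncated (on '+' ref strand)
                cut3 = hi < ge
                if g.strand == "-":
                    cut5, cut3 = cut3, cut5
                pos = lo - ft.start
                strand = g.strand  # strand on the emitted fragment
                if ft.orientation == "-":
                    pos = flen - (hi - ft.start)
                    strand = "-" if strand == "+" else "+"
                # partial flags are biological: flipping the fragment moves
                # the truncation to the other fragment side but it is still
                # the same gene end that is missing
                entries.append(
                    (pos,
                     MappedOrf(g.gene_id, g.order_index, strand,
                               partial5=cut5, partial3=cut3,
                               ref_strand=g.strand))
                )
        entries.sort(key=lambda e: e[0])
        maps.append(FragmentGeneMap(ft.fragment_id, [o for _, o in entries], flen))
    return maps


def simulate_reads(sequences: list[SequenceRecord], coverage: float = 18.5,
                   read_length: int = 100, error_rate: float = 0.002,
                   seed: int = 0) -> list[Read]:
    """Uniformly sample fixed-length single-end reads from each sequence.

    Read count per sequence is round(coverage x length / read_length);
    substitution errors occur i.i.d. at ``error_rate``. Base qualities are
    Phred 40 except at planted error positions (Phred 10), so quality
    trimming is exercised without a full error-quality model. Read ids
    record the source, position and strand (the mapping truth).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for rec in sequences:
        L = len(rec.seq)
        if read_length > L:
            raise ValueError(
                f"read_length {read_length} exceeds sequence {rec.id!r} ({L} bp)"
            )
        n_reads = round(coverage * L / read_length)
        starts = rng.integers(0, L - read_length + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for ri, (start, minus) in enumerate(zip(starts, strands)):
            seq = rec.seq[start : start + read_length]
            if minus:
                seq = revcomp(seq)
            bases = list(seq)
            qual = [40] * read_length
            for i in range(read_length):
                if rng.random() < error_rate:
                    alts = [b for b in "ACGT" if b != bases[i]]
                    bases[i] = alts[rng.integers(3)]
                    qual[i] = 10
            strand = "-" if minus else "+"
            reads.append(
                Read(f"{rec.id}:{start}:{strand}:{ri}", "".join(bases), qual)
            )
    return reads


def random_host_contigs(n: int = 50, length_range: tuple[int, int] = (500, 5000),
                        gc: float = 0.33, seed: int = 0) -> list[SequenceRecord]:
    """Random host background contigs with no planted viral genes."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(SequenceRecord(f"host{i:03d}", _random_bases(rng, L, gc)))
    return out


@dataclass
class SimulatedDataset:
    """One complete synthetic study with its ground truth."""

    reference: ReferenceVirusModel
    novel_genome: str
    truth_genes: list[TruthGene]
    homology: dict[str, str]
    fragments: list[SequenceRecord]
    fragment_truths: list[FragmentTruth]
    host_contigs: list[SequenceRecord]
    reads: list[Read]
    params: dict = field(default_factory=dict)

    def contigs(self) -> list[SequenceRecord]:
        """Viral fragments mixed with host background, as an assembler
        would deliver them."""
        return list(self.fragments) + list(self.host_contigs)

    def gene_maps(self) -> list[FragmentGeneMap]:
        return truth_gene_maps(
            self.truth_genes, self.fragment_truths, len(self.novel_genome)
        )

    def layout(self) -> ScaffoldLayout:
        return truth_layout(self.fragment_truths)


def simulate_dataset(n_genes: int = 100, genome_length: int = 130_000,
                     core_fraction: float = 0.2, gc: float = 0.28,
                     aa_divergence: float = 0.4, gene_loss_rate: float = 0.05,
                     n_fragments: int = 5, min_gap: int = 50,
                     coverage: float = 18.5, read_length: int = 100,
                     error_rate: float = 0.002, n_host: int = 50,
                     host_length_range: tuple[int, int] = (500, 5000),
                     host_gc: float = 0.33, seed: int = 0) -> SimulatedDataset:
    """Generate a full synthetic discovery study (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    model = build_reference_model(n_genes, genome_length, core_fraction, gc,
                                  seed=int(seeds[0]))
    novel, truth_genes, homology = evolve_virus(
        model, aa_divergence, gene_loss_rate, seed=int(seeds[1])
    )
    fragments, frag_truths = fragment_genome(
        novel, n_fragments, min_gap, seed=int(seeds[2])
    )
    hosts = random_host_contigs(n_host, host_length_range, host_gc,
                                seed=int(seeds[3]))
    reads = simulate_reads(fragments, coverage, read_length, error_rate,
                           seed=int(seeds[4]))
    params = dict(
        n_genes=n_genes, genome_length=genome_length,
        core_fraction=core_fraction, gc=gc, aa_divergence=aa_divergence,
        gene_loss_rate=gene_loss_rate, n_fragments=n_fragments,
        min_gap=min_gap, coverage=coverage, read_length=read_length,
        error_rate=error_rate, n_host=n_host, seed=seed,
    )
    return SimulatedDataset(model, novel, truth_genes, homology, fragments,
                            frag_truths, hosts, reads, params)


def simulate_proteome_groups(n_genes: int = 100, n_per_group: int = 2,
                             within_divergence: float = 0.2,
                             between_divergence: float = 0.6,
                             mean_len: int = 250, seed: int = 0
                             ) -> tuple[dict[str, list[SequenceRecord]], dict[str, str]]:
    """Two groups of related proteomes with controlled divergence structure.

    Pairwise protein identity is ~(1 - within_divergence) inside a group and
    ~(1 - between_divergence) across groups, mirroring the homolog-sharing
    contrast between virus lineages. Returns (proteomes, group labels).
    """
    rng = np.random.default_rng(seed)
    member_div = 1 - np.sqrt(1 - within_divergence)
    anc_div = 1 - (1 - between_divergence) / (1 - within_divergence)
    lengths = np.clip(
        rng.lognormal(np.log(mean_len), 0.6, size=n_genes), 50, 1200
    ).astype(int)
    root = [
        "M" + "".join(np.array(list(_AA_LIST))[rng.integers(0, 20, size=L - 1)])
        for L in lengths
    ]
    anc2 = [_mutate_protein(rng, p, anc_div) for p in root]
    proteomes: dict[str, list[SequenceRecord]] = {}
    labels: dict[str, str] = {}
    for gi, (label, ancestor) in enumerate((("alpha", root), ("beta", anc2))):
        for m in range(n_per_group):
            gid = f"{label}{m + 1}"
            proteomes[gid] = [
                SequenceRecord(f"{gid}_g{i:03d}",
                               _mutate_protein(rng, p, member_div),
                               alphabet="protein")
                for i, p in enumerate(ancestor)
            ]
            labels[gid] = label
    return proteomes, labels
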