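"""FASTA/FASTQ/GFF3/TSV input and output, read trimming, and the protein
database container used by the homology screen.

Parsing of the standard formats is delegated to Bio.SeqIO; this module adds
the validation the pipeline contracts require (unique ids, legal alphabets,
length invariants) and raises :class:`~nudimine.records.FormatError` with the
offending line where it can be located.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .records import FormatError, IUPAC_NT, Read, SequenceRecord

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _header_lines(path: Path, marker: str) -> list[int]:
    """1-based line numbers of record headers, for error reporting."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(marker):
                out.append(i)
    return out


def read_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Record order is preserved; whitespace inside sequences is stripped by the
    parser. Duplicate or empty ids, empty sequences and (for ``alphabet="dna"``)
    non-IUPAC characters raise :class:`FormatError` naming the header line.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    headers = _header_lines(path, ">")
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: expected '>' header")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython wording varies
        raise FormatError(f"{path}: {exc}") from exc
    for idx, rec in enumerate(parsed):
        line = headers[idx] if idx < len(headers) else -1
        if not rec.id:
            raise FormatError(f"{path}: line {line}: empty record id")
        if rec.id in seen:
            raise FormatError(f"{path}: line {line}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        if not str(rec.seq):
            raise FormatError(f"{path}: line {line}: record {rec.id!r} has no sequence")
        desc = rec.description
        if desc == rec.id:
            desc = ""
        elif desc.startswith(rec.id + " "):
            desc = desc[len(rec.id) + 1 :]
        out = SequenceRecord(rec.id, str(rec.seq), desc, alphabet)
        if alphabet == "dna":
            bad = set(out.seq) - IUPAC_NT
            if bad:
                raise FormatError(
                    f"{path}: line {line}: illegal character {sorted(bad)[0]!r} "
                    f"in record {rec.id!r}"
                )
        records.append(out)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[Read]:
    """Read 4-line Phred+33 FASTQ into :class:`Read` objects."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    try:
        parsed = list(SeqIO.parse(str(path), "fastq"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return [
        Read(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
        for rec in parsed
    ]


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qual)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def trim_reads(reads: Iterable[Read], qmin: int) -> list[Read]:
    """End-trim bases with quality < ``qmin``; drop reads emptied entirely.

    Only leading and trailing low-quality runs are removed — interior bases
    are never touched, matching quality trimming of read ends.
    """
    if qmin < 0:
        raise ValueError("qmin must be >= 0")
    out: list[Read] = []
    for read in reads:
        lo = 0
        hi = len(read)
        while lo < hi and read.qual[lo] < qmin:
            lo += 1
        while hi > lo and read.qual[hi - 1] < qmin:
            hi -= 1
        if hi > lo:
            out.append(Read(read.id, read.seq[lo:hi], read.qual[lo:hi]))
    return out


# ---------------------------------------------------------------------------
# GFF3


def write_annotation_gff(orfs, annotations, path, contig_lengths=None) -> None:
    """Write called ORFs and their best-hit annotations as GFF3.

    ``annotations`` maps ORF name -> Annotation (or None). Internal 0-based
    half-open coordinates are converted to GFF3 1-based inclusive. Raises
    ``ValueError`` if an ORF overflows its contig.
    """
    contig_lengths = contig_lengths or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, length in sorted(contig_lengths.items()):
            fh.write(f"##sequence-region {cid} 1 {length}\n")
        for orf in orfs:
            length = contig_lengths.get(orf.contig_id)
            if length is not None and orf.end > length:
                raise ValueError(
                    f"ORF {orf.name!r} end {orf.end} exceeds contig "
                    f"{orf.contig_id!r} length {length}"
                )
            ann = annotations.get(orf.name) if annotations else None
            score = "."
            attrs = [f"ID={orf.name}"]
            if ann is not None and ann.hit is not None:
                score = f"{ann.hit.evalue:.3g}"
                if ann.gene_name:
                    attrs.append(f"Name={ann.gene_name}")
                attrs.append(f"subject={ann.hit.subject_id}")
            attrs.append(f"partial5={'true' if orf.partial5 else 'false'}")
            attrs.append(f"partial3={'true' if orf.partial3 else 'false'}")
            fh.write(
                "\t".join(
                    [
                        orf.contig_id,
                        "nudimine",
                        "CDS",
                        str(orf.start + 1),
                        str(orf.end),
                        score,
                        orf.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff(path) -> list[dict]:
    """Parse a GFF3 file written by :func:`write_annotation_gff`.

    Returns feature dicts with internal 0-based half-open coordinates; used
    for round-trip checks and downstream consumption of pipeline output.
    """
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns, got {len(cols)}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                {
                    "contig_id": cols[0],
                    "type": cols[2],
                    "start": int(cols[3]) - 1,
                    "end": int(cols[4]),
                    "score": None if cols[5] == "." else float(cols[5]),
                    "strand": cols[6],
                    "attributes": attrs,
                }
            )
    return feats


# ---------------------------------------------------------------------------
# Protein database with genome-of-origin / gene-order sidecar


@dataclass
class ProteinDatabase:
    """Viral protein FASTA plus per-protein metadata.

    ``meta`` columns: protein_id, genome_id, gene_order_index, is_core,
    gene_name. ``gene_order_index`` is the 0-based position of the gene on
    its (circular) genome, the quantity the synteny scaffolder consumes.
    """

    records: list[SequenceRecord]
    meta: pd.DataFrame
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids in database")
        missing = set(ids) - set(self.meta["protein_id"])
        if missing:
            raise ValueError(f"proteins missing metadata: {sorted(missing)[:3]}")
        self.meta = self.meta.set_index("protein_id", drop=False)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def genome_of(self, protein_id: str) -> str:
        return self.meta.at[protein_id, "genome_id"]

    def gene_order_index(self, protein_id: str):
        val = self.meta.at[protein_id, "gene_order_index"]
        return None if pd.isna(val) else int(val)

    def gene_name(self, protein_id: str) -> str:
        val = self.meta.at[protein_id, "gene_name"]
        return "" if pd.isna(val) else str(val)

    def gene_strand(self, protein_id: str) -> str:
        if "gene_strand" not in self.meta.columns:
            return "+"
        val = self.meta.at[protein_id, "gene_strand"]
        return "+" if pd.isna(val) else str(val)

    def proteomes(self) -> dict[str, list[SequenceRecord]]:
        by_genome: dict[str, list[SequenceRecord]] = {}
        for rec in self.records:
            by_genome.setdefault(self.genome_of(rec.id), []).append(rec)
        return by_genome

    @classmethod
    def load(cls, fasta_path, meta_path) -> "ProteinDatabase":
        records = read_fasta(fasta_path, alphabet="protein")
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(records, meta)

    def save(self, fasta_path, meta_path) -> None:
        write_fasta(self.records, fasta_path)
        self.meta.to_csv(meta_path, sep="\t", index=False)
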