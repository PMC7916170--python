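"""Core sequence record types shared across the pipeline.

Coordinates everywhere in this package are 0-based half-open on the forward
strand; conversion to 1-based inclusive happens only at the GFF3 boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

#: IUPAC nucleotide one-letter codes (uppercase).
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")

#: The 20 standard amino acids.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


class FormatError(ValueError):
    """A sequence file violated its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    ``alphabet`` is declared, not sniffed: "dna" restricts ``seq`` to IUPAC
    nucleotide codes, "protein" accepts amino-acid letters plus X/*.
    """

    id: str
    seq: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Read:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    seq: str
    qual: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide sequence (standard code, table 1).

    Trailing bases short of a codon are dropped; ambiguous codons become X;
    stops are '*'.
    """
    trimmed = seq[: len(seq) - len(seq) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate(table=1))


def gc_fraction(seq: str) -> float:
    """G+C over unambiguous A/C/G/T; ValueError if no unambiguous base."""
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / (gc + at)


def validate_nucleotide(rec: SequenceRecord) -> None:
    """Raise :class:`FormatError` naming the first illegal character."""
    bad = set(rec.seq) - IUPAC_NT
    if bad:
        ch = sorted(bad)[0]
        raise FormatError(
            f"illegal nucleotide character {ch!r} in record {rec.id!r}"
        )
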